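"""Two-step clustering of categorical (optionally continuous) profiles.

Step one compresses subjects into *pre-clusters* — dense regions of the
response space — with a single-pass leader algorithm: subjects are visited in
a seeded random order and each joins the nearest existing pre-cluster when
the merge distance does not exceed a threshold, otherwise founds a new one.
At the default ``threshold = 0`` the pre-clusters are exactly the distinct
complete response patterns, which makes the whole procedure independent of
visiting order.

Step two merges pre-clusters agglomeratively under a log-likelihood distance.
For categorical items the within-cluster cost of cluster v is

    xi_v = N_v * sum_j H_vj,    H_vj = -sum_k (N_vjk / N_v) ln(N_vjk / N_v)

(the summed Shannon entropy of the item margins inside v, scaled by cluster
size); a continuous variable c adds the Gaussian term
N_v * 0.5 * ln(sigma_c^2 + sigma_vc^2), where sigma_c^2 is the overall
variance (it regularises single-member clusters). The distance between
clusters s and t is the cost increase of merging,

    d(s, t) = xi_{s u t} - xi_s - xi_t  >=  0.

Per-k information criteria use the total cost as a deviance:
AIC_k = 2 sum_v xi_v + 2 m_k and BIC_k = 2 sum_v xi_v + m_k ln N with
m_k = k * (sum_j (K_j - 1) + 2 * n_continuous) free parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_random_state

from .base import N_LEVELS, ClusterSolution, FitIndices, decode_levels, encode_levels
from .lca import relative_entropy

logger = logging.getLogger(__name__)

_EMPTY = np.zeros(0)
_TIE_TOL = 1e-12


@dataclass
class PreCluster:
    """A dense region: member ids plus sufficient statistics per variable."""

    members: list
    counts: np.ndarray  # (J, K) categorical level counts
    cont_sum: np.ndarray = field(default_factory=lambda: _EMPTY.copy())
    cont_sumsq: np.ndarray = field(default_factory=lambda: _EMPTY.copy())

    @property
    def size(self) -> int:
        return len(self.members)


def _entropy_term(counts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """sum_j H_vj * N_v for stacked count tables; counts (..., J, K), sizes (...)."""
    freq = counts / sizes[..., None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freq > 0, -freq * np.log(freq), 0.0)
    return sizes * terms.sum(axis=(-2, -1))


def _cost_vec(counts, sizes, csum, cssq, base_var) -> np.ndarray:
    cost = _entropy_term(counts, sizes)
    if base_var.size:
        var = np.maximum(cssq / sizes[..., None] - (csum / sizes[..., None]) ** 2, 0.0)
        cost = cost + sizes * 0.5 * np.log(base_var + var).sum(axis=-1)
    return cost


def cluster_cost(counts: np.ndarray, size: int) -> float:
    """Within-cluster entropy cost xi_v = N_v * sum_j H_vj.

    ``counts`` is the (items x levels) table of member level counts; each
    fully observed item row sums to ``size``. A cluster whose members agree
    on every item costs 0.
    """
    if size < 1:
        raise ValueError("cluster cost is undefined for an empty cluster")
    return float(_entropy_term(np.asarray(counts, dtype=float), np.asarray(float(size))))


def merge_distance(a: PreCluster, b: PreCluster, base_var: np.ndarray | None = None) -> float:
    """Cost increase d(a, b) = xi_{a u b} - xi_a - xi_b (always >= 0)."""
    if base_var is None:
        base_var = _EMPTY
    stats = [
        (c.counts[None], np.array([float(c.size)]), c.cont_sum[None], c.cont_sumsq[None])
        for c in (a, b)
    ]
    xi = [float(_cost_vec(*s, base_var)[0]) for s in stats]
    merged = (
        (a.counts + b.counts)[None],
        np.array([float(a.size + b.size)]),
        (a.cont_sum + b.cont_sum)[None],
        (a.cont_sumsq + b.cont_sumsq)[None],
    )
    return float(_cost_vec(*merged, base_var)[0]) - xi[0] - xi[1]


def _prepare(profiles, continuous):
    """Complete-case encode; returns codes, ids, continuous values, base variances."""
    if profiles is None and continuous is None:
        raise ValueError("provide categorical profiles, continuous scores, or both")
    if profiles is not None:
        codes = encode_levels(profiles)
        ids = np.asarray(profiles.index, dtype=object)
        ok = (codes >= 0).all(axis=1)
    else:
        ids = np.asarray(continuous.index, dtype=object)
        codes = np.zeros((len(ids), 0), dtype=np.int8)
        ok = np.ones(len(ids), dtype=bool)
    if continuous is not None:
        if profiles is not None and not continuous.index.equals(profiles.index):
            raise ValueError("continuous scores must share the profile index")
        cont = continuous.to_numpy(dtype=float)
        ok &= np.isfinite(cont).all(axis=1)
    else:
        cont = np.zeros((len(ids), 0))
    dropped = int((~ok).sum())
    if dropped:
        logger.info(
            "two-step: dropping %d of %d subjects with incomplete profiles",
            dropped,
            len(ids),
        )
    cont = cont[ok]
    base_var = np.maximum(cont.var(axis=0), 1e-12) if cont.shape[1] else _EMPTY
    return codes[ok], list(ids[ok]), cont, base_var


def _onehot(code_row: np.ndarray) -> np.ndarray:
    J = code_row.shape[0]
    counts = np.zeros((J, N_LEVELS))
    if J:
        counts[np.arange(J), code_row] = 1.0
    return counts


def precluster(
    profiles: pd.DataFrame | None,
    threshold: float = 0.0,
    order_seed: int | None = 0,
    continuous: pd.DataFrame | None = None,
) -> list[PreCluster]:
    """Leader-pass pre-clustering of complete-case profiles.

    Subjects are visited in a random order drawn from ``order_seed``; each
    joins the nearest pre-cluster if the merge distance is <= ``threshold``,
    else founds a new one. For purely categorical data ``threshold = 0``
    yields one pre-cluster per distinct response pattern regardless of order.
    """
    codes, subject_ids, cont, base_var = _prepare(profiles, continuous)

    if threshold <= 0.0 and not base_var.size:
        # exact mode: a singleton joins a cluster at d = 0 iff the cluster is
        # pure and shares its pattern, so grouping by pattern is equivalent
        # to the leader pass and independent of visiting order
        groups: dict[tuple, list[int]] = {}
        for i, row in enumerate(codes):
            groups.setdefault(tuple(row), []).append(i)
        return [
            PreCluster(
                members=[subject_ids[i] for i in idx],
                counts=_onehot(codes[idx[0]]) * len(idx),
            )
            for _, idx in sorted(groups.items())
        ]

    rng = check_random_state(order_seed)
    order = rng.permutation(len(subject_ids))

    counts_list: list[np.ndarray] = []
    sizes: list[float] = []
    csum: list[np.ndarray] = []
    cssq: list[np.ndarray] = []
    members: list[list] = []
    costs: list[float] = []
    for i in order:
        c1 = _onehot(codes[i])
        xi1 = float(
            _cost_vec(c1[None], np.ones(1), cont[i][None], (cont[i] ** 2)[None], base_var)[0]
        )
        if counts_list:
            mc = np.stack(counts_list) + c1
            ms = np.asarray(sizes) + 1.0
            mcs = np.stack(csum) + cont[i]
            mcq = np.stack(cssq) + cont[i] ** 2
            d = _cost_vec(mc, ms, mcs, mcq, base_var) - np.asarray(costs) - xi1
            j = int(np.argmin(d))
            if d[j] <= threshold + _TIE_TOL:
                counts_list[j] = counts_list[j] + c1
                sizes[j] += 1.0
                csum[j] = csum[j] + cont[i]
                cssq[j] = cssq[j] + cont[i] ** 2
                members[j].append(subject_ids[i])
                costs[j] = float(
                    _cost_vec(
                        counts_list[j][None],
                        np.array([sizes[j]]),
                        csum[j][None],
                        cssq[j][None],
                        base_var,
                    )[0]
                )
                continue
        counts_list.append(c1)
        sizes.append(1.0)
        csum.append(cont[i].copy())
        cssq.append(cont[i] ** 2)
        members.append([subject_ids[i]])
        costs.append(xi1)
    return [
        PreCluster(members=m, counts=c, cont_sum=s, cont_sumsq=q)
        for m, c, s, q in zip(members, counts_list, csum, cssq)
    ]


def agglomerate(
    preclusters: list[PreCluster],
    k_min: int = 1,
    method: str = "twostep",
    base_var: np.ndarray | None = None,
    record_max_k: int | None = None,
) -> dict[int, ClusterSolution]:
    """Stepwise merging of pre-clusters down to ``k_min`` clusters.

    At every step the pair with the smallest merge distance d(s, t) is
    joined; ties break on the smallest combined cost xi_s + xi_t, then on the
    lexicographically smallest member id of the merged pair. The partition is
    recorded at every k (or only k <= ``record_max_k``) together with its
    information criteria.
    """
    if not preclusters:
        raise ValueError("at least one pre-cluster is required")
    m = len(preclusters)
    J = preclusters[0].counts.shape[0]
    n_cont = np.asarray(preclusters[0].cont_sum).size
    counts = np.stack([c.counts.astype(float) for c in preclusters])
    sizes = np.array([float(c.size) for c in preclusters])
    csum = np.stack([np.asarray(c.cont_sum, dtype=float) for c in preclusters])
    cssq = np.stack([np.asarray(c.cont_sumsq, dtype=float) for c in preclusters])
    members = [list(c.members) for c in preclusters]
    min_id = [str(min(ms, key=str)) for ms in members]

    if base_var is None:
        if n_cont:
            tot = sizes.sum()
            mean = csum.sum(0) / tot
            base_var = np.maximum(cssq.sum(0) / tot - mean**2, 1e-12)
        else:
            base_var = _EMPTY

    costs = _cost_vec(counts, sizes, csum, cssq, base_var)
    n_total = int(sizes.sum())
    active = np.ones(m, dtype=bool)

    def dist_to_all(i: int) -> np.ndarray:
        """d(i, j) for all active j != i; inactive/self get +inf."""
        mc = counts[i] + counts
        ms = sizes[i] + sizes
        mcs = csum[i] + csum
        mcq = cssq[i] + cssq
        d = _cost_vec(mc, ms, mcs, mcq, base_var) - costs[i] - costs
        d[~active] = np.inf
        d[i] = np.inf
        return d

    D = np.full((m, m), np.inf)
    for i in range(m):
        D[i] = dist_to_all(i)

    solutions: dict[int, ClusterSolution] = {}

    def record(k: int) -> None:
        if record_max_k is not None and k > record_max_k:
            return
        idx = np.flatnonzero(active)
        ordered = sorted(idx, key=lambda v: min_id[v])
        assignment = {
            sid: label
            for label, v in enumerate(ordered, start=1)
            for sid in members[v]
        }
        series = pd.Series(assignment, name="cluster")
        series.index.name = "subject_id"
        total_cost = float(costs[active].sum())
        m_k = k * (J * (N_LEVELS - 1) + 2 * n_cont)
        fit = FitIndices(
            loglik=-total_cost,
            aic=2.0 * total_cost + 2.0 * m_k,
            bic=2.0 * total_cost + m_k * np.log(n_total),
            entropy=_assignment_entropy(
                counts[idx], sizes[idx], csum[idx], cssq[idx], costs[idx], base_var
            ),
        )
        solutions[k] = ClusterSolution(method=method, k=k, assignment=series, fit=fit)

    k = m
    record(k)
    while k > max(1, k_min):
        dmin = D.min()
        cand = np.argwhere(D <= dmin + _TIE_TOL)
        # tie-break: lowest combined cost, then smallest member id of the pair
        key = lambda st: (
            costs[st[0]] + costs[st[1]],
            min(min_id[st[0]], min_id[st[1]]),
            max(min_id[st[0]], min_id[st[1]]),
        )
        s, t = min((tuple(p) for p in cand), key=key)
        counts[s] += counts[t]
        sizes[s] += sizes[t]
        csum[s] += csum[t]
        cssq[s] += cssq[t]
        members[s] = members[s] + members[t]
        min_id[s] = min(min_id[s], min_id[t])
        costs[s] = float(
            _cost_vec(counts[s][None], sizes[s : s + 1], csum[s][None], cssq[s][None], base_var)[0]
        )
        active[t] = False
        D[t, :] = np.inf
        D[:, t] = np.inf
        row = dist_to_all(s)
        D[s, :] = row
        D[:, s] = row
        k -= 1
        record(k)
    return solutions


def _assignment_entropy(counts, sizes, csum, cssq, costs, base_var) -> float:
    """Certainty of subject-to-cluster assignment, as a relative entropy.

    Each cluster's average member (its level-frequency profile) is softly
    re-assigned to the final clusters with weight exp(-d) in its merge
    distance d to each cluster; the relative entropy of those weights plays
    the role the posterior entropy plays for the latent-class solution
    (1 = unambiguous assignment).
    """
    k = len(sizes)
    if k < 2:
        return 1.0
    taus = []
    for v in range(k):
        proto_c = counts[v] / sizes[v]
        proto_s = csum[v] / sizes[v]
        proto_q = cssq[v] / sizes[v]
        mc = counts + proto_c
        ms = sizes + 1.0
        mcs = csum + proto_s
        mcq = cssq + proto_q
        d_row = _cost_vec(mc, ms, mcs, mcq, base_var) - costs
        d_row[v] = 0.0
        weights = np.exp(-(d_row - d_row.min()))
        weights /= weights.sum()
        taus.extend([weights] * int(sizes[v]))
    return relative_entropy(np.asarray(taus))


def twostep_fit(
    profiles: pd.DataFrame | None,
    k_max: int = 4,
    threshold: float = 0.0,
    seed: int | None = 0,
    continuous: pd.DataFrame | None = None,
) -> dict[int, ClusterSolution]:
    """Full two-step path: pre-cluster then agglomerate, solutions for k = 1..k_max."""
    pres = precluster(profiles, threshold=threshold, order_seed=seed, continuous=continuous)
    if k_max > len(pres):
        logger.warning(
            "two-step: k_max=%d exceeds %d pre-clusters; path truncated",
            k_max,
            len(pres),
        )
    return agglomerate(pres, record_max_k=k_max)


class TwoStepClusterer(ClusterMixin, BaseEstimator):
    """Two-step (pre-cluster + agglomerate) estimator at a fixed cluster count.

    Parameters
    ----------
    n_clusters : int, default=2
    threshold : float, default=0.0
        Leader-pass merge threshold; 0 keeps distinct patterns separate.
    random_state : int, optional
        Seed for the leader-pass visiting order (irrelevant at threshold 0).

    Attributes
    ----------
    labels_ : ndarray — 0-based cluster labels of complete-case subjects
    subject_ids_ : list — ids retained after listwise deletion
    solution_ : ClusterSolution at ``n_clusters``
    path_ : dict k -> ClusterSolution for k <= n_clusters
    """

    def __init__(self, n_clusters: int = 2, threshold: float = 0.0, random_state=None):
        self.n_clusters = n_clusters
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            arr = np.asarray(X, dtype=np.int8)
            X = decode_levels(arr, range(arr.shape[0]), range(arr.shape[1]))
        path = twostep_fit(
            X,
            k_max=max(int(self.n_clusters), 1),
            threshold=self.threshold,
            seed=self.random_state,
        )
        if self.n_clusters not in path:
            raise ValueError(
                f"n_clusters={self.n_clusters} unreachable: only "
                f"{max(path)} pre-clusters"
            )
        self.path_ = path
        self.solution_ = path[self.n_clusters]
        self.subject_ids_ = list(self.solution_.assignment.index)
        self.labels_ = self.solution_.assignment.to_numpy() - 1
        return self
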