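"""Latent class analysis of polytomous items via the EM algorithm.

The model: each subject belongs to one of R latent classes with prevalence
p_r; given the class, the J three-level items are independent (local
independence), item j responding at level k with probability pi[j, r, k].
The observed-data likelihood of subject i with responses x_ij is

    L_i = sum_r p_r * prod_{j observed} pi[j, r, x_ij]

with the product running over observed items only, so incomplete batteries
contribute through their observed cells and no imputation is performed.

Estimation is plain EM from several random starts; the best start by
maximized log-likelihood is kept. All posterior arithmetic is done in log
space to survive near-deterministic response patterns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_random_state

from .base import (
    LEVELS,
    N_LEVELS,
    ClusterSolution,
    DegenerateModelError,
    FitIndices,
    encode_levels,
)

# pi is clipped away from {0, 1} during EM so log(pi) stays finite on
# separable data; the clip is well below any scientifically meaningful
# probability resolution.
_PI_CLIP = 1e-10


@dataclass
class LatentClassModel:
    """Fitted latent-class mixture for three-level items.

    Attributes
    ----------
    n_classes : int
        Number of latent classes R.
    prevalences : ndarray, shape (R,)
        Class mixing proportions, summing to 1.
    response_probs : ndarray, shape (J, R, K)
        pi[j, r, k]: probability that an item-j response in class r falls at
        level k; each (j, r) row sums to 1.
    item_ids : list of str
    loglik : float
        Maximized observed-data log-likelihood.
    n_parameters : int
        Free parameters: (R - 1) + R * sum_j (K_j - 1).
    n_used : int
        Subjects with at least one observed item.
    converged : bool
    """

    n_classes: int
    prevalences: np.ndarray
    response_probs: np.ndarray
    item_ids: list[str]
    loglik: float
    n_parameters: int
    n_used: int
    converged: bool
    seed: int | None = None
    n_starts: int | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "R": self.n_classes,
            "item_ids": list(self.item_ids),  # order matters; JSON keys are sorted
            "p": self.prevalences.tolist(),
            "pi": {
                item: {
                    f"class_{r + 1}": {
                        LEVELS[k]: float(self.response_probs[j, r, k])
                        for k in range(N_LEVELS)
                    }
                    for r in range(self.n_classes)
                }
                for j, item in enumerate(self.item_ids)
            },
            "loglik": self.loglik,
            "q": self.n_parameters,
            "n_used": self.n_used,
            "converged": self.converged,
            "seed": self.seed,
            "n_starts": self.n_starts,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LatentClassModel":
        payload = json.loads(Path(path).read_text())
        items = payload.get("item_ids") or list(payload["pi"])
        R = payload["R"]
        pi = np.array(
            [
                [
                    [payload["pi"][item][f"class_{r + 1}"][lv] for lv in LEVELS]
                    for r in range(R)
                ]
                for item in items
            ]
        )
        return cls(
            n_classes=R,
            prevalences=np.array(payload["p"], dtype=float),
            response_probs=pi,
            item_ids=items,
            loglik=payload["loglik"],
            n_parameters=payload["q"],
            n_used=payload["n_used"],
            converged=payload["converged"],
            seed=payload.get("seed"),
            n_starts=payload.get("n_starts"),
        )


def relative_entropy(tau: np.ndarray) -> float:
    """Relative entropy of a posterior-membership matrix, in [0, 1].

    E = 1 - [sum_i sum_r -tau_ir ln tau_ir] / (N ln R); 1 means every subject
    is assigned with certainty, 0 means uniform posteriors. Defined as 1 for
    R = 1 (a one-class model classifies with certainty by convention).
    """
    tau = np.asarray(tau, dtype=float)
    n, R = tau.shape
    if R < 2 or n == 0:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(tau > 0, -tau * np.log(tau), 0.0)
    return float(1.0 - terms.sum() / (n * np.log(R)))


def _as_codes(profiles) -> tuple[np.ndarray, list, list]:
    if isinstance(profiles, pd.DataFrame):
        return encode_levels(profiles), list(profiles.index), list(profiles.columns)
    X = np.asarray(profiles)
    if X.dtype.kind not in "iu":
        raise TypeError("array profiles must be integer level codes (-1 = missing)")
    return (
        X.astype(np.int8),
        list(range(X.shape[0])),
        [f"item_{j + 1}" for j in range(X.shape[1])],
    )


def _loglik_matrix(X, observed, log_p, log_pi):
    """Per-subject, per-class complete log-likelihood log p_r + sum_j log pi."""
    n = X.shape[0]
    ll = np.broadcast_to(log_p, (n, log_p.size)).copy()
    Xc = np.where(observed, X, 0)
    for j in range(X.shape[1]):
        lj = log_pi[j][:, Xc[:, j]].T  # (n, R)
        ll += np.where(observed[:, j][:, None], lj, 0.0)
    return ll


def _em_single(X, observed, R, rng, tol, max_iter):
    """One EM run from a random responsibility matrix; returns a dict."""
    n, J = X.shape
    tau = rng.uniform(0.1, 1.0, size=(n, R))
    tau /= tau.sum(axis=1, keepdims=True)

    obs_f = observed.astype(float)
    level_ind = [(X == k) & observed for k in range(N_LEVELS)]

    loglik = -np.inf
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        # M step from current responsibilities
        p = tau.mean(axis=0)
        p = np.clip(p, 1e-12, None)
        p /= p.sum()
        pi = np.empty((J, R, N_LEVELS))
        for k in range(N_LEVELS):
            pi[:, :, k] = level_ind[k].T.astype(float) @ tau
        denom = obs_f.T @ tau  # (J, R) weighted observed counts
        pi /= np.clip(denom, 1e-12, None)[:, :, None]
        pi = np.clip(pi, _PI_CLIP, 1.0 - _PI_CLIP)

        # E step and observed-data log-likelihood under the new parameters
        ll = _loglik_matrix(X, observed, np.log(p), np.log(pi))
        norm = logsumexp(ll, axis=1)
        new_loglik = float(norm.sum())
        tau = np.exp(ll - norm[:, None])
        trace.append(new_loglik)
        if np.isfinite(loglik) and new_loglik - loglik <= tol * (1.0 + abs(new_loglik)):
            converged = True
            loglik = new_loglik
            break
        loglik = new_loglik

    return {
        "p": p,
        "pi": pi,
        "tau": tau,
        "loglik": loglik,
        "trace": np.asarray(trace),
        "converged": converged,
    }


class LatentClassAnalysis(ClusterMixin, BaseEstimator):
    """Latent-class mixture estimator for three-level categorical profiles.

    Parameters
    ----------
    n_classes : int, default=2
        Number of latent classes R.
    n_starts : int, default=20
        Random EM restarts; the start with the highest maximized
        log-likelihood wins.
    tol : float, default=1e-8
        Relative log-likelihood improvement below which a start stops.
    max_iter : int, default=5000
        EM iteration cap per start; hitting it flags non-convergence but the
        best iterate is still returned.
    random_state : int or RandomState, optional

    Attributes
    ----------
    prevalences_ : ndarray (R,)
    response_probs_ : ndarray (J, R, K)
    loglik_ : float
    n_parameters_ : int
    n_used_ : int
    aic_, bic_ : float
    relative_entropy_ : float
    labels_ : ndarray — modal class (0-based) of each training subject
    posterior_ : ndarray (n, R) — training-set class posteriors
    loglik_trace_ : ndarray — per-iteration log-likelihood of the best start
    converged_ : bool
    """

    def __init__(
        self,
        n_classes: int = 2,
        n_starts: int = 20,
        tol: float = 1e-8,
        max_iter: int = 5000,
        random_state=None,
    ):
        self.n_classes = n_classes
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        codes, subject_ids, item_ids = _as_codes(X)
        R = int(self.n_classes)
        if R < 1:
            raise ValueError("n_classes must be >= 1")
        observed = codes >= 0
        if not observed.any(axis=0).all():
            raise ValueError("every item needs at least one observed response")
        n_levels_seen = np.array(
            [len(np.unique(codes[observed[:, j], j])) for j in range(codes.shape[1])]
        )
        if (n_levels_seen < 2).any():
            j = int(np.argmin(n_levels_seen))
            raise ValueError(
                f"item {item_ids[j]!r} shows a single level; it carries no "
                "grouping information"
            )
        complete = codes[observed.all(axis=1)]
        n_patterns = len({tuple(row) for row in codes[observed.any(axis=1)]}) if len(
            codes
        ) else 0
        del complete
        if R > max(n_patterns, 1):
            raise DegenerateModelError(
                f"{R} classes requested but only {n_patterns} distinct observed "
                "response patterns"
            )

        rng = check_random_state(self.random_state)
        best = None
        for _ in range(max(1, int(self.n_starts))):
            run = _em_single(codes, observed, R, rng, self.tol, self.max_iter)
            if best is None or run["loglik"] > best["loglik"]:
                best = run

        self.subject_ids_ = subject_ids
        self.item_ids_ = item_ids
        self.prevalences_ = best["p"]
        self.response_probs_ = best["pi"]
        self.loglik_ = best["loglik"]
        self.loglik_trace_ = best["trace"]
        self.converged_ = bool(best["converged"])
        self.n_used_ = int(observed.any(axis=1).sum())
        J = codes.shape[1]
        self.n_parameters_ = (R - 1) + R * J * (N_LEVELS - 1)
        self.posterior_ = best["tau"]
        self.labels_ = best["tau"].argmax(axis=1)
        self.relative_entropy_ = relative_entropy(best["tau"])
        self.aic_ = -2.0 * self.loglik_ + 2.0 * self.n_parameters_
        self.bic_ = -2.0 * self.loglik_ + self.n_parameters_ * np.log(self.n_used_)
        return self

    def _check_fitted(self):
        if not hasattr(self, "response_probs_"):
            raise RuntimeError("estimator is not fitted")

    def predict_proba(self, X) -> np.ndarray:
        """Posterior class membership tau[i, r] via Bayes' rule (log space)."""
        self._check_fitted()
        codes, _, item_ids = _as_codes(X)
        if item_ids != self.item_ids_ and not isinstance(X, np.ndarray):
            raise ValueError("profile items do not match the fitted model")
        observed = codes >= 0
        ll = _loglik_matrix(
            codes,
            observed,
            np.log(np.clip(self.prevalences_, 1e-300, None)),
            np.log(self.response_probs_),
        )
        return np.exp(ll - logsumexp(ll, axis=1)[:, None])

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y=None) -> float:
        """Mean per-subject observed-data log-likelihood."""
        self._check_fitted()
        codes, _, _ = _as_codes(X)
        observed = codes >= 0
        ll = _loglik_matrix(
            codes,
            observed,
            np.log(np.clip(self.prevalences_, 1e-300, None)),
            np.log(self.response_probs_),
        )
        return float(logsumexp(ll, axis=1).mean())

    def to_model(self) -> LatentClassModel:
        self._check_fitted()
        seed = self.random_state if isinstance(self.random_state, (int, np.integer)) else None
        return LatentClassModel(
            n_classes=self.n_classes,
            prevalences=self.prevalences_,
            response_probs=self.response_probs_,
            item_ids=list(self.item_ids_),
            loglik=self.loglik_,
            n_parameters=self.n_parameters_,
            n_used=self.n_used_,
            converged=self.converged_,
            seed=seed,
            n_starts=self.n_starts,
        )

    def fit_indices(self) -> FitIndices:
        self._check_fitted()
        return FitIndices(
            loglik=self.loglik_,
            aic=self.aic_,
            bic=self.bic_,
            entropy=self.relative_entropy_,
        )


def lca_fit(
    profiles: pd.DataFrame,
    n_classes: int,
    n_starts: int = 20,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> tuple[LatentClassModel, pd.DataFrame]:
    """Fit a latent-class model; returns the model and posterior memberships.

    The returned membership frame has one column per class (``class_1`` ..
    ``class_R``) plus ``modal_class`` with labels in {1..R}.
    """
    est = LatentClassAnalysis(
        n_classes=n_classes,
        n_starts=n_starts,
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    ).fit(profiles)
    membership = _membership_frame(est.posterior_, est.subject_ids_)
    return est.to_model(), membership


def posterior(model: LatentClassModel, profiles: pd.DataFrame) -> pd.DataFrame:
    """Posterior memberships of (possibly new) profiles under a fitted model."""
    if isinstance(profiles, pd.DataFrame):
        if list(profiles.columns) != model.item_ids:
            raise ValueError("profile items do not match the model's items")
        codes = encode_levels(profiles)
        subject_ids = list(profiles.index)
    else:
        codes, subject_ids, _ = _as_codes(profiles)
    observed = codes >= 0
    ll = _loglik_matrix(
        codes,
        observed,
        np.log(np.clip(model.prevalences, 1e-300, None)),
        np.log(np.clip(model.response_probs, 1e-300, 1.0)),
    )
    tau = np.exp(ll - logsumexp(ll, axis=1)[:, None])
    return _membership_frame(tau, subject_ids)


def _membership_frame(tau: np.ndarray, subject_ids) -> pd.DataFrame:
    R = tau.shape[1]
    out = pd.DataFrame(
        tau,
        index=pd.Index(subject_ids, name="subject_id"),
        columns=[f"class_{r + 1}" for r in range(R)],
    )
    out["modal_class"] = tau.argmax(axis=1) + 1
    return out


def lca_solution(
    profiles: pd.DataFrame,
    n_classes: int,
    n_starts: int = 20,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> ClusterSolution:
    """Convenience wrapper returning a :class:`ClusterSolution` at one k."""
    est = LatentClassAnalysis(
        n_classes=n_classes,
        n_starts=n_starts,
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    ).fit(profiles)
    assignment = pd.Series(
        est.labels_ + 1, index=pd.Index(est.subject_ids_, name="subject_id")
    )
    flags = [] if est.converged_ else ["non-convergence: best iterate returned"]
    return ClusterSolution(
        method="lca", k=n_classes, assignment=assignment, fit=est.fit_indices(),
        flags=flags,
    )
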