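"""Characterising and validating cluster solutions.

Covers the descriptive and agreement statistics used to interpret a chosen
partition: per-item cluster x level contingency tables with Pearson chi-square
tests, Low/High profile labelling of a two-cluster solution, optimal label
alignment between independent clusterings, Cohen's kappa agreement, and the
internal-validity exercise of refitting the whole pipeline inside each
diagnostic stratum and scoring agreement with the whole-sample partition.

Bundled reference data: the package ships the published cluster-composition
count tables of a cross-diagnostic inpatient cohort (N = 387; two methods x
10 executive-function items x 3 levels) together with the published
chi-square statistics, plus the per-diagnosis cluster counts. They serve as
exact fixtures for the contingency machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .base import LEVELS, ClusterSolution
from .model_selection import SelectionResult, index_path, select_best

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df, "p_value": self.p_value}


@dataclass
class AgreementReport:
    """Chance-corrected agreement between two labelings of the same subjects."""

    confusion: pd.DataFrame
    kappa: float
    p_observed: float
    p_chance: float
    percent_agreement: float
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.to_dict(),
            "kappa": None if np.isnan(self.kappa) else self.kappa,
            "p_observed": self.p_observed,
            "p_chance": self.p_chance,
            "percent_agreement": self.percent_agreement,
            "flags": self.flags,
        }


def crosstab(assignment: pd.Series, categories: pd.Series) -> pd.DataFrame:
    """Cluster x category count table over the shared subjects.

    ``categories`` may hold per-item levels or stratum labels. Raises when
    the two series share no subjects.
    """
    joined = pd.concat(
        {"cluster": assignment, "category": categories}, axis=1, join="inner"
    ).dropna()
    if joined.empty:
        raise ValueError("assignment and categories share no labelled subjects")
    table = pd.crosstab(joined["cluster"], joined["category"])
    if set(joined["category"].unique()) <= set(LEVELS):
        table = table.reindex(
            columns=[lv for lv in LEVELS if lv in table.columns]
        )
    return table


def row_percentages(table: pd.DataFrame) -> pd.DataFrame:
    """Within-cluster percentages, rows summing to 100."""
    return table.div(table.sum(axis=1), axis=0) * 100.0


def chi_square(table: pd.DataFrame | np.ndarray) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction.

    The statistic is sum (O - E)^2 / E with expected counts from the table
    margins; df = (rows - 1)(cols - 1). Requires at least a 2 x 2 table and
    strictly positive margins.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("chi-square needs at least a 2 x 2 table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero margin: expected counts are undefined")
    res = chi2_contingency(counts, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic), df=int(res.dof), p_value=float(res.pvalue)
    )


def per_item_chi_square(
    assignment: pd.Series, profiles: pd.DataFrame
) -> pd.DataFrame:
    """Chi-square of cluster membership against each item's levels."""
    rows = []
    for item in profiles.columns:
        table = crosstab(assignment, profiles[item])
        res = chi_square(table)
        rows.append(
            {
                "item": item,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows).set_index("item")


def label_profiles(
    assignment: pd.Series, profiles: pd.DataFrame
) -> tuple[dict[int, str], list[str]]:
    """Name the two clusters Low/High by their share of below-norm scores.

    The cluster with the larger overall proportion of "below" performances
    across all items is the Low Cognitive Profile; the other is High. An
    exact tie is flagged and resolved by cluster-label order.
    """
    clusters = sorted(assignment.unique())
    if len(clusters) != 2:
        raise ValueError("Low/High labelling is defined for k = 2 solutions")
    shares = {}
    for c in clusters:
        sub = profiles.loc[assignment.index[assignment == c]]
        values = sub.to_numpy(dtype=object)
        observed = ~pd.isna(values)
        shares[c] = float((values == "below").sum() / max(observed.sum(), 1))
    flags = []
    if shares[clusters[0]] == shares[clusters[1]]:
        flags.append("tie: equal below-share; Low assigned to the first cluster label")
        low = clusters[0]
    else:
        low = max(clusters, key=lambda c: shares[c])
    labels = {c: ("Low" if c == low else "High") for c in clusters}
    if flags:
        logger.warning(flags[0])
    return labels, flags


def align_labels(reference: pd.Series, other: pd.Series) -> pd.Series:
    """Permute ``other``'s labels to maximise agreement with ``reference``.

    Exhaustive over the k! label permutations (intended for k <= 4). Both
    series must label the same subjects with the same number of clusters.
    """
    joined = pd.concat({"a": reference, "b": other}, axis=1, join="inner").dropna()
    labels_a = sorted(joined["a"].unique())
    labels_b = sorted(joined["b"].unique())
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"cannot align: {len(labels_a)} vs {len(labels_b)} clusters"
        )
    confusion = pd.crosstab(joined["a"], joined["b"])
    confusion = confusion.reindex(index=labels_a, columns=labels_b, fill_value=0)
    best_perm, best_diag = None, -1
    for perm in permutations(range(len(labels_b))):
        diag = sum(confusion.iloc[i, perm[i]] for i in range(len(labels_a)))
        if diag > best_diag:
            best_perm, best_diag = perm, diag
    mapping = {labels_b[best_perm[i]]: labels_a[i] for i in range(len(labels_a))}
    return other.map(mapping)


def cohen_kappa(a: pd.Series, b: pd.Series) -> AgreementReport:
    """Cohen's kappa between two (already aligned) labelings.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o and chance
    agreement p_e from the marginal label distributions. Degenerate tables
    with p_e = 1 yield kappa = NaN with a flag.
    """
    joined = pd.concat({"a": a, "b": b}, axis=1, join="inner").dropna()
    if joined.empty:
        raise ValueError("no shared subjects")
    labels = sorted(set(joined["a"].unique()) | set(joined["b"].unique()))
    confusion = pd.crosstab(joined["a"], joined["b"]).reindex(
        index=labels, columns=labels, fill_value=0
    )
    counts = confusion.to_numpy(dtype=float)
    n = counts.sum()
    p_o = float(np.trace(counts) / n)
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum() / n**2)
    flags = []
    if p_e >= 1.0 - 1e-12:
        kappa = float("nan")
        flags.append("degenerate margins: chance agreement is 1, kappa undefined")
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementReport(
        confusion=confusion,
        kappa=kappa,
        p_observed=p_o,
        p_chance=p_e,
        percent_agreement=100.0 * p_o,
        flags=flags,
    )


@dataclass
class StratumValidation:
    stratum: str
    n_subjects: int
    selection: SelectionResult | None
    agreement: AgreementReport | None
    flags: list[str] = field(default_factory=list)


def within_stratum_validation(
    profiles: pd.DataFrame,
    strata: pd.Series,
    method: str = "lca",
    k_max: int = 4,
    seed: int = 0,
    whole_assignment: pd.Series | None = None,
    min_stratum_size: int = 20,
    n_starts: int = 10,
) -> dict[str, StratumValidation]:
    """Refit the chosen pipeline inside each stratum and score agreement.

    For each stratum (e.g. diagnosis) with at least ``min_stratum_size``
    subjects the full path k = 1..k_max is refitted by ``method``, the
    consecutive-change rule picks k, and — when the stratum solution has the
    same k as the whole-sample solution — the two labelings are aligned and
    Cohen's kappa plus the percent of consistently reclassified subjects is
    reported against the whole-sample labels restricted to the stratum.
    """
    from .lca import lca_solution
    from .twostep import twostep_fit

    def fit_path(data: pd.DataFrame, fit_seed: int) -> dict[int, ClusterSolution]:
        if method == "lca":
            return {
                k: lca_solution(data, k, n_starts=n_starts, seed=fit_seed + k)
                for k in range(1, k_max + 1)
            }
        if method == "twostep":
            return twostep_fit(data, k_max=k_max, seed=fit_seed)
        raise ValueError(f"unknown method {method!r}")

    if whole_assignment is None:
        whole_path = fit_path(profiles, seed)
        whole_sel = select_best(index_path(whole_path))
        whole_assignment = whole_path[max(whole_sel.chosen_k, 2)].assignment

    results: dict[str, StratumValidation] = {}
    for stratum in sorted(strata.dropna().unique()):
        ids = strata.index[strata == stratum]
        sub = profiles.loc[profiles.index.intersection(ids)]
        if len(sub) < min_stratum_size:
            logger.warning(
                "stratum %s skipped: %d subjects < minimum %d",
                stratum,
                len(sub),
                min_stratum_size,
            )
            results[str(stratum)] = StratumValidation(
                stratum=str(stratum),
                n_subjects=len(sub),
                selection=None,
                agreement=None,
                flags=["skipped: too few subjects"],
            )
            continue
        path = fit_path(sub, seed)
        sel = select_best(index_path(path))
        flags: list[str] = []
        agreement = None
        whole_sub = whole_assignment.loc[
            whole_assignment.index.intersection(sub.index)
        ]
        k_whole = whole_sub.nunique()
        stratum_assignment = path[min(sel.chosen_k, max(path))].assignment
        if sel.chosen_k < 2:
            flags.append("one-class stratum solution; kappa undefined")
        elif whole_sub.nunique() < 2:
            flags.append("whole-sample labels are constant in this stratum; kappa undefined")
        elif stratum_assignment.nunique() != k_whole:
            flags.append(
                f"stratum solution has k={stratum_assignment.nunique()} but "
                f"whole-sample restriction has {k_whole} labels; kappa skipped"
            )
        else:
            aligned = align_labels(whole_sub, stratum_assignment)
            agreement = cohen_kappa(whole_sub, aligned)
        results[str(stratum)] = StratumValidation(
            stratum=str(stratum),
            n_subjects=len(sub),
            selection=sel,
            agreement=agreement,
            flags=flags,
        )
    return results


# ---------------------------------------------------------------------------
# bundled published count tables


def _read_bundled(name: str) -> pd.DataFrame:
    with resources.files("cogclust.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_cluster_composition() -> pd.DataFrame:
    """Published cluster x level counts per method and item (N = 387 cohort).

    Columns: method, item, then below/within/above counts for the Low and
    High profile clusters, and the published chi-square statistic.
    """
    return _read_bundled("cluster_composition_counts.tsv")


def load_diagnosis_distribution() -> pd.DataFrame:
    """Published per-diagnosis cluster counts for both methods."""
    return _read_bundled("diagnosis_cluster_counts.tsv")


def composition_chi_square(composition: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute the chi-square statistic for every bundled composition row."""
    if composition is None:
        composition = load_cluster_composition()
    rows = []
    for _, row in composition.iterrows():
        table = np.array(
            [
                [row["low_below"], row["low_within"], row["low_above"]],
                [row["high_below"], row["high_within"], row["high_above"]],
            ]
        )
        res = chi_square(table)
        rows.append(
            {
                "method": row["method"],
                "item": row["item"],
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "published_statistic": row["published_chi2"],
            }
        )
    return pd.DataFrame(rows)
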