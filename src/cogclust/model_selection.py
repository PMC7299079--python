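"""Choosing the number of clusters by consecutive fit-index change.

Candidate solutions at k = 1..k_max are compared through the *improvement*
between adjacent solutions: for the information criteria the improvement at
k is AIC_{k-1} - AIC_k (lower criterion = better fit, so a positive change
is an improvement), for relative entropy it is entropy_k - entropy_{k-1}
(higher = cleaner classification). With k_max = 4 this yields three labelled
changes per index — "2vs1", "3vs2", "4vs3". Each index votes for the k with
its strongest improvement (ties go to the smaller k, the parsimony rule);
the chosen k is the majority vote across BIC, AIC and entropy, again
breaking full disagreement toward the smallest candidate. When no index
improves anywhere the one-cluster solution stands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .base import ClusterSolution, FitIndices

INDEX_NAMES = ("bic", "aic", "entropy")


@dataclass
class FitIndexPath:
    """Per-k fit indices for one method plus consecutive improvements."""

    method: str
    indices: dict[int, FitIndices]
    changes: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def k_values(self) -> list[int]:
        return sorted(self.indices)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "indices": {str(k): fi.to_dict() for k, fi in sorted(self.indices.items())},
            "changes": self.changes,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, payload: dict) -> "FitIndexPath":
        indices = {int(k): FitIndices(**v) for k, v in payload["indices"].items()}
        return cls(method=payload["method"], indices=indices, changes=payload["changes"])

    @classmethod
    def from_json(cls, path: str | Path) -> "FitIndexPath":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SelectionResult:
    """Outcome of the consecutive-change rule."""

    method: str
    chosen_k: int
    winners: dict[str, int]  # index name -> k with the strongest improvement
    votes: dict[int, int]  # k -> number of indices voting for it
    rationale: str

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "chosen_k": self.chosen_k,
            "winners": self.winners,
            "votes": {str(k): v for k, v in self.votes.items()},
            "rationale": self.rationale,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def index_path(solutions: dict[int, ClusterSolution | FitIndices], method: str | None = None) -> FitIndexPath:
    """Build the consecutive-change table from per-k solutions.

    ``solutions`` must cover a contiguous k range starting at 1. Values may
    be :class:`ClusterSolution` or bare :class:`FitIndices`.
    """
    ks = sorted(solutions)
    if not ks or ks[0] != 1 or ks != list(range(1, ks[-1] + 1)):
        raise ValueError(f"solutions must cover k = 1..k_max without gaps, got {ks}")
    indices: dict[int, FitIndices] = {}
    for k in ks:
        sol = solutions[k]
        if isinstance(sol, ClusterSolution):
            if method is None:
                method = sol.method
            indices[k] = sol.fit
        else:
            indices[k] = sol
    changes: dict[str, dict[str, float]] = {name: {} for name in INDEX_NAMES}
    for k in ks[1:]:
        label = f"{k}vs{k - 1}"
        changes["bic"][label] = indices[k - 1].bic - indices[k].bic
        changes["aic"][label] = indices[k - 1].aic - indices[k].aic
        changes["entropy"][label] = indices[k].entropy - indices[k - 1].entropy
    return FitIndexPath(method=method or "unknown", indices=indices, changes=changes)


def select_best(path: FitIndexPath) -> SelectionResult:
    """Apply the strongest-change / parsimony rule to a fit-index path.

    Per index the winning k maximises the improvement (ties -> smaller k);
    the overall choice is the majority vote, a full three-way disagreement
    resolving to the smallest winning k. If no index improves at any k the
    one-cluster solution is chosen.
    """
    ks = path.k_values
    if len(ks) < 2:
        return SelectionResult(
            method=path.method,
            chosen_k=1,
            winners={},
            votes={},
            rationale="single solution available; k = 1",
        )
    winners: dict[str, int] = {}
    any_improvement = False
    for name in INDEX_NAMES:
        deltas = [(k, path.changes[name][f"{k}vs{k - 1}"]) for k in ks[1:]]
        best_k, best_delta = deltas[0]
        for k, delta in deltas[1:]:
            if delta > best_delta:  # strict: ties keep the smaller k
                best_k, best_delta = k, delta
        winners[name] = best_k
        if best_delta > 0:
            any_improvement = True

    if not any_improvement:
        return SelectionResult(
            method=path.method,
            chosen_k=1,
            winners=winners,
            votes={},
            rationale="no index improves at any k; keeping the one-cluster solution",
        )

    votes: dict[int, int] = {}
    for k in winners.values():
        votes[k] = votes.get(k, 0) + 1
    top = max(votes.values())
    chosen_k = min(k for k, v in votes.items() if v == top)
    detail = ", ".join(f"{name} -> k={winners[name]}" for name in INDEX_NAMES)
    rationale = (
        f"strongest consecutive change per index: {detail}; "
        f"majority vote (parsimony on ties) -> k={chosen_k}"
    )
    return SelectionResult(
        method=path.method,
        chosen_k=chosen_k,
        winners=winners,
        votes=votes,
        rationale=rationale,
    )


def changes_table(paths: list[FitIndexPath]) -> "pd.DataFrame":
    """Long-format table of index changes, one row per (method, index, step)."""
    import pandas as pd

    rows = []
    for p in paths:
        for name in INDEX_NAMES:
            for label, value in p.changes[name].items():
                rows.append(
                    {"method": p.method, "index": name, "step": label, "change": value}
                )
    return pd.DataFrame(rows, columns=["method", "index", "step", "change"])
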