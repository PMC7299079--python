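"""Normative standardization and three-band categorization of raw test scores.

Raw neuropsychological scores live on test-specific scales, so they are first
standardized against published norms, z = (x - mu) / sigma, and then banded at
the 10th and 90th normative percentiles (z = -1.3 and z = +1.3) into the three
performance levels used by the clustering stages.

Tests scored in time or errors run the "wrong way" (higher raw score = worse
performance); each normative entry therefore carries a ``direction`` flag and
z is negated for ``lower_is_better`` tests so that, after standardization,
larger z always means better performance and ``below`` always means deficit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .base import (
    LEVELS,
    InvalidReferenceError,
    ReferenceMissingError,
    decode_levels,
)

#: z cutpoints: below the 10th percentile / at-or-above the 90th percentile.
DEFICIT_CUT: float = -1.3
SUPERIOR_CUT: float = 1.3

DIRECTIONS = ("higher_is_better", "lower_is_better")


@dataclass(frozen=True)
class NormativeEntry:
    """Normative mean/SD and scoring direction for one test."""

    test_id: str
    mu: float
    sigma: float
    direction: str = "higher_is_better"

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise InvalidReferenceError(
                f"test {self.test_id!r}: sigma must be > 0, got {self.sigma}"
            )
        if self.direction not in DIRECTIONS:
            raise InvalidReferenceError(
                f"test {self.test_id!r}: direction must be one of {DIRECTIONS}"
            )


class NormativeReference:
    """Per-test normative parameters: mean, SD and scoring direction."""

    def __init__(self, entries: Iterable[NormativeEntry | Mapping]) -> None:
        parsed = [
            e if isinstance(e, NormativeEntry) else NormativeEntry(**e) for e in entries
        ]
        self._entries: dict[str, NormativeEntry] = {}
        for e in parsed:
            if e.test_id in self._entries:
                raise InvalidReferenceError(f"duplicate reference for {e.test_id!r}")
            self._entries[e.test_id] = e

    def __getitem__(self, test_id: str) -> NormativeEntry:
        try:
            return self._entries[test_id]
        except KeyError:
            raise ReferenceMissingError(
                f"no normative reference for test {test_id!r}"
            ) from None

    def __contains__(self, test_id: str) -> bool:
        return test_id in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def test_ids(self) -> list[str]:
        return list(self._entries)

    def to_records(self) -> list[dict]:
        return [
            {"test_id": e.test_id, "mu": e.mu, "sigma": e.sigma, "direction": e.direction}
            for e in self
        ]

    @classmethod
    def from_file(cls, path: str | Path) -> "NormativeReference":
        """Load from a JSON or YAML list of {test_id, mu, sigma, direction}."""
        path = Path(path)
        text = path.read_text()
        records = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
        return cls(records)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        records = self.to_records()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(records, indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(records, sort_keys=True))


def standardize(raw: pd.DataFrame, reference: NormativeReference) -> pd.DataFrame:
    """Convert raw scores to normative z-scores oriented larger = better.

    Parameters
    ----------
    raw : DataFrame
        Subjects x tests raw scores; NaN marks a missing administration.
    reference : NormativeReference
        Must contain a row for every column of ``raw``.

    Returns
    -------
    DataFrame of z-scores with the same shape; missing cells propagate.
    """
    z = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for test_id in raw.columns:
        entry = reference[test_id]
        col = pd.to_numeric(raw[test_id], errors="coerce")
        scores = (col - entry.mu) / entry.sigma
        if entry.direction == "lower_is_better":
            scores = -scores
        z[test_id] = scores
    return z


def categorize(z: pd.DataFrame) -> pd.DataFrame:
    """Band oriented z-scores into below / within / above performance levels.

    The bands are half-open: z < -1.3 -> below; -1.3 <= z < 1.3 -> within;
    z >= 1.3 -> above. NaN propagates.
    """
    values = z.to_numpy(dtype=float)
    codes = np.full(values.shape, -1, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        codes[values < DEFICIT_CUT] = 0
        codes[(values >= DEFICIT_CUT) & (values < SUPERIOR_CUT)] = 1
        codes[values >= SUPERIOR_CUT] = 2
    return decode_levels(codes, z.index, z.columns)


class NormativeBander(TransformerMixin, BaseEstimator):
    """Transformer mapping raw scores to three-level normative bands.

    Parameters
    ----------
    reference : NormativeReference or list of records or path
        Normative mean/SD/direction per test.

    Attributes
    ----------
    reference_ : NormativeReference
        Validated reference used by :meth:`transform`.
    """

    def __init__(self, reference=None):
        self.reference = reference

    def _resolve_reference(self) -> NormativeReference:
        ref = self.reference
        if isinstance(ref, NormativeReference):
            return ref
        if isinstance(ref, (str, Path)):
            return NormativeReference.from_file(ref)
        if ref is None:
            raise InvalidReferenceError("a normative reference is required")
        return NormativeReference(ref)

    def fit(self, X: pd.DataFrame, y=None):
        self.reference_ = self._resolve_reference()
        missing = [c for c in X.columns if c not in self.reference_]
        if missing:
            raise ReferenceMissingError(f"no normative reference for tests {missing}")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "reference_"):
            raise RuntimeError("NormativeBander must be fitted before transform")
        return categorize(standardize(X, self.reference_))


def read_raw_scores(path: str | Path) -> pd.DataFrame:
    """Read a subjects x tests raw-score CSV (subject id in the first column)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return df


def read_profiles(
    path: str | Path, strata_col: str | None = None
) -> pd.DataFrame | tuple[pd.DataFrame, pd.Series]:
    """Read a subjects x items level CSV; validates the level vocabulary.

    With ``strata_col`` the named column is split off (before validation)
    and returned alongside the profile table.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    strata = df.pop(strata_col) if strata_col is not None else None
    bad = set(df.stack().unique()) - set(LEVELS)
    if bad:
        raise ValueError(f"unexpected level values in {path}: {sorted(bad)}")
    return (df, strata) if strata_col is not None else df


def write_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.to_csv(path, index_label="subject_id")
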