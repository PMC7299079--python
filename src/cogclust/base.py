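"""Shared containers and level coding for banded cognitive profiles.

Profiles are subjects x items tables whose cells take one of three ordinal
performance levels relative to a normative sample:

* ``below``  — deficit (z < -1.3, below the 10th percentile),
* ``within`` — normal range (-1.3 <= z < 1.3),
* ``above``  — superior (z >= 1.3, at or above the 90th percentile).

Internally levels are coded as int8 {0, 1, 2}; missing cells are -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: Ordinal performance levels, worst to best.
LEVELS: tuple[str, ...] = ("below", "within", "above")

#: Number of levels per item (fixed three-band coding).
N_LEVELS: int = len(LEVELS)

_LEVEL_CODE: Mapping[str, int] = {name: i for i, name in enumerate(LEVELS)}


class ReferenceMissingError(KeyError):
    """A test in the score matrix has no row in the normative reference."""


class InvalidReferenceError(ValueError):
    """A normative reference row is unusable (e.g. sigma <= 0)."""


class DegenerateModelError(ValueError):
    """More latent classes requested than distinct observed response patterns."""


def encode_levels(profiles: pd.DataFrame) -> np.ndarray:
    """Encode a subjects x items level table as an int8 array.

    Parameters
    ----------
    profiles : DataFrame
        Cells are "below" / "within" / "above"; NaN marks a missing score.

    Returns
    -------
    ndarray of shape (n_subjects, n_items), int8, missing coded -1.
    """
    arr = np.full(profiles.shape, -1, dtype=np.int8)
    values = profiles.to_numpy(dtype=object)
    for name, code in _LEVEL_CODE.items():
        arr[values == name] = code
    bad = (arr == -1) & ~pd.isna(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"unrecognised level {values[i, j]!r} at subject "
            f"{profiles.index[i]!r}, item {profiles.columns[j]!r}"
        )
    return arr


def decode_levels(
    codes: np.ndarray, index, columns, *, dtype: str = "object"
) -> pd.DataFrame:
    """Inverse of :func:`encode_levels`; -1 decodes to NaN."""
    values = np.full(codes.shape, np.nan, dtype=object)
    for name, code in _LEVEL_CODE.items():
        values[codes == code] = name
    return pd.DataFrame(values, index=index, columns=columns, dtype=dtype)


@dataclass(frozen=True)
class FitIndices:
    """Goodness-of-fit summary attached to a clustering solution.

    AIC = -2 loglik + 2 q and BIC = -2 loglik + q ln(n); ``entropy`` is the
    relative entropy of the (soft) assignment in [0, 1], 1 meaning perfectly
    certain classification.
    """

    loglik: float
    aic: float
    bic: float
    entropy: float

    def to_dict(self) -> dict[str, float]:
        return {
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "entropy": self.entropy,
        }

    @classmethod
    def from_loglik(cls, loglik: float, q: int, n: int, entropy: float) -> "FitIndices":
        return cls(
            loglik=float(loglik),
            aic=-2.0 * loglik + 2.0 * q,
            bic=-2.0 * loglik + q * float(np.log(n)),
            entropy=float(entropy),
        )


@dataclass
class ClusterSolution:
    """A hard partition of subjects produced by one method at one k.

    ``assignment`` maps subject id -> cluster label in {1..k}; ``fit`` holds
    the per-solution information criteria used by model selection.
    """

    method: str
    k: int
    assignment: pd.Series
    fit: FitIndices
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = set(self.assignment.unique())
        if not labels <= set(range(1, self.k + 1)):
            raise ValueError(f"labels {labels} outside 1..{self.k}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.assignment.index, "cluster": self.assignment.values}
        )
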