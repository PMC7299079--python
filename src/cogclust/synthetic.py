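"""Synthetic cognitive batteries with a known latent-class structure.

The generator draws, per subject, a latent class from the configured
prevalences (optionally via a diagnosis stratum with stratum-specific class
probabilities) and then, given the class, each item's three-level response
independently from its class-conditional distribution — exactly the
local-independence mixture the latent-class model assumes. Missingness, when
requested, is completely at random. A raw-score layer can be emitted on top
of the levels so the standardization/banding stage is exercisable end to
end: each level maps back to a uniform z draw inside its band, inverted
through the normative reference.

The default preset reproduces the study conditions of a published
cross-diagnostic inpatient cohort (N = 387): two classes with prevalences
184/387 (Low profile) and 203/387 (High profile) over 10 executive-function
items, the class-conditional level probabilities set to the published
within-cluster percentage composition of the latent-class solution
(renormalised to sum to 1 per item), and optional diagnosis strata (BD, DD,
PD, SZ) with the published class-by-diagnosis mixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .base import LEVELS, N_LEVELS, decode_levels
from .preprocess import DEFICIT_CUT, SUPERIOR_CUT, NormativeEntry, NormativeReference

#: z band edges used when emitting raw scores: below [-3, -1.3), within
#: [-1.3, 1.3), above [1.3, 3].
Z_BANDS = ((-3.0, DEFICIT_CUT), (DEFICIT_CUT, SUPERIOR_CUT), (SUPERIOR_CUT, 3.0))

ITEM_IDS = (
    "MCST_categories",
    "MCST_errors",
    "CPM47",
    "AM",
    "ToL_rule_violations",
    "ToL_correct_moves",
    "ToL_time_violations",
    "ToL_total_moves",
    "STROOP_time",
    "STROOP_errors",
)

# Published latent-class within-cluster composition (percent below/within/
# above per item) of the N = 387 cohort; class 0 = Low profile (n = 184),
# class 1 = High profile (n = 203). Rows are renormalised at load time.
_COHORT_PCT = {
    "MCST_categories": ((38, 36, 26), (3, 14, 83)),
    "MCST_errors": ((33, 45, 22), (4, 30, 66)),
    "CPM47": ((34, 50, 16), (3, 29, 68)),
    "AM": ((49, 31, 20), (9, 35, 56)),
    "ToL_rule_violations": ((85, 14, 1), (37, 56, 7)),
    "ToL_correct_moves": ((26, 71, 4), (7, 69, 24)),
    "ToL_time_violations": ((75, 24, 1), (35, 61, 4)),
    "ToL_total_moves": ((64, 34, 2), (22, 63, 15)),
    "STROOP_time": ((59, 22, 19), (21, 44, 35)),
    "STROOP_errors": ((36, 32, 33), (9, 41, 50)),
}

_COHORT_PREVALENCES = (184 / 387, 203 / 387)

# Published per-diagnosis (Low, High) cluster counts of the latent-class
# solution; converted to P(class | diagnosis) and diagnosis marginals.
_COHORT_STRATA = {
    "BD": (73, 61),
    "DD": (26, 67),
    "PD": (19, 31),
    "SZ": (66, 44),
}


@dataclass
class GeneratorConfig:
    """Parameters of the latent-class sampling model.

    Attributes
    ----------
    n_subjects : int
    prevalences : ndarray (R,) — class mixing proportions
    response_probs : ndarray (J, R, K) — class-conditional level probabilities
    item_ids : list of str
    stratum_probs : dict or None — stratum -> marginal probability
    stratum_mixing : dict or None — stratum -> class-probability vector
    missing_rate : float — probability a cell is masked, MCAR
    seed : int — mandatory; all randomness flows from it
    """

    n_subjects: int
    prevalences: np.ndarray
    response_probs: np.ndarray
    item_ids: list[str]
    seed: int
    stratum_probs: dict[str, float] | None = None
    stratum_mixing: dict[str, np.ndarray] | None = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        self.prevalences = np.asarray(self.prevalences, dtype=float)
        self.prevalences = self.prevalences / self.prevalences.sum()
        self.response_probs = np.asarray(self.response_probs, dtype=float)
        J, R, K = self.response_probs.shape
        if R != self.prevalences.size or K != N_LEVELS or J != len(self.item_ids):
            raise ValueError("response_probs shape does not match items/classes")
        if (self.response_probs < 0).any():
            raise ValueError("negative response probability")
        self.response_probs = self.response_probs / self.response_probs.sum(
            axis=2, keepdims=True
        )
        if (self.stratum_probs is None) != (self.stratum_mixing is None):
            raise ValueError("stratum_probs and stratum_mixing go together")
        if self.stratum_mixing is not None:
            total = sum(self.stratum_probs.values())
            self.stratum_probs = {s: p / total for s, p in self.stratum_probs.items()}
            self.stratum_mixing = {
                s: np.asarray(v, dtype=float) / np.sum(v)
                for s, v in self.stratum_mixing.items()
            }

    @property
    def n_classes(self) -> int:
        return self.prevalences.size

    def to_dict(self) -> dict:
        out = {
            "n_subjects": self.n_subjects,
            "prevalences": self.prevalences.tolist(),
            "response_probs": {
                item: self.response_probs[j].tolist()
                for j, item in enumerate(self.item_ids)
            },
            "item_ids": list(self.item_ids),
            "missing_rate": self.missing_rate,
            "seed": self.seed,
        }
        if self.stratum_mixing is not None:
            out["stratum_probs"] = dict(self.stratum_probs)
            out["stratum_mixing"] = {
                s: v.tolist() for s, v in self.stratum_mixing.items()
            }
        return out

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, payload: dict) -> "GeneratorConfig":
        items = list(payload["item_ids"])
        pi = np.array([payload["response_probs"][item] for item in items])
        return cls(
            n_subjects=payload["n_subjects"],
            prevalences=np.asarray(payload["prevalences"], dtype=float),
            response_probs=pi,
            item_ids=items,
            seed=payload["seed"],
            stratum_probs=payload.get("stratum_probs"),
            stratum_mixing=(
                {s: np.asarray(v) for s, v in payload["stratum_mixing"].items()}
                if "stratum_mixing" in payload
                else None
            ),
            missing_rate=payload.get("missing_rate", 0.0),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class LabeledSample:
    """A generated cohort: level profiles plus ground truth."""

    profiles: pd.DataFrame
    true_class: pd.Series  # labels 1..R
    stratum: pd.Series | None = None

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.profiles.to_csv(directory / "profiles.csv", index_label="subject_id")
        truth = pd.DataFrame({"true_class": self.true_class})
        if self.stratum is not None:
            truth["stratum"] = self.stratum
        truth.to_csv(directory / "truth.tsv", sep="\t", index_label="subject_id")


def cohort_preset(
    n_subjects: int = 387,
    seed: int = 0,
    with_strata: bool = False,
    missing_rate: float = 0.0,
) -> GeneratorConfig:
    """The two-class, 10-item cohort preset (see module docstring).

    With ``with_strata`` the four diagnosis strata (BD, DD, PD, SZ) are
    sampled at their cohort proportions and the class is drawn from the
    published class-by-diagnosis mixing instead of the marginal prevalences.
    """
    pi = np.array(
        [[_COHORT_PCT[item][r] for r in range(2)] for item in ITEM_IDS], dtype=float
    )
    stratum_probs = stratum_mixing = None
    if with_strata:
        total = sum(sum(v) for v in _COHORT_STRATA.values())
        stratum_probs = {s: sum(v) / total for s, v in _COHORT_STRATA.items()}
        stratum_mixing = {
            s: np.array(v, dtype=float) / sum(v) for s, v in _COHORT_STRATA.items()
        }
    return GeneratorConfig(
        n_subjects=n_subjects,
        prevalences=np.array(_COHORT_PREVALENCES),
        response_probs=pi,
        item_ids=list(ITEM_IDS),
        seed=seed,
        stratum_probs=stratum_probs,
        stratum_mixing=stratum_mixing,
        missing_rate=missing_rate,
    )


def generate(config: GeneratorConfig) -> LabeledSample:
    """Draw a cohort from the configured latent-class model.

    Fully reproducible: the same config (including seed) yields a
    byte-identical sample.
    """
    rng = np.random.default_rng(config.seed)
    n, R = config.n_subjects, config.n_classes
    J = len(config.item_ids)

    stratum = None
    if config.stratum_mixing is not None:
        names = sorted(config.stratum_probs)
        probs = np.array([config.stratum_probs[s] for s in names])
        stratum_idx = rng.choice(len(names), size=n, p=probs)
        mixing = np.stack([config.stratum_mixing[s] for s in names])
        classes = np.empty(n, dtype=int)
        for i in range(n):
            classes[i] = rng.choice(R, p=mixing[stratum_idx[i]])
        stratum = pd.Series(
            [names[i] for i in stratum_idx], name="stratum"
        )
    else:
        classes = rng.choice(R, size=n, p=config.prevalences)

    codes = np.empty((n, J), dtype=np.int8)
    for j in range(J):
        cum = config.response_probs[j].cumsum(axis=1)  # (R, K)
        u = rng.random(n)
        codes[:, j] = (u[:, None] > cum[classes]).sum(axis=1)

    if config.missing_rate > 0:
        mask = rng.random((n, J)) < config.missing_rate
        codes[mask] = -1

    subject_ids = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="subject_id")
    profiles = decode_levels(codes, subject_ids, list(config.item_ids))
    true_class = pd.Series(classes + 1, index=subject_ids, name="true_class")
    if stratum is not None:
        stratum.index = subject_ids
    return LabeledSample(profiles=profiles, true_class=true_class, stratum=stratum)


def default_norms(item_ids=ITEM_IDS) -> NormativeReference:
    """A plausible normative reference for the preset battery.

    Accuracy-type scores get mu = 50, sigma = 10 with higher_is_better;
    time/error subscales are scored lower_is_better on the same scale, so the
    direction flip is exercised.
    """
    lower_is_better = {
        "MCST_errors",
        "ToL_rule_violations",
        "ToL_time_violations",
        "ToL_total_moves",
        "STROOP_time",
        "STROOP_errors",
    }
    return NormativeReference(
        NormativeEntry(
            test_id=item,
            mu=50.0,
            sigma=10.0,
            direction=(
                "lower_is_better" if item in lower_is_better else "higher_is_better"
            ),
        )
        for item in item_ids
    )


def emit_raw_scores(
    sample: LabeledSample, reference: NormativeReference, seed: int
) -> pd.DataFrame:
    """Raw-score layer consistent with the sampled levels.

    For every observed cell an oriented z is drawn uniformly inside its
    level's band and inverted through the standardization (including the
    direction flip), so banding the emitted scores reproduces the sample's
    levels exactly.
    """
    rng = np.random.default_rng(seed)
    profiles = sample.profiles
    raw = pd.DataFrame(index=profiles.index, columns=profiles.columns, dtype=float)
    level_code = {name: i for i, name in enumerate(LEVELS)}
    for item in profiles.columns:
        entry = reference[item]
        col = profiles[item]
        out = np.full(len(col), np.nan)
        for name, code in level_code.items():
            mask = (col == name).to_numpy()
            if not mask.any():
                continue
            lo, hi = Z_BANDS[code]
            z = rng.uniform(lo, hi, size=int(mask.sum()))
            if entry.direction == "lower_is_better":
                z = -z
            out[mask] = entry.mu + z * entry.sigma
        raw[item] = out
    return raw
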