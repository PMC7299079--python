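import numpy as np
import pandas as pd
import pytest

from cogclust.base import decode_levels
from cogclust.synthetic import cohort_preset, generate


def profiles_from_codes(codes, prefix="s"):
    """Wrap an integer level-code array as a level DataFrame (-1 = missing)."""
    codes = np.asarray(codes, dtype=np.int8)
    n, J = codes.shape
    return decode_levels(
        codes,
        [f"{prefix}{i:03d}" for i in range(n)],
        [f"item_{j + 1}" for j in range(J)],
    )


@pytest.fixture(scope="session")
def cohort_sample():
    """One synthetic cohort at the study scale (N = 387, no missingness)."""
    return generate(cohort_preset(seed=0))


@pytest.fixture(scope="session")
def two_block_profiles():
    """20 all-below and 20 all-above subjects over 4 items: two clean blocks."""
    codes = np.vstack([np.zeros((20, 4)), np.full((20, 4), 2)])
    return profiles_from_codes(codes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
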