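import numpy as np
import pytest

from radfuse.cohort import CohortSpec
from radfuse.cohort import generate_feature_tables


def half_cohort_spec(seed: int = 0, **kwargs) -> CohortSpec:
    """Half-size cohort with the default class proportions (168/38/27)."""
    defaults = dict(n_per_class={"HR+": 168, "HEBC": 38, "TNBC": 27}, test_size=60)
    defaults.update(kwargs)
    return CohortSpec(seed=seed, **defaults)


@pytest.fixture(scope="session")
def half_tables():
    """Feature-mode tables of the half-size default cohort (seed 0)."""
    return generate_feature_tables(half_cohort_spec(0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
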