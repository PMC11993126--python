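import numpy as np
import pytest

from photopheno.stimulus import default_device


@pytest.fixture(scope="session")
def device():
    """The standard-protocol device model (background solved once)."""
    return default_device()


@pytest.fixture(scope="session")
def study_scale_cohort_md():
    """One n=200 cohort taken through measurement and metrics (fast path)."""
    from photopheno.cohort import generate_cohort, measure_cohort
    from photopheno.metrics import cohort_md_profiles

    dev = default_device()
    obs = generate_cohort(group_sizes={"normal": 36, "RP": 64, "STGD": 56, "OMD": 44},
                          seed=424242)
    raw = measure_cohort(obs, dev.max_contrasts, seed=424243, method="ideal")
    return cohort_md_profiles(raw)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
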