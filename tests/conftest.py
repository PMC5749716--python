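import numpy as np
import pytest

from retestkit import SyntheticCohortConfig, simulate_cohort, single_stratum_config


@pytest.fixture(scope="session")
def default_cohort():
    """A full default synthetic test-retest cohort (8 young + 8 elderly)."""
    return simulate_cohort(SyntheticCohortConfig(seed=42))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Retest identical to test: zero error, zero bias, one stratum."""
    cfg = single_stratum_config(sigma_between=5.0, sigma_error=0.0, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
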