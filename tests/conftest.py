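import pytest

from wristgait.pipeline import windowed_dataset
from wristgait.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """30 single-day subjects with default noise — shared across tests."""
    return simulate_cohort(30, CohortConfig.training(), seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    """Window tensor + label table for the shared cohort."""
    X, meta = windowed_dataset(small_cohort)
    return X, meta


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Small cohort with sensor noise off: the swing-speed coupling is exact."""
    cfg = CohortConfig.training(noise_sd_g=0.0)
    cohort = simulate_cohort(16, cfg, seed=7)
    X, meta = windowed_dataset(cohort)
    return X, meta
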