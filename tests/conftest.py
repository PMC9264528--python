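import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lfqimpute import AbundanceMatrix, SyntheticConfig, generate_complete_dataset

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("det")


def make_matrix(values, scale_tag="log"):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    return AbundanceMatrix([f"P{i}" for i in range(p)],
                           [f"S{j}" for j in range(n)], values, scale_tag)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """60 proteins x 30 samples, correlated blocks — complete log matrix."""
    cfg = SyntheticConfig(n_samples=30, n_proteins=60,
                          block_sizes=(10,) * 6, seed=7)
    return generate_complete_dataset(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    """The full-size study twin: 296 proteins x 45 samples."""
    return generate_complete_dataset(SyntheticConfig(seed=11))
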