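import numpy as np
import pytest

from simclass.simdata import SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small well-separated dataset reused across learner/evaluate tests."""
    config = SimConfig(
        n=60, p=5, sigma_b=0.5, sigma_e=0.5, r=1, theta_min=4.0,
        corr_kind="independent", seed=42,
    )
    return simulate_dataset(config)
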