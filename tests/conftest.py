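import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_acq():
    from oxirelax import AcquisitionConfig
    return AcquisitionConfig(tau=4.0e-4, n_echoes=256, noise_sigma=0.0)


@pytest.fixture(scope="session")
def tiny_records():
    """A small seeded labeled dataset shared across tests."""
    from oxirelax import AcquisitionConfig, generate_dataset
    acq = AcquisitionConfig(n_echoes=512, noise_sigma=0.01)
    return generate_dataset(60, (1 / 3, 1 / 3, 1 / 3), acq, seed=99)
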