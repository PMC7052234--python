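import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sflimfret import InstrumentConfig, default_config, gaussian_irf

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config():
    """Reference instrument configuration (40 MHz PIE, 8 channels, 1024 bins)."""
    return default_config()


@pytest.fixture(scope="session")
def irf(config):
    return gaussian_irf(config)


@pytest.fixture(scope="session")
def small_config():
    """Cheap configuration for simulation-heavy tests (256 TCSPC bins)."""
    return InstrumentConfig(n_tcspc=256)


@pytest.fixture(scope="session")
def small_irf(small_config):
    return gaussian_irf(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
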