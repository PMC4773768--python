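import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from demyelin import default_config

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config():
    """Packaged default model configuration."""
    return default_config()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
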