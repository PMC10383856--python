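import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def grid():
    """Standard 5-200 cm^-1 grid at 0.5 cm^-1 steps."""
    from lframan.synthetic_data import default_grid

    return default_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(2023)
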