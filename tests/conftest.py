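import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from coopgate import ModelParams

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


class ScriptedRng:
    """Stand-in random stream returning a preset sequence of uniforms."""

    def __init__(self, values):
        self._values = list(values)

    def random(self):
        return self._values.pop(0)


@pytest.fixture
def scripted_rng():
    return ScriptedRng


@pytest.fixture(scope="session")
def quick_params():
    """Small, fast parameter set for structural tests."""
    return ModelParams(n_channels=2, n_dwells=300, timescale_ratio=50,
                       b_max=6, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
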