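import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lipidtiers.nomenclature import default_registry
from lipidtiers.panel import load_is_map, load_panel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def is_map():
    return load_is_map()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
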