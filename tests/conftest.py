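import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from densescreen import ParameterSet, generate_cohort, generate_life_table
from densescreen.screening import scenario_presets

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def life_table():
    return generate_life_table()


@pytest.fixture(scope="session")
def presets():
    return scenario_presets()


@pytest.fixture(scope="session")
def small_cohort(params, life_table):
    """2,000 women, enough signal for structural checks, fast."""
    return generate_cohort(2_000, 42, params, life_table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
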