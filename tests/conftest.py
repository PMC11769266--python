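import numpy as np
import pytest
from hypothesis import settings

from canopy_yield.grid import GridSpec
from canopy_yield.synthetic import ScenarioConfig, generate_field

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale two-stage scenario used across the suite."""
    return ScenarioConfig(
        seed=7,
        grid=GridSpec(100, 100, 1.0),
        n_stages=2,
        canopy_cover_by_stage=(0.4, 0.6),
        stage_labels=("V9", "V14/VT"),
        daps=(64, 83),
    )


@pytest.fixture(scope="session")
def small_field(small_config):
    return generate_field(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
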