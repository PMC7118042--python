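import numpy as np
import pytest

from wqbench.synthetic_data import (
    HOURS_3_YEARS,
    generate_population,
    preset_scenario,
)


@pytest.fixture(scope="session")
def good_pop():
    """A 3-year hourly population from the good-near-boundary preset."""
    return generate_population(
        preset_scenario("good_near_boundary").spec, HOURS_3_YEARS, seed=101
    )


@pytest.fixture(scope="session")
def moderate_pop():
    return generate_population(
        preset_scenario("moderate_far").spec, HOURS_3_YEARS, seed=202
    )


@pytest.fixture(scope="session")
def lognormal_sample36():
    """A fixed surveillance-monitoring-sized sample from LogN(-3.5, 0.8)."""
    rng = np.random.default_rng(42)
    return rng.lognormal(-3.5, 0.8, 36)
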