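import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def life_tables():
    from tempyll.life_table import synthetic_life_table

    return synthetic_life_table(2010), synthetic_life_table(2019)


@pytest.fixture(scope="session")
def city_2yr():
    """One simulated city over a 2-year window (fast first-stage fits)."""
    from tempyll.synthetic import SimulationConfig, simulate_city_series

    return simulate_city_series(SimulationConfig(end="2015-12-31"), seed=11)


@pytest.fixture(scope="session")
def city_full():
    """One simulated city over the full 2557-day window."""
    from tempyll.synthetic import simulate_city_series

    return simulate_city_series(seed=7)


@pytest.fixture(scope="session")
def fitted_city_full(city_full):
    from tempyll.first_stage import fit_city

    series, truth = city_full
    fit, assoc, cb = fit_city(series)
    return series, truth, fit, assoc, cb
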