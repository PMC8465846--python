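import datetime as dt

import numpy as np
import pandas as pd
import pytest

from heterowheat.data import TrialMeta, WeatherSeries
from heterowheat.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic trial shared by read-only tests."""
    return simulate(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Trial with no NDVI noise; plot-level trait noise still on."""
    return simulate(SimulationConfig(seed=7, ndvi_noise_sd=0.0))


def constant_weather(location: str = "L1", days: int = 301,
                     start: dt.date = dt.date(2019, 10, 1),
                     tmin: float = 10.0, tmax: float = 10.0) -> WeatherSeries:
    rows = [{"date": start + dt.timedelta(days=i), "tmin": tmin, "tmax": tmax,
             "rainfall": 0.0} for i in range(days)]
    return WeatherSeries(location, pd.DataFrame(rows))


@pytest.fixture
def flat_weather():
    return constant_weather()


@pytest.fixture
def flat_meta():
    return TrialMeta("L1", 48.0, 2.0, 12.0, dt.date(2019, 10, 1),
                     dt.date(2020, 7, 8))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
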