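import numpy as np
import pandas as pd
import pytest

from phenodd import ClimateScenario, GridSpec, Region, TemperatureGrid, simulate_temperature


@pytest.fixture
def small_spec():
    return GridSpec(origin_lon=10.0, origin_lat=55.0, n_lon=3, n_lat=2)


@pytest.fixture
def small_region(small_spec):
    return Region(name="toy", cells=frozenset(small_spec.all_cells()))


@pytest.fixture
def constant_grid(small_spec):
    """Two years of constant tmax=tmin=6.5 °C everywhere."""
    dates = pd.date_range("2003-01-01", "2004-12-31", freq="D")
    shape = (len(dates), small_spec.n_lat, small_spec.n_lon)
    return TemperatureGrid(
        spec=small_spec,
        dates=dates,
        tmax=np.full(shape, 6.5),
        tmin=np.full(shape, 6.5),
    )


@pytest.fixture
def seasonal_grid(small_spec):
    """A mild-noise seasonal climate, 2003-2006."""
    scenario = ClimateScenario(
        annual_mean=6.9, daily_noise_sd=1.0, year_anomaly_sd=0.5,
        years=range(2003, 2007), seed=123,
    )
    return simulate_temperature(scenario, small_spec)
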