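import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from airhia.synthetic import GeneratorConfig, PollutantSignal
from airhia.exposure import Pollutant

settings.register_profile(
    "derandomized", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("derandomized")


def hourly_index(n_days: int = 3, start: str = "2015-03-01") -> pd.DatetimeIndex:
    return pd.date_range(start, periods=n_days * 24, freq="h")


@pytest.fixture
def day_index():
    return pd.date_range("2015-03-01", periods=24, freq="h")


@pytest.fixture
def small_config():
    """Two periods, two stations, small noise: fast but structurally complete."""
    return GeneratorConfig(
        seed=11,
        n_stations=2,
        period_labels=("2012-2013", "2013-2014"),
        signals={
            Pollutant.PM25: PollutantSignal(baseline=40.0, station_offsets=(0.0, 4.0)),
            Pollutant.NO2: PollutantSignal(baseline=42.0, station_offsets=(0.0, 3.0)),
            Pollutant.O3: PollutantSignal(baseline=15.0, station_offsets=(0.0, 1.5)),
        },
    )


@pytest.fixture
def noise_free_config():
    """Constant signal, no noise, no gaps: every stage has a closed form."""
    sig = dict(seasonal_amplitude=0.0, diurnal_amplitude=0.0, sigma=0.0, missing_rate=0.0)
    return GeneratorConfig(
        seed=0,
        n_stations=2,
        period_labels=("2012-2013",),
        signals={
            Pollutant.PM25: PollutantSignal(baseline=30.0, station_offsets=(0.0, 0.0), **sig),
            Pollutant.NO2: PollutantSignal(baseline=50.0, station_offsets=(0.0, 0.0), **sig),
            Pollutant.O3: PollutantSignal(baseline=20.0, station_offsets=(0.0, 0.0), **sig),
        },
    )
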