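import datetime as dt

import numpy as np
import pytest

from wheatda.crop_model import (
    CropParams,
    Management,
    SoilProfile,
    WeatherDay,
)


def make_weather(
    seed=0,
    start=dt.date(2018, 10, 1),
    n_days=290,
    rain_prob=0.22,
    rain_depth=5.0,
    temp_noise=1.5,
):
    """Sinusoidal warm-temperate season with Poisson rainfall (test forcing)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_days):
        d = start + dt.timedelta(days=i)
        doy = d.timetuple().tm_yday
        phase = 2 * np.pi * (doy - 15) / 365.25
        t = 13 - 12 * np.cos(phase) + rng.normal(0, temp_noise)
        srad = max(0.5, 16 - 9 * np.cos(phase) + rng.normal(0, 2))
        rain = rain_depth if rng.random() < rain_prob else 0.0
        out.append(WeatherDay(d, t + 4.5, t - 4.5, rain, srad))
    return out


@pytest.fixture(scope="session")
def weather():
    return make_weather()


@pytest.fixture(scope="session")
def soil():
    return SoilProfile()


@pytest.fixture(scope="session")
def params():
    return CropParams()


@pytest.fixture(scope="session")
def irrigated_mgmt():
    events = tuple(
        [(dt.date(2018, 10, 15), 60.0), (dt.date(2018, 11, 20), 60.0)]
        + [(dt.date(2019, 2, 10) + dt.timedelta(days=8 * i), 50.0) for i in range(16)]
    )
    return Management(dt.date(2018, 10, 10), irrigation_events=events)


@pytest.fixture(scope="session")
def rainfed_mgmt():
    return Management(dt.date(2018, 10, 10))
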