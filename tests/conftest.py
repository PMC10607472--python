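from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import onionfly as of
from onionfly.thermal_models import lactin_rate


@pytest.fixture(scope="session")
def table1():
    return of.load_fixture("table1_params")


@pytest.fixture(scope="session")
def table2():
    return of.load_fixture("table2_params")


@pytest.fixture(scope="session")
def jinju_weather():
    return of.generate_synthetic_weather("jinju-like", year=2022, seed=3)


def constant_weather(tmean_air: float, days: int = 200, start: str = "2022-08-01"):
    """A gap-free series with a fixed daily mean air temperature."""
    frame = pd.DataFrame(
        {
            "date": pd.date_range(start, periods=days),
            "tmin": tmean_air - 3.0,
            "tmax": tmean_air + 3.0,
        }
    )
    return of.WeatherSeries(frame)


def mc_emergence_days(t3d, soil, n, seed, config=None):
    """Individual-based Monte Carlo oracle for the two-phase cohort model.

    Each individual draws a diapause-termination threshold and a pupal
    development threshold from the two Weibull distributions (inverse-CDF
    sampling) and advances by the same daily rates as the cohort model:
    phase II progress only from the day after pupation. Returns the day
    index (0-based from the first weather day) of each emergence; -1 for
    individuals still unemerged at the horizon.
    """
    cfg = config or of.SimulationConfig()
    rng = np.random.default_rng(seed)
    a1, b1 = cfg.sdt_dist.alpha, cfg.sdt_dist.beta
    a2, b2 = cfg.pupal_dist.alpha, cfg.pupal_dist.beta
    thr_s = a1 * (-np.log1p(-rng.random(n))) ** (1.0 / b1)
    thr_p = a2 * (-np.log1p(-rng.random(n))) ** (1.0 / b2)
    x = np.zeros(n)
    px = np.zeros(n)
    # 0 = aestivating, 2 = pupal (advancing), 3 = emerged
    state = np.zeros(n, dtype=int)
    emerged_day = np.full(n, -1)
    for i in range(len(soil)):
        rs = lactin_rate(float(t3d[i]), cfg.sdt_rate)
        rp = lactin_rate(float(soil[i]), cfg.pupal_rate)
        pupal = state == 2
        px[pupal] += rp
        done = pupal & (px >= thr_p)
        emerged_day[done] = i
        state[done] = 3
        aest = state == 0
        x[aest] += rs
        new_pupae = aest & (x >= thr_s)
        state[new_pupae] = 1
        state[state == 1] = 2  # advances from tomorrow
    return emerged_day
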