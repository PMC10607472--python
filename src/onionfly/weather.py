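"""Daily weather series: ingestion, soil conversion, synthetic generation.

The emergence model runs on daily mean soil temperatures at pupation depth
(~5 cm). Field inputs are daily minimum/maximum air temperatures; the
air-to-soil conversion is the empirical two-branch offset

    T_soil = T_air + 0.9   if daily mean air < 23.3 °C
    T_soil = T_air + 0.6   otherwise

applied to the daily mean. A synthetic-weather generator produces annual
sinusoidal temperature cycles with configurable summer intensity, standing
in for station data: a "jeju-like" profile sustains more than two months of
soil means above the ~22.1 °C diapause-termination limit, "jinju-like" a
shorter hot spell, and "cool-temperate" essentially none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "DailyWeather",
    "WeatherSeries",
    "WeatherError",
    "SOIL_THRESHOLD",
    "daily_mean",
    "air_to_soil_mean",
    "air_to_soil",
    "moving_average",
    "WEATHER_PROFILES",
    "generate_synthetic_weather",
    "read_weather_csv",
    "write_weather_csv",
]

#: Daily-mean air temperature (°C) above which the soil offset drops
#: from +0.9 to +0.6.
SOIL_THRESHOLD = 23.3


class WeatherError(ValueError):
    """Invalid weather input (non-monotonic dates, gaps, tmin > tmax)."""


class DailyWeather(NamedTuple):
    date: pd.Timestamp
    tmin_air: float
    tmax_air: float


def daily_mean(day: DailyWeather) -> float:
    """Daily mean air temperature: midpoint of min and max."""
    return (day.tmin_air + day.tmax_air) / 2.0


@dataclass(frozen=True)
class WeatherSeries:
    """A gap-free, date-ordered daily min/max air temperature series."""

    frame: pd.DataFrame  # columns: date (datetime64), tmin, tmax

    def __post_init__(self) -> None:
        df = self.frame
        required = {"date", "tmin", "tmax"}
        if not required.issubset(df.columns):
            raise WeatherError(f"weather frame needs columns {sorted(required)}")
        if len(df) == 0:
            raise WeatherError("empty weather series")
        dates = pd.to_datetime(df["date"])
        diffs = dates.diff().dropna()
        if (diffs <= pd.Timedelta(0)).any():
            raise WeatherError("dates must be strictly increasing")
        if (diffs != pd.Timedelta(days=1)).any():
            raise WeatherError("weather series has date gaps; fill or fix the input")
        if (df["tmin"] > df["tmax"]).any():
            raise WeatherError("tmin exceeds tmax on at least one day")
        object.__setattr__(self, "frame", df.assign(date=dates).reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.Series:
        return self.frame["date"]

    @property
    def julian(self) -> pd.Series:
        """Day of year (1 = 1 January)."""
        return self.frame["date"].dt.dayofyear

    @property
    def tmean_air(self) -> pd.Series:
        return (self.frame["tmin"] + self.frame["tmax"]) / 2.0

    @property
    def tmean_soil(self) -> pd.Series:
        return air_to_soil(self)

    def soil_means(self) -> pd.Series:
        """Daily mean soil temperature indexed by date."""
        s = air_to_soil(self)
        s.index = pd.DatetimeIndex(self.frame["date"])
        return s

    def __getitem__(self, i: int) -> DailyWeather:
        row = self.frame.iloc[i]
        return DailyWeather(row["date"], float(row["tmin"]), float(row["tmax"]))


def air_to_soil_mean(tmean_air: float) -> float:
    """Convert one daily mean air temperature to a soil mean (°C)."""
    return tmean_air + (0.9 if tmean_air < SOIL_THRESHOLD else 0.6)


def air_to_soil(series: WeatherSeries) -> pd.Series:
    """Soil-converted daily means for a whole series.

    The branch condition is evaluated per day on the daily mean air
    temperature; the offset is +0.9 below 23.3 °C and +0.6 at or above it.
    """
    tmean = series.tmean_air
    offset = np.where(tmean < SOIL_THRESHOLD, 0.9, 0.6)
    return tmean + offset


def moving_average(values, window: int) -> np.ndarray:
    """Trailing moving average; the window shrinks at the series start.

    Causal by construction: day i averages days max(0, i-window+1)..i, so a
    forecast never depends on future temperatures.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, min_periods=1).mean().to_numpy()


#: Named synthetic profiles. Parameters are annual mean (°C), seasonal
#: amplitude (°C), calendar day of the warm peak, diurnal range (°C) and
#: day-to-day noise s.d. (°C). jeju-like sustains >60 consecutive summer
#: days of soil means above 22.1 °C; jinju-like a shorter hot spell;
#: cool-temperate soil means rarely reach 22.1 °C at all.
WEATHER_PROFILES: dict[str, dict[str, float]] = {
    "jeju-like": {
        "annual_mean": 16.5,
        "amplitude": 10.0,
        "peak_day": 210,
        "diurnal_range": 6.0,
        "noise_sd": 1.0,
    },
    "jinju-like": {
        "annual_mean": 13.0,
        "amplitude": 11.5,
        "peak_day": 207,
        "diurnal_range": 8.0,
        "noise_sd": 1.0,
    },
    "cool-temperate": {
        "annual_mean": 10.0,
        "amplitude": 9.0,
        "peak_day": 200,
        "diurnal_range": 8.0,
        "noise_sd": 1.0,
    },
}


def generate_synthetic_weather(
    profile: str | dict[str, float],
    year: int = 2022,
    seed: int = 0,
    n_years: int = 1,
) -> WeatherSeries:
    """Generate a sinusoidal-annual-cycle daily weather series.

    Daily mean = annual_mean + amplitude * cos(2*pi*(doy - peak_day)/365)
    + N(0, noise_sd); min/max are the mean -/+ half the diurnal range.
    Reproducible bit-for-bit for a fixed seed and parameter set.
    """
    if isinstance(profile, str):
        try:
            p = WEATHER_PROFILES[profile]
        except KeyError:
            raise WeatherError(
                f"unknown weather profile {profile!r}; known: {sorted(WEATHER_PROFILES)}"
            ) from None
    else:
        p = dict(profile)
    if p["amplitude"] < 0 or p["noise_sd"] < 0:
        raise WeatherError("amplitude and noise_sd must be non-negative")

    start = pd.Timestamp(year=year, month=1, day=1)
    end = pd.Timestamp(year=year + n_years - 1, month=12, day=31)
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    mean = (
        p["annual_mean"]
        + p["amplitude"] * np.cos(2.0 * np.pi * (doy - p["peak_day"]) / 365.0)
        + rng.normal(0.0, p["noise_sd"], size=len(dates))
    )
    half = p["diurnal_range"] / 2.0
    frame = pd.DataFrame({"date": dates, "tmin": mean - half, "tmax": mean + half})
    return WeatherSeries(frame)


def read_weather_csv(path) -> WeatherSeries:
    """Read a `date,tmin,tmax` CSV (ISO-8601 dates, °C) with validation."""
    df = pd.read_csv(path, parse_dates=["date"])
    missing = {"date", "tmin", "tmax"} - set(df.columns)
    if missing:
        raise WeatherError(f"weather CSV missing columns: {sorted(missing)}")
    return WeatherSeries(df[["date", "tmin", "tmax"]])


def write_weather_csv(series: WeatherSeries, path, include_soil: bool = False) -> None:
    """Write the series back in the same dialect, optionally with soil means."""
    df = series.frame.copy()
    if include_soil:
        df["tmean_soil"] = air_to_soil(series)
    df.to_csv(path, index=False, date_format="%Y-%m-%d")
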