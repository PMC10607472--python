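"""Degree-day (thermal constant) bookkeeping for generation tracking.

A single common lower threshold T_cb (the mean of the stage-specific lower
thresholds, 3.9 °C by default) is used for every stage so field degree-days
can be accumulated once and compared against per-stage thermal constants K
(°C·day). The shipped constants give 650.9 DD for a full egg-to-egg
generation and 433.9 DD from adult emergence to pupation of the offspring
(preoviposition + egg + three larval instars); subtracting the 19.1 DD of
one day at 23 °C gives the 414.8 DD backtracking constant used to date
adult presence from late-stage larvae found in the field.

Daily increments use the daily-mean-minus-base method, truncated at zero,
on soil-converted means. Dates are whole days: development begun on the
start date accrues its first increment over that day, so the cumulative
total *at* the start date is zero and a target K is completed on the first
date by which the preceding days' increments sum to at least K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StageConstants",
    "DDTrack",
    "TargetNotReached",
    "common_base_temperature",
    "thermal_constant",
    "accumulate_dd",
    "date_at_dd",
    "backtrack_date",
]

_DEFAULT_STAGES = {
    "egg": 53.6,
    "instar1": 79.3,
    "instar2": 73.6,
    "instar3": 159.2,
    "pupa": 217.0,
    "preoviposition": 68.2,
}


class TargetNotReached(RuntimeError):
    """The degree-day target is not met within the series.

    In the field this is the "not completed this season" outcome: the
    thermal sum required for the generation never forms before the series
    (typically the calendar year) ends.
    """


@dataclass(frozen=True)
class StageConstants:
    """Common base temperature plus per-stage thermal constants (°C·day)."""

    t_cb: float = 3.9
    egg: float = _DEFAULT_STAGES["egg"]
    instar1: float = _DEFAULT_STAGES["instar1"]
    instar2: float = _DEFAULT_STAGES["instar2"]
    instar3: float = _DEFAULT_STAGES["instar3"]
    pupa: float = _DEFAULT_STAGES["pupa"]
    preoviposition: float = _DEFAULT_STAGES["preoviposition"]

    def __post_init__(self) -> None:
        for name in _DEFAULT_STAGES:
            if getattr(self, name) < 0:
                raise ValueError(f"thermal constant for {name} must be >= 0")

    @property
    def egg_to_egg(self) -> float:
        """Full-generation thermal requirement (all stages)."""
        return (
            self.egg + self.instar1 + self.instar2 + self.instar3
            + self.pupa + self.preoviposition
        )

    @property
    def emergence_to_pupation(self) -> float:
        """Adult emergence to offspring pupation: preoviposition + egg + instars."""
        return self.preoviposition + self.egg + self.instar1 + self.instar2 + self.instar3

    def backtrack_constant(self, days_short: float = 1.0, temperature: float = 23.0) -> float:
        """Emergence-to-pupation minus the DD of the final pre-pupation day(s).

        Larvae that pupate within ``days_short`` days of collection lack
        only that much thermal input, so adults must have been present once
        the remainder had accumulated.
        """
        return self.emergence_to_pupation - thermal_constant(days_short, temperature, self.t_cb)


@dataclass(frozen=True)
class DDTrack:
    """Per-day degree-day increments and their running sum from a start date."""

    start: pd.Timestamp
    dates: pd.DatetimeIndex
    increments: np.ndarray
    cumulative: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        inc = np.asarray(self.increments, dtype=float)
        if (inc < 0).any():
            raise ValueError("degree-day increments must be non-negative")
        object.__setattr__(self, "increments", inc)
        object.__setattr__(self, "cumulative", np.cumsum(inc))


def common_base_temperature(thresholds) -> float:
    """Mean of the stage lower thresholds, rounded to one decimal (°C)."""
    arr = np.asarray(thresholds, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one threshold")
    return round(float(arr.mean()), 1)


def thermal_constant(days: float, temperature: float, t_cb: float) -> float:
    """K = d * (T - T_cb) for development completed in d days at constant T."""
    if days <= 0:
        raise ValueError("days must be positive")
    if temperature <= t_cb:
        raise ValueError(
            f"temperature {temperature} °C is at or below the threshold {t_cb} °C; "
            "no development occurs"
        )
    return days * (temperature - t_cb)


def accumulate_dd(soil_means: pd.Series, t_cb: float, start) -> DDTrack:
    """Accumulate daily degree-days from ``start`` along a soil-mean series.

    ``soil_means`` is a daily series indexed by date (e.g. from
    :meth:`onionfly.weather.WeatherSeries.soil_means`). Each day contributes
    ``max(0, T_soil - t_cb)``.
    """
    start = pd.Timestamp(start)
    if start not in soil_means.index:
        raise ValueError(f"start date {start.date()} not in the weather series")
    sub = soil_means.loc[start:]
    inc = np.maximum(sub.to_numpy(dtype=float) - t_cb, 0.0)
    return DDTrack(start=start, dates=pd.DatetimeIndex(sub.index), increments=inc)


def date_at_dd(track: DDTrack, target: float) -> pd.Timestamp:
    """First date by which the preceding days' increments total >= target.

    A target of 0 is met on the start date itself. Raises
    :class:`TargetNotReached` if the sum never reaches the target within
    the series — the generation does not complete that season.
    """
    if target < 0:
        raise ValueError("target must be >= 0")
    if target == 0:
        return track.start
    # cumulative[i] covers days start..start+i inclusive; completion then
    # falls on the following date.
    idx = np.searchsorted(track.cumulative, target)
    if idx >= len(track.cumulative):
        raise TargetNotReached(
            f"{target} DD not reached within the series "
            f"(total {track.cumulative[-1]:.1f} DD by {track.dates[-1].date()})"
        )
    completion = track.dates[idx] + pd.Timedelta(days=1)
    return pd.Timestamp(completion)


def backtrack_date(soil_means: pd.Series, end, target: float, t_cb: float) -> pd.Timestamp:
    """Latest start date whose degree-days through ``end`` reach ``target``.

    Inverse of forward tracking: increments are summed backwards from the
    day before ``end`` (the end date itself accrues nothing, mirroring the
    start-date convention of :func:`accumulate_dd`).
    """
    end = pd.Timestamp(end)
    if end not in soil_means.index:
        raise ValueError(f"end date {end.date()} not in the weather series")
    if target < 0:
        raise ValueError("target must be >= 0")
    if target == 0:
        return end
    sub = soil_means.loc[:end].iloc[:-1]  # days strictly before end
    inc = np.maximum(sub.to_numpy(dtype=float) - t_cb, 0.0)
    rev_cum = np.cumsum(inc[::-1])
    idx = np.searchsorted(rev_cum, target)
    if idx >= len(rev_cum):
        raise TargetNotReached(
            f"{target} DD not available before {end.date()} "
            f"(total {rev_cum[-1] if len(rev_cum) else 0.0:.1f} DD)"
        )
    return pd.Timestamp(sub.index[len(sub) - 1 - idx])
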