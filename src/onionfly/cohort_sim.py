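"""Two-phase daily cohort simulation of post-aestivation adult emergence.

The model starts on 1 August with a single cohort of aestivating pupae
(default 1000) of physiological age 0 and runs in daily steps:

Phase I (summer-diapause termination). The aestivating cohort's
physiological age x advances each day by the SDT Lactin rate evaluated at
the trailing 3-day moving average of soil means (the moving average
stabilizes the start of termination; temperatures above the ~22.1 °C
thermal maximum contribute nothing — the hot summer effect). The fraction
F_s(x_new) - F_s(x_old) of the cohort's initial count leaves diapause that
day and founds a new non-diapausing pupal cohort at physiological age 0.

Phase II (pupal development). Every pupal cohort created on a previous day
advances its age by the pupal Lactin rate at the same-day soil mean, and
emits F_p(px_new) - F_p(px_old) of its initial count as newly emerged
adults. A cohort never advances on its creation day, so no individual makes
progress in both phases within one 24 h step.

All counts are expected values carried as real numbers: the stage
transitions are deterministic, with the Weibull distributions supplying the
inter-individual spread. A cohort whose CDF passes the tail-closure
threshold (0.999) transfers its entire residual and is retired, keeping the
total mass exactly conserved over a finite horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .thermal_models import (
    CompletionDistribution,
    ThermalResponseParams,
    lactin_rate,
    weibull_cdf,
)
from .weather import WeatherSeries, air_to_soil, moving_average

__all__ = [
    "Cohort",
    "SimulationConfig",
    "SimulationState",
    "SimulationResult",
    "step_day",
    "run_simulation",
    "emergence_curve",
]

# Published defaults (SDT = Phase I, pupal = Phase II).
DEFAULT_SDT_RATE = ThermalResponseParams(rho=0.16978, t_max=22.13802, delta_t=5.67016)
DEFAULT_SDT_DIST = CompletionDistribution(alpha=1.15460, beta=1.71717)
DEFAULT_PUPAL_RATE = ThermalResponseParams(
    rho=0.151932200, t_max=37.88922166, delta_t=6.572996371
)
DEFAULT_PUPAL_DIST = CompletionDistribution(alpha=1.121146325, beta=3.155020615)


@dataclass
class Cohort:
    """A daily cohort: individuals sharing an entry day and physiological age."""

    stage: str  # "aestivating" or "pupal"
    entry_day: pd.Timestamp
    initial_count: float
    physio_age: float = 0.0
    emitted_fraction: float = 0.0
    active: bool = True

    @property
    def remaining(self) -> float:
        return self.initial_count * (1.0 - self.emitted_fraction) if self.active else 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation settings; defaults are the published study conditions."""

    initial_count: float = 1000.0
    start_month: int = 8
    start_day: int = 1
    sdt_rate: ThermalResponseParams = DEFAULT_SDT_RATE
    sdt_dist: CompletionDistribution = DEFAULT_SDT_DIST
    pupal_rate: ThermalResponseParams = DEFAULT_PUPAL_RATE
    pupal_dist: CompletionDistribution = DEFAULT_PUPAL_DIST
    tail_threshold: float = 0.999
    t3d_window: int = 3

    def __post_init__(self) -> None:
        if self.initial_count <= 0:
            raise ValueError("initial cohort size must be positive")
        if not 0 < self.tail_threshold < 1:
            raise ValueError("tail_threshold must lie in (0, 1)")

    def start_date(self, year: int) -> pd.Timestamp:
        return pd.Timestamp(year=year, month=self.start_month, day=self.start_day)


@dataclass
class SimulationState:
    """Mutable per-day state: one aestivating cohort plus pupal cohorts."""

    config: SimulationConfig
    aestivating: Cohort
    pupal_cohorts: list[Cohort] = field(default_factory=list)
    cumulative_adults: float = 0.0

    @property
    def aestivating_count(self) -> float:
        return self.aestivating.remaining

    @property
    def pupal_count(self) -> float:
        return sum(c.remaining for c in self.pupal_cohorts)

    def total_mass(self) -> float:
        """Conserved quantity: everyone is somewhere."""
        return self.aestivating_count + self.pupal_count + self.cumulative_adults


def _advance(cohort: Cohort, rate: float, dist: CompletionDistribution, tail: float) -> float:
    """Advance one cohort a day at the given rate; return the count emitted."""
    if not cohort.active:
        return 0.0
    new_age = cohort.physio_age + rate
    new_cdf = float(weibull_cdf(new_age, dist))
    if new_cdf >= tail:
        emitted = cohort.initial_count * (1.0 - cohort.emitted_fraction)
        cohort.physio_age = new_age
        cohort.emitted_fraction = 1.0
        cohort.active = False
        return emitted
    emitted = cohort.initial_count * (new_cdf - cohort.emitted_fraction)
    cohort.physio_age = new_age
    cohort.emitted_fraction = new_cdf
    return emitted


def step_day(
    state: SimulationState, today: pd.Timestamp, t3d_soil: float, tmean_soil: float
) -> tuple[float, float]:
    """Advance the whole state one day; return (new pupae, new adults).

    Update order is fixed: Phase I transfer first, then Phase II advancement
    of cohorts created on previous days only.
    """
    cfg = state.config

    # Phase I: diapause termination driven by the 3-day soil average.
    sdt_rate = float(lactin_rate(t3d_soil, cfg.sdt_rate))
    new_pupae = _advance(state.aestivating, sdt_rate, cfg.sdt_dist, cfg.tail_threshold)

    # Phase II: development of pre-existing pupal cohorts at today's soil mean.
    pup_rate = float(lactin_rate(tmean_soil, cfg.pupal_rate))
    new_adults = 0.0
    for cohort in state.pupal_cohorts:
        if cohort.entry_day >= today:
            continue  # created today; starts advancing tomorrow
        new_adults += _advance(cohort, pup_rate, cfg.pupal_dist, cfg.tail_threshold)

    if new_pupae > 0.0:
        state.pupal_cohorts.append(
            Cohort(stage="pupal", entry_day=today, initial_count=new_pupae)
        )
    state.pupal_cohorts = [c for c in state.pupal_cohorts if c.active]
    state.cumulative_adults += new_adults
    return new_pupae, new_adults


@dataclass(frozen=True)
class SimulationResult:
    """Daily ledger of the simulation.

    ``frame`` columns: date, t3d_soil, tmean_soil, aestivating, pupae,
    adults_new, adults_cum.
    """

    frame: pd.DataFrame
    initial_count: float

    @property
    def total_emerged(self) -> float:
        return float(self.frame["adults_cum"].iloc[-1])


def run_simulation(
    weather: WeatherSeries,
    config: SimulationConfig | None = None,
    start: pd.Timestamp | str | None = None,
) -> SimulationResult:
    """Run the two-phase model over a weather series.

    ``start`` defaults to 1 August of the series' first year and must lie
    within the series. Soil means are derived from the air series; the
    Phase I driving temperature is their trailing 3-day moving average
    (computed over the full series, so the first simulated day already has
    real history when available).
    """
    cfg = config or SimulationConfig()
    dates = pd.DatetimeIndex(weather.dates)
    soil = air_to_soil(weather).to_numpy(dtype=float)
    t3d = moving_average(soil, cfg.t3d_window)

    if start is None:
        start_ts = cfg.start_date(int(dates[0].year))
    else:
        start_ts = pd.Timestamp(start)
    pos = dates.get_indexer([start_ts])
    if pos[0] < 0:
        raise ValueError(f"start date {start_ts.date()} not within the weather series")
    i0 = int(pos[0])

    state = SimulationState(
        config=cfg,
        aestivating=Cohort(
            stage="aestivating", entry_day=start_ts, initial_count=float(cfg.initial_count)
        ),
    )
    records = []
    for i in range(i0, len(dates)):
        today = dates[i]
        _, new_adults = step_day(state, today, float(t3d[i]), float(soil[i]))
        records.append(
            {
                "date": today,
                "t3d_soil": t3d[i],
                "tmean_soil": soil[i],
                "aestivating": state.aestivating_count,
                "pupae": state.pupal_count,
                "adults_new": new_adults,
                "adults_cum": state.cumulative_adults,
            }
        )
    return SimulationResult(frame=pd.DataFrame(records), initial_count=float(cfg.initial_count))


def emergence_curve(result: SimulationResult):
    """Cumulative emergence scaled to the final total.

    Returns an :class:`onionfly.evaluation.EmergenceCurve` over Julian
    day-of-year. If nothing emerged, returns an explicit empty curve.
    """
    from .evaluation import EmergenceCurve

    total = result.total_emerged
    if total <= 0.0:
        return EmergenceCurve(dates=np.array([]), fractions=np.array([]))
    df = result.frame
    # Julian day-of-year continued past 31 December (366, 367, ...) so a
    # simulation crossing the year boundary keeps strictly increasing dates.
    origin = pd.Timestamp(year=int(df["date"].iloc[0].year), month=1, day=1)
    julian = (df["date"] - origin).dt.days.to_numpy(dtype=float) + 1.0
    fractions = df["adults_cum"].to_numpy(dtype=float) / total
    return EmergenceCurve(dates=julian, fractions=fractions)
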