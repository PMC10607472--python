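"""Model-vs-observation comparison of cumulative emergence curves.

Observed and predicted cumulative emergence curves are matched at fixed
percentiles (10, 15, 25, 50, 75, 90, 95% by default) by linear
interpolation between successive observation dates. The per-percentile
discrepancies are taken in absolute value and tested against a null mean
of 5 days with a two-sided one-sample t-test (a discrepancy of about five
days being the practical accuracy limit for spray-timing forecasts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EmergenceCurve",
    "ComparisonReport",
    "PercentileNotReached",
    "DEFAULT_PERCENTILES",
    "percentile_dates",
    "compare_emergence",
    "report_from_percentile_dates",
]

DEFAULT_PERCENTILES = (10.0, 15.0, 25.0, 50.0, 75.0, 90.0, 95.0)


class PercentileNotReached(ValueError):
    """A requested percentile exceeds the curve's maximum cumulative fraction."""


@dataclass(frozen=True)
class EmergenceCurve:
    """Cumulative emergence fractions over (fractional) Julian dates."""

    dates: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dates, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if d.shape != f.shape or d.ndim != 1:
            raise ValueError("dates and fractions must be 1-D and equal length")
        if d.size:
            if np.any(np.diff(d) <= 0):
                raise ValueError("dates must be strictly increasing")
            if np.any(np.diff(f) < 0):
                raise ValueError("cumulative fractions must be non-decreasing")
            if np.any((f < 0) | (f > 1)):
                raise ValueError("fractions must lie in [0, 1]")
        object.__setattr__(self, "dates", d)
        object.__setattr__(self, "fractions", f)

    @property
    def empty(self) -> bool:
        return self.dates.size == 0


@dataclass(frozen=True)
class ComparisonReport:
    """Percentile-matched discrepancy statistics between two curves."""

    percentiles: tuple[float, ...]
    observed_dates: tuple[float, ...]
    predicted_dates: tuple[float, ...]
    differences: tuple[float, ...]  # absolute, days
    mean_difference: float
    se: float | None
    t_statistic: float | None
    p_value: float | None
    null_days: float = 5.0

    @property
    def significant(self) -> bool | None:
        """True when the mean discrepancy differs from the null at p < 0.05."""
        return None if self.p_value is None else bool(self.p_value < 0.05)


def percentile_dates(curve: EmergenceCurve, percentiles: Sequence[float]) -> np.ndarray:
    """Dates at which the curve crosses each cumulative percentile.

    Linear interpolation between the two bracketing observations; an exact
    hit returns that date. A percentile already met at the first point
    returns the first date. Raises :class:`PercentileNotReached` for
    percentiles above the curve's maximum.
    """
    if curve.empty:
        raise PercentileNotReached("curve is empty; no emergence occurred")
    f = curve.fractions
    d = curve.dates
    out = np.empty(len(percentiles), dtype=float)
    fmax = f[-1]
    for k, p in enumerate(percentiles):
        target = p / 100.0
        if not 0.0 < target <= fmax + 1e-12:
            raise PercentileNotReached(
                f"percentile {p}% exceeds the curve maximum {100 * fmax:.1f}%"
            )
        i = min(int(np.searchsorted(f, target, side="left")), f.size - 1)
        if f[i] == target or i == 0:
            out[k] = d[i]
            continue
        f0, f1 = f[i - 1], f[i]
        # flat segments cannot bracket (f0 == target handled above via
        # searchsorted picking the first equal entry)
        out[k] = d[i - 1] + (target - f0) / (f1 - f0) * (d[i] - d[i - 1])
    return out


def report_from_percentile_dates(
    percentiles: Sequence[float],
    observed_dates: Sequence[float],
    predicted_dates: Sequence[float],
    null_days: float = 5.0,
) -> ComparisonReport:
    """Build the discrepancy report from already-matched percentile dates.

    This is the input form of published validation tables: a row per
    percentile with observed and predicted Julian dates. Differences are
    absolute; mean, SE (sd/sqrt(n), n-1 denominator) and the two-sided
    one-sample t-test against ``null_days`` are computed when at least two
    percentiles are available.
    """
    obs = np.asarray(observed_dates, dtype=float)
    pred = np.asarray(predicted_dates, dtype=float)
    pcts = tuple(float(p) for p in percentiles)
    if not (len(pcts) == obs.size == pred.size):
        raise ValueError("percentiles, observed and predicted lengths must agree")
    if obs.size == 0:
        raise ValueError("need at least one percentile")
    diffs = np.abs(obs - pred)
    mean = float(diffs.mean())
    if diffs.size < 2:
        se = t_stat = p_val = None
    else:
        se = float(diffs.std(ddof=1) / np.sqrt(diffs.size))
        if se == 0.0:
            # degenerate: identical differences at every percentile
            t_stat = 0.0 if mean == null_days else float(np.sign(mean - null_days) * np.inf)
            p_val = 1.0 if t_stat == 0.0 else 0.0
        else:
            t_res = stats.ttest_1samp(diffs, popmean=null_days)
            t_stat, p_val = float(t_res.statistic), float(t_res.pvalue)
    return ComparisonReport(
        percentiles=pcts,
        observed_dates=tuple(float(v) for v in obs),
        predicted_dates=tuple(float(v) for v in pred),
        differences=tuple(float(v) for v in diffs),
        mean_difference=mean,
        se=se,
        t_statistic=t_stat,
        p_value=p_val,
        null_days=float(null_days),
    )


def compare_emergence(
    observed: EmergenceCurve,
    predicted: EmergenceCurve,
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
    null_days: float = 5.0,
) -> ComparisonReport:
    """Percentile-matched comparison of observed and predicted curves."""
    obs_dates = percentile_dates(observed, percentiles)
    pred_dates = percentile_dates(predicted, percentiles)
    return report_from_percentile_dates(percentiles, obs_dates, pred_dates, null_days)


def format_report(report: ComparisonReport) -> str:
    """Human-readable rendition of a comparison report."""
    lines = ["%emerg  observed  predicted  |diff| (d)"]
    for p, o, pr, d in zip(
        report.percentiles, report.observed_dates, report.predicted_dates, report.differences
    ):
        lines.append(f"{p:6.0f}  {o:8.1f}  {pr:9.1f}  {d:6.1f}")
    lines.append(f"mean |diff| = {report.mean_difference:.2f} d (null {report.null_days:.0f} d)")
    if report.se is not None:
        mark = "*" if report.significant else "ns"
        lines.append(
            f"SE = {report.se:.4f}, t = {report.t_statistic:.4f}, "
            f"p = {report.p_value:.4f} {mark}"
        )
    return "\n".join(lines)
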