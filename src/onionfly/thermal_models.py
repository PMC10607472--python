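"""Temperature-response and completion-time models.

Two unit models drive both phases of the *Delia antiqua* emergence model:

* a Lactin temperature–rate curve ``r(T) = exp(rho*T) - exp(rho*T_max -
  (T_max - T)/delta_T)``, clamped at zero, giving the daily development
  (or diapause-termination) rate at temperature ``T``;
* a two-parameter Weibull CDF ``F(x) = 1 - exp(-(x/alpha)**beta)`` over
  physiological age / normalized time, distributing individual completion
  times around the cohort mean.

The fitting routines here reproduce the published parameter tables from raw
laboratory data: through-origin exposure regressions (P50 estimation),
nonlinear least squares for the Lactin curve, and CDF fitting for the
Weibull distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "ThermalResponseParams",
    "CompletionDistribution",
    "ExposureAssay",
    "ExposureFit",
    "DevelopmentObservation",
    "FitResult",
    "FitError",
    "lactin_rate",
    "lactin_upper_limit",
    "fit_exposure",
    "normalize_times",
    "fit_lactin",
    "weibull_cdf",
    "fit_weibull",
    "density_surface",
]


class FitError(RuntimeError):
    """Raised when a model fit cannot be performed or does not converge."""


@dataclass(frozen=True)
class ThermalResponseParams:
    """Lactin rate-curve parameters.

    Parameters
    ----------
    rho : float
        Composite rate coefficient for the enzyme-kinetic term (1/°C scale).
    t_max : float
        Thermal maximum (°C); the rate is exactly zero at ``t_max`` and
        clamped to zero wherever the raw expression is negative.
    delta_t : float
        Thermal-breakdown temperature range (°C); must be positive.
    """

    rho: float
    t_max: float
    delta_t: float

    def __post_init__(self) -> None:
        if not self.delta_t > 0:
            raise ValueError(f"delta_t must be positive, got {self.delta_t}")


@dataclass(frozen=True)
class CompletionDistribution:
    """Two-parameter Weibull distribution of completion time.

    ``alpha`` is the dimensionless scale (the transition center: 63.2% of
    individuals have completed at x = alpha); ``beta`` the shape
    (steepness of the transition).
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"alpha and beta must be positive, got {self.alpha}, {self.beta}"
            )


@dataclass(frozen=True)
class ExposureAssay:
    """Completed proportions after fixed exposure periods at one temperature."""

    temperature: float
    exposure_days: tuple[float, ...]
    completed_proportion: tuple[float, ...]

    def __post_init__(self) -> None:
        days = tuple(float(d) for d in self.exposure_days)
        props = tuple(float(p) for p in self.completed_proportion)
        object.__setattr__(self, "exposure_days", days)
        object.__setattr__(self, "completed_proportion", props)
        if len(days) != len(props):
            raise ValueError("exposure_days and completed_proportion differ in length")
        if any(d <= 0 for d in days):
            raise ValueError("exposure days must be strictly positive")
        if any(not 0 <= p <= 1 for p in props):
            raise ValueError("proportions must lie in [0, 1]")


@dataclass(frozen=True)
class ExposureFit:
    """Through-origin regression of completed proportion on exposure days.

    ``p50 = 1 / (2 * slope_a)`` is the exposure (days) at which half the
    cohort has completed; a non-positive slope flags an invalid fit
    (no detectable termination at that temperature).
    """

    temperature: float
    slope_a: float
    p50: float | None

    @property
    def valid(self) -> bool:
        return self.slope_a > 0


@dataclass(frozen=True)
class DevelopmentObservation:
    """Mean development time at a constant temperature."""

    temperature: float
    mean_days: float

    def __post_init__(self) -> None:
        if not self.mean_days > 0:
            raise ValueError("mean_days must be positive")

    @property
    def rate(self) -> float:
        return 1.0 / self.mean_days


@dataclass(frozen=True)
class FitResult:
    """Outcome of a nonlinear model fit: parameters, R², residuals."""

    params: ThermalResponseParams | CompletionDistribution
    r_squared: float
    residuals: tuple[float, ...] = field(default=())


def lactin_rate(t, params: ThermalResponseParams):
    """Daily rate at temperature ``t`` (°C); vectorized, clamped at zero."""
    t = np.asarray(t, dtype=float)
    raw = np.exp(params.rho * t) - np.exp(
        params.rho * params.t_max - (params.t_max - t) / params.delta_t
    )
    out = np.maximum(raw, 0.0)
    return float(out) if out.ndim == 0 else out


def _lactin_raw(t, rho, t_max, delta_t):
    return np.exp(rho * t) - np.exp(rho * t_max - (t_max - t) / delta_t)


def lactin_upper_limit(params: ThermalResponseParams, bracket: tuple[float, float] | None = None) -> float:
    """Upper temperature at which the rate curve falls to zero.

    The raw Lactin expression crosses zero exactly at ``t_max``; this
    locates that root numerically so the curve itself, not the parameter
    label, defines the limit.
    """
    if bracket is None:
        bracket = (params.t_max - 10.0, params.t_max + 10.0)
    f = lambda t: _lactin_raw(t, params.rho, params.t_max, params.delta_t)
    return float(brentq(f, *bracket))


def fit_exposure(assay: ExposureAssay) -> ExposureFit:
    """Least-squares line through the origin for one exposure assay.

    The slope estimator is the through-origin least-squares solution
    ``a = sum(x*y) / sum(x**2)``. Extrapolation of P50 beyond the observed
    exposure range is permitted (required for temperatures where completion
    never reached 50% within the assay horizon).
    """
    x = np.asarray(assay.exposure_days, dtype=float)
    y = np.asarray(assay.completed_proportion, dtype=float)
    if x.size < 2:
        raise FitError("need at least 2 assay points for a through-origin fit")
    a = float(np.sum(x * y) / np.sum(x * x))
    p50 = 1.0 / (2.0 * a) if a > 0 else None
    return ExposureFit(temperature=assay.temperature, slope_a=a, p50=p50)


def normalize_times(days: Sequence[float], p50: float) -> np.ndarray:
    """Divide exposure periods by the 50%-completion period (dimensionless)."""
    if not p50 > 0:
        raise ValueError("p50 must be positive")
    return np.asarray(days, dtype=float) / p50


# Deterministic multi-start grid for the Lactin fit: coarse SSE screen over
# the grid, local refinement of the best candidates, best refined SSE wins
# (ties broken by lowest rho). No randomness anywhere.
_RHO_GRID = np.arange(0.05, 0.3001, 0.05)
_DELTA_T_GRID = np.arange(1.0, 10.001, 1.0)
_N_REFINE = 15


def fit_lactin(observations: Sequence[tuple[float, float]]) -> FitResult:
    """Fit the Lactin curve to (temperature °C, rate per day) points.

    Unweighted nonlinear least squares with a deterministic coarse-grid
    multi-start followed by local refinement. R² is computed about the
    mean observed rate.

    Raises
    ------
    FitError
        If fewer than 4 points are supplied or no start converges.
    """
    obs = [(float(t), float(r)) for t, r in observations]
    if len(obs) < 4:
        raise FitError(f"need at least 4 points to fit 3 parameters, got {len(obs)}")
    temps = np.array([t for t, _ in obs])
    rates = np.array([r for _, r in obs])
    t_hi = temps.max()

    def resid(p):
        return _lactin_raw(temps, *p) - rates

    starts = [
        (rho, tm, dt)
        for rho in _RHO_GRID
        for tm in np.arange(t_hi, t_hi + 20.001, 2.0)
        for dt in _DELTA_T_GRID
    ]
    screened = sorted(
        ((float(np.sum(resid(p) ** 2)), p) for p in starts),
        key=lambda sp: (sp[0], sp[1][0]),
    )
    lower = [1e-8, t_hi, 1e-3]
    upper = [5.0, t_hi + 40.0, 100.0]
    best: tuple[float, float, np.ndarray] | None = None
    for _, p0 in screened[:_N_REFINE]:
        try:
            sol = least_squares(resid, p0, bounds=(lower, upper))
        except Exception:  # pragma: no cover - defensive
            continue
        if not sol.success:
            continue
        key = (2.0 * sol.cost, sol.x[0])
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], sol.x)
    if best is None:
        raise FitError("Lactin fit did not converge from any multi-start point")
    sse, _, p = best
    sst = float(np.sum((rates - rates.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    params = ThermalResponseParams(rho=float(p[0]), t_max=float(p[1]), delta_t=float(p[2]))
    res = _lactin_raw(temps, *p) - rates
    return FitResult(params=params, r_squared=float(r2), residuals=tuple(float(v) for v in res))


def weibull_cdf(x, dist: CompletionDistribution):
    """Cumulative completed fraction at normalized time / physiological age x."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("normalized time must be non-negative")
    out = 1.0 - np.exp(-np.power(x / dist.alpha, dist.beta))
    return float(out) if out.ndim == 0 else out


def fit_weibull(points: Sequence[tuple[float, float]]) -> FitResult:
    """Fit the two-parameter Weibull CDF to (normalized time, fraction) points.

    Deterministic initialization: ``alpha`` starts at the x value closest to
    63.2% completion, ``beta`` at 2.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise FitError(f"need at least 3 points to fit 2 parameters, got {len(pts)}")
    x = np.array([p for p, _ in pts])
    y = np.array([q for _, q in pts])
    if np.any((y < 0) | (y > 1)):
        raise FitError("fractions must lie in [0, 1]")
    if np.all(x == x[0]):
        raise FitError("degenerate data: all normalized times equal")

    alpha0 = float(x[np.argmin(np.abs(y - 0.632))])
    if alpha0 <= 0:
        alpha0 = float(np.median(x[x > 0])) if np.any(x > 0) else 1.0

    def resid(p):
        return 1.0 - np.exp(-np.power(x / p[0], p[1])) - y

    sol = least_squares(resid, [alpha0, 2.0], bounds=([1e-8, 1e-8], [np.inf, np.inf]))
    if not sol.success:
        raise FitError("Weibull CDF fit did not converge")
    sse = 2.0 * sol.cost
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    dist = CompletionDistribution(alpha=float(sol.x[0]), beta=float(sol.x[1]))
    return FitResult(params=dist, r_squared=float(r2), residuals=tuple(float(v) for v in sol.fun))


def density_surface(
    params: ThermalResponseParams,
    dist: CompletionDistribution,
    temperatures: Sequence[float],
    horizon: int,
) -> np.ndarray:
    """Daily completion fractions on a (temperature, day) grid.

    At each constant temperature the physiological age advances by the
    daily rate; entry ``(T, i)`` is the fraction of the cohort completing
    on day ``i + 1``, i.e. ``F(x_{i+1}) - F(x_i)``. Rows at or above the
    thermal maximum are all zeros (arrested development); row sums never
    exceed 1.
    """
    if horizon < 1:
        raise ValueError("horizon must be at least 1 day")
    temps = np.asarray(temperatures, dtype=float)
    rates = lactin_rate(temps, params)
    days = np.arange(horizon + 1, dtype=float)
    ages = np.outer(rates, days)  # (T, horizon+1) physiological ages
    cdf = 1.0 - np.exp(-np.power(ages / dist.alpha, dist.beta))
    return np.diff(cdf, axis=1)
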