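# Methods

## Model structure and assumptions

The package models adult emergence of *Delia antiqua* from aestivating
(summer-diapausing) pupae as two sequential temperature-driven processes,
each built from the same pair of unit models — a Lactin temperature–rate
curve and a two-parameter Weibull distribution of completion time.

* **Phase I, summer-diapause termination.** A single cohort of aestivating
  pupae (physiological age 0) starts on 1 August, the hottest part of the
  season. Each day its age advances by the SDT Lactin rate evaluated at the
  trailing 3-day moving average of daily mean soil temperature; the Weibull
  CDF over that age dictates the fraction terminating diapause that day.
  Temperature is assumed to be the sole driver of termination; no separate
  critical "initiation" temperature is needed because the curve's thermal
  maximum (≈22.1 °C) already plays that role — above it the rate is clamped
  to zero and the cohort is arrested (the hot summer effect).
* **Phase II, post-diapause pupal development.** Individuals leaving
  diapause found a new pupal cohort at physiological age 0 dated that day.
  Pupal cohorts advance by the pupal Lactin rate at the same-day soil mean
  and emit adults through their own Weibull distribution.

Counts are expected values carried as real numbers; the model is
deterministic, with the Weibull CDFs expressing inter-individual variation
in completion time rather than sampling noise. Mortality, oviposition and
larval dynamics, winter-diapause induction, and photoperiod effects are all
outside the model; the subsequent generation is handled only through
degree-day bookkeeping.

## Unit models and parameters

Lactin rate: `r(T) = exp(ρT) − exp(ρT_m − (T_m − T)/ΔT)`, clamped at zero.
`T_m` is the thermal maximum (the rate's upper zero), `ΔT` the thermal
breakdown range, `ρ` a composite enzyme-kinetic coefficient. Shipped
defaults (per day, °C):

| phase | ρ | T_m | ΔT |
|---|---|---|---|
| SDT | 0.16978 | 22.13802 | 5.67016 |
| pupal | 0.151932 | 37.88922 | 6.57300 |

Weibull CDF: `F(x) = 1 − exp(−(x/α)^β)` over dimensionless normalized
time / physiological age; `α` is the transition center (63.2% completion at
x = α exactly), `β` the steepness. Defaults: SDT α = 1.15460, β = 1.71717;
pupal α = 1.12115, β = 3.15502. The standard Weibull form is used; the
63.2%-at-α identity holds only for this form and anchors the choice.

The SDT rate at temperature T_i is defined through exposure assays: the
completed proportion is linear in exposure days through the origin
(y = a·x), the 50% completion period is P50 = 1/(2a), and 1/P50 is the
daily rate. Non-positive slopes are flagged invalid (no detectable
termination at that temperature) rather than propagated.

## Fitting

All nonlinear fits are unweighted least squares. The Lactin fit uses a
deterministic coarse-grid multi-start — ρ ∈ {0.05…0.30 step 0.05},
T_m ∈ {max observed T … +20 °C step 2}, ΔT ∈ {1…10 step 1} — screened by
SSE, with the best 15 grid points refined by bounded trust-region least
squares; the lowest refined SSE wins and ties break toward the lowest ρ.
This makes refits reproducible without any random seed. R² is computed as
1 − SSE/SST about the mean observed rate, matching curve-fitting-software
convention. Rates are exact reciprocals of mean development days, unrounded.

Refitting the pupal curve to the 17 packaged temperature/development-time
points (three published laboratory series) is the package's standing check
of the fitting machinery. The refit optimum has T_m ≈ 39.1 °C with a very
flat SSE surface in T_m (the published table reports a standard error above
3 °C on this parameter), about 1.2 °C above the published point estimate;
R² reproduces to 0.94. The acceptance suite asserts the published ±1 °C
band and therefore records this single comparison as a failure; the package
reports its own computed optimum rather than adopting the published value.

## Weather handling

Inputs are gap-free daily min/max air temperature series (`date,tmin,tmax`
CSV, ISO dates, °C). Missing dates are an error, never interpolated —
silent gap-filling corrupts degree-day totals. The daily mean is
(min+max)/2. Air→soil conversion adds +0.9 °C when the daily mean air
temperature is below 23.3 °C and +0.6 °C at or above it (an empirical 5 cm
soil-depth relationship); the branch is evaluated per day on the daily mean,
and only daily mean soil temperatures feed the model. The Phase I moving
average is trailing (causal), window 3 days, shrinking at the series start —
a forecasting model cannot use future days.

The synthetic generator produces daily means as an annual cosine
(mean + amplitude·cos(2π(doy − peak)/365)) plus i.i.d. Gaussian noise, with
min/max at ∓ half the diurnal range; it is bit-reproducible for a fixed
seed. Three presets emulate regional summer intensity: `jeju-like`
(subtropical; >60 consecutive days of soil means above the 22.1 °C
termination limit), `jinju-like` (hot but shorter exceedance, the pattern
that produces a strongly delayed but complete autumn flight) and
`cool-temperate` (soil means rarely reach the limit; generations before and
after summer overlap). Preset parameters (annual mean 16.5/13.0/10.0 °C,
amplitude 10/11.5/9 °C, noise sd 1 °C) were chosen once to realize those
qualitative regimes with realistic mid-latitude values. The generator
emulates only the seasonal cycle and day-to-day noise of real station data —
no autocorrelated synoptic weather, no heat waves beyond the sinusoid, no
soil thermal inertia — so passing tests demonstrate correct model mechanics
under controlled forcing, not forecast skill on real weather.

## Degree days

Daily increments are max(0, soil mean − T_cb) (daily-mean-minus-base with
truncation; sine-wave and hourly methods are out of scope). T_cb is the
mean of the five published stage lower thresholds rounded to one decimal
(3.9 °C, used as-is: one day at 23 °C is exactly 19.1 DD). Dates are whole
days: the cumulative total *at* the start date is zero, and a target K is
completed on the first date by which the preceding days' increments reach K;
backtracking mirrors this (the end date accrues nothing), making
forward/backward tracking agree within daily resolution on
constant-temperature series. Stage constants (53.6, 79.3, 73.6, 159.2,
217.0, 68.2 DD) give the derived totals 650.9 (egg-to-egg), 433.9
(emergence to offspring pupation) and 414.8 DD (433.9 − 19.1, for
backtracking adult presence from late-stage larvae). If a target is not
met within the series the functions raise an explicit not-reached error —
the "generation not completed this season" outcome, which a cold year can
legitimately produce.

## Numerical choices

* Update order within a day is fixed: Phase I transfer first, then Phase II
  advancement of cohorts created on previous days only; a cohort never
  advances on its creation day, so no individual progresses in both phases
  within one 24 h step.
* Tail closure: the Weibull CDF never reaches 1, so a cohort whose CDF
  passes 0.999 transfers its entire residual that day and is retired. This
  keeps mass conservation exact on a finite horizon at the cost of a ≤0.1%
  early transfer per cohort.
* The emergence curve scales cumulative daily adults by the final total; if
  nothing emerged (e.g. soil above the SDT limit all season) an explicit
  empty curve is returned rather than a division by zero.
* Percentile dates are linearly interpolated between bracketing
  observations; exact hits return the observed date; percentiles above a
  curve's maximum raise an explicit error.
* Discrepancy statistics use absolute observed-minus-predicted differences;
  SE = sd/√n with n−1 denominator; the one-sample t-test against the 5-day
  null is two-sided with df = n−1. With identical differences at every
  percentile (zero variance) the t statistic is defined as 0 when the mean
  equals the null and ±∞ otherwise. The published 1987 validation row's SE
  does not recompute from its own printed differences (1.133 vs a printed
  1.331, the former consistent with the printed t ≈ 0.189); the package
  always recomputes from differences.

## Testing strategy and problem sizes

The default suite runs entirely on packaged data and synthetic weather.
The cohort model is cross-checked against an independent individual-based
Monte Carlo simulator (each pupa draws termination and development
thresholds from the two Weibull distributions by inverse-CDF sampling and
advances by the same daily rates); at 100,000 individuals the percentile
dates of the two simulators agree within one day over a full season, run
once in the acceptance tests with a fixed seed. Structural properties —
exact mass conservation, arrest under sustained heat, the guarantee that
inserting extra above-limit days never advances any emergence percentile,
linearity in cohort size — are asserted on one-year series, which a single
CPU completes in seconds.

## Known limitations

Validation against multi-decade station records is out of scope (no real
weather ships with the package); the soil conversion is a two-branch
empirical offset calibrated for one region's soils; the model predicts
timing and relative abundance of one emergence wave, not absolute
population size; and behaviour after emergence (oviposition timing beyond
a fixed preoviposition thermal sum) is not simulated.
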