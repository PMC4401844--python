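# Methods

## The annual displacement design

The quantity of interest is the association between a year's mortality and
that year's temperature extremes. Any excess death displaced by less than
the distance to the next year boundary contributes a compensating deficit
inside the same year and cancels out of the annual count; an annual
association therefore reflects only deaths *not* due to occur within the
year. The analysis year is anchored in early autumn so that a winter's cold
spells and their lagged deaths (lags of up to ~3 weeks are documented for
cold) sit on the same side of the boundary.

### Calendar

Weeks are 7 consecutive days numbered sequentially from the series start
date. A new analysis year begins with the first week whose start date falls
on or after 1 October; with a weekly cadence this start drifts within
1–7 October, and years naturally contain 52 or 53 weeks. Week 53, where it
occurs, is dropped before aggregation so that every year sums exactly
52 weeks (364 days). Annual exposure means are taken over exactly those 364
retained days, so outcome and exposure always cover identical days (the
alternative — averaging over all calendar days — would let dropped-week
weather influence an exposure that its deaths cannot influence). Truncated
years at either end of the series are excluded with a warning; a trailing
partial week is discarded. Missing temperatures are a hard error listing
the dates: imputation is an upstream decision.

### Exposures

Degree-days around a single threshold encode the V-shaped
temperature–mortality relation in one annual number per arm:
`cold_d = max(0, θ − T_d)`, `heat_d = max(0, T_d − θ)`, θ = 18 °C by
default (a consensus minimum-mortality temperature for temperate-maritime
cities; 15 and 21 °C are sensitivity variants). Annual cold/heat are means
of the daily values over the retained days.

### Annual model

Quasi-Poisson regression of annual deaths on annual cold and heat jointly,
with: a natural cubic spline in the year index at 1 df per decade of data
(5 df for a 57-year series — flexible enough to absorb population and
healthcare trends, stiff enough to leave interannual variation to the
exposures; behaves like a ~10-year moving average); the proportion of the
year's deaths coded to influenza (a conservative control — influenza may be
on the causal pathway from cold); and 0/1 step indicators from a given year
onward for administrative boundary or coding discontinuities. Dispersion is
estimated as Pearson χ²/(n − p); confidence intervals use z = 1.96 on the
log scale and are transformed to percent per °C. AIC is −2 logL + 2k on the
unscaled Poisson likelihood (k = mean-model terms; the NB shape adds one);
it is undefined for the log-scale OLS variant and reported as NA.

The spline basis is the truncated-power natural cubic construction with
boundary knots at the data extremes and interior knots at equally spaced
quantiles, giving the conventional knots-minus-one parameterisation
(6 knots ↔ 5 df); df = 1 degenerates to a linear trend, and every basis
column is exactly linear beyond the boundary knots.

### Weekly comparator

A conditional quasi-Poisson model on weekly counts, stratified by calendar
year × month of the week's start date, estimates the conventional
short-horizon association on the same data. Cold enters as the mean of the
daily cold-degrees over the index and previous week (14 days, reflecting
cold's lag); heat enters unlagged (heat effects appear within days). The
conditional likelihood (stratum totals conditioned out) is maximised by
Newton iteration with step-halving; its coefficients coincide with a
Poisson regression carrying one fixed effect per stratum, which the test
suite verifies to 1e-6 against an independent GLM fit. Singleton and
all-zero strata are dropped. Dispersion uses Pearson residuals around the
conditional fitted means `Y_s · softmax(X_s β)` with
df = n − #strata − #exposure terms. Note that weeks are not split at month
boundaries, so a stratum's weeks can extend a few days into the next month;
a confounder constant at the stratum level is still conditioned out exactly.

## The synthetic-data generator

Temperature: `T_d = a0 + a1·cos(2π(doy − phase)/365.25) + e_d` with AR(1)
anomalies (ρ = 0.8, σ = 2.2 °C, stationary start). Defaults a0 = 11 °C,
a1 = 7 °C, phase = day 201 give annual cold-degrees(18) averaging ≈7.4 °C
(range across years ≈6–9 °C) and annual heat-degrees ≈0.2–0.35 °C — a
temperate-maritime climate where cold-degrees are positive on ~89% of days
and hot days are scarce, which is what makes annual heat estimates
intrinsically imprecise.

Mortality, per day: baseline `m_d = b0·exp(trend + steps)`; attributable
excess `a_d = m_d·(exp(β_c·c̄_d + β_h·h̄_d + flu_d) − 1)` with c̄/h̄ trailing
lag-window means (14 d cold, 3 d heat) of the degree exposures; displaced
load `r_d = f·Σ_δ a_{d−δ}/D` (δ uniform on 1..D); rate
`λ_d = m_d + a_d − r_d`, floored at `0.1·m_d` with the shortfall carried
forward so displaced deaths are conserved exactly; deaths are Poisson draws,
or λ itself in expectation mode. Influenza epidemics are winter-peaked
Gaussian pulses of random size on the log scale; flu-coded deaths are drawn
from the flu share of the excess so the annual influenza proportion is
coherent with the planted inflation. Default acute effects
(β_cold = 0.014/°C, β_heat = 0.013/°C) bracket published daily-study values
for the same threshold; the validation scenarios use β_cold = 0.02/°C and
b0 = 170/day (≈62 000 deaths/year, a large-city all-cause stream).

Displacement is modelled at the rate level (deficit subtraction), not by an
individual frailty pool: it is exactly conservative, has a closed-form
ground truth (`net excess = (1 − f)·Σ a_d` up to the tail leaking past the
series end, which is logged), and suffices to exercise the estimators.

What the generator does *not* emulate: day-of-week and holiday structure,
reporting delays, demographic drift in the at-risk population, pollution
co-variation, or frailty heterogeneity. Passing recovery tests on this
generator therefore shows the estimators do what the design intends under
log-linear acute effects and additive displacement — not that any real
series is free of residual confounding.

## Known properties and limitations

* **Aggregation (Jensen) inflation.** Annual deaths aggregate
  `exp(β·exposure)` over days, so the annual model's estimand is
  `β + ½β²·dV/dC`, where V_t is the within-year variance of the lag-window
  exposure and dV/dC its regression on annual cold. In the default climate
  colder years are also more variable (dV/dC ≈ 3.4), inflating the annual
  estimand by ≈3.5% relative at β = 0.02 (predicted +0.00069, matching the
  measured expectation-mode bias exactly). Consequently 95% intervals centred
  on the annual estimate cover the acute β at ≈90% rather than 95% when
  counts are large enough that the bias is an appreciable fraction of the SE.
  This is a property of annual aggregation itself, not of the fitting code.
* **Weekly attenuation.** The weekly regressor (two-week cold mean aligned
  to week boundaries) is a smoothed proxy for the daily 14-day trailing
  exposure that drives deaths, so the weekly estimator recovers ~85–90% of
  the planted acute effect; its strength is precision, not exactness.
* **Displacement beyond a year.** With f = 1 and D = 400 days the annual
  estimate retains ≈55–60% of the acute truth (not less): because cold
  occurs year-round in this climate, excess arising late in the analysis
  year pushes most of its deficit past the year boundary. Attenuation below
  half would require winter-concentrated excess.
* The conditional-model stratum count, dispersion convention (Pearson), and
  CI multiplier (1.96, no small-sample correction) are conventional choices;
  alternatives would move third decimals, not conclusions.
* Numerical notes: Poisson/quasi-Poisson and NB fits run through IRLS
  (statsmodels) at tolerance 1e-10; the NB shape is profiled on log(α) by
  bounded 1-D maximisation, which is stable at the Poisson limit α → 0;
  the conditional Newton solver uses analytic score/Hessian with
  log-sum-exp stabilisation and step-halving, tolerance 1e-8 on the score.

## Problem sizes

Tests and the acceptance script simulate full 57-year daily series
(~20 800 days, ~3 000 weeks) for point estimates, 500 (tests) or 200
(script) replicates for coverage, and 15–40 replicates for Monte-Carlo
direction checks; the whole suite runs in well under a minute on one core.
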