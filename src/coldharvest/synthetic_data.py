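"""Synthetic daily temperature and mortality series with known ground truth.

The generator exists to validate the annual estimator's inferential logic:
acute temperature effects of known size are planted in a daily death series,
and a tunable fraction ``f`` of the temperature-attributable excess deaths is
*displaced* — subtracted from baseline mortality over the following ``D``
days.  With ``f = 0`` no lives are merely brought forward and both the annual
and the weekly estimator should recover the acute effect; with ``f = 1`` and a
short horizon (displacement within the analysis year) the annual estimator
should see almost nothing while the weekly estimator still sees the acute
effect — the contrast the annual design is built to expose.

Temperature is a seasonal cosine plus AR(1) noise, calibrated so that the
default 18 degC degree-day summaries resemble temperate-maritime (London-like)
values: annual cold-degrees averaging about 7.4 degC and annual heat-degrees
about 0.2 degC.

Displacement is modelled at the rate level: the expected deficit is the
convolution of past attributable excess with a uniform delay distribution on
1..D days.  The daily rate is floored at 10% of baseline, any shortfall being
carried to the next day, so displaced deaths are exactly conserved inside the
series; in expectation mode net attributable excess equals ``(1 - f)`` times
the planted excess up to the tail that leaks past the series end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


@dataclass
class TempSimConfig:
    """Seasonal AR(1) daily mean temperature model.

    T_d = a0 + a1 * cos(2*pi*(doy_d - phase)/365.25) + e_d,  e_d AR(1).

    Defaults give a temperate-maritime climate: with an 18 degC threshold the
    annual mean cold-degrees is ~7.4 degC and annual heat-degrees ~0.2 degC.
    """

    start: str = "1949-10-02"
    n_years: int = 57
    a0: float = 11.0  # annual mean level, degC
    a1: float = 7.0  # seasonal amplitude, degC
    phase: float = 201.0  # day-of-year of seasonal maximum (~20 July)
    rho: float = 0.8  # AR(1) coefficient of daily anomalies
    sigma: float = 2.2  # innovation SD, degC
    seed: int = 0

    def __post_init__(self):
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class HarvestConfig:
    """Acute temperature effects and the displacement mechanism.

    beta_cold / beta_heat are acute log-rates per degC, applied to the mean of
    the daily degree exposure over a trailing lag window (14 days for cold,
    3 for heat, reflecting the longer lag of cold effects).  A fraction ``f``
    of each day's attributable excess is displaced: subtracted from baseline
    over the following ``displacement_days`` days, uniformly.
    """

    beta_cold: float = 0.014
    beta_heat: float = 0.013
    lag_cold: int = 14
    lag_heat: int = 3
    displaced_fraction: float = 0.0
    displacement_days: int = 60

    def __post_init__(self):
        if not 0.0 <= self.displaced_fraction <= 1.0:
            raise ValueError("displaced fraction must be in [0, 1]")
        if self.displacement_days < 1 or self.lag_cold < 1 or self.lag_heat < 1:
            raise ValueError("displacement horizon and lag windows must be >= 1 day")


@dataclass
class MortSimConfig:
    """Daily mortality model around the temperature effects.

    baseline
        Expected deaths/day absent all effects (170/day is roughly 62k/year,
        a large-city all-cause stream).
    trend_log_range
        Total smooth secular change on the log scale across the series
        (a half-cosine; negative means declining mortality).
    steps
        (year_label, multiplicative factor) administrative jumps applied from
        the first day of that analysis year onward.
    flu
        Winter influenza epidemics: each year an epidemic of random size
        multiplies mortality around a mid-winter peak; flu-coded deaths are
        recorded so the annual influenza proportion can be formed.
    expectation_mode
        If True, return expected rates instead of Poisson draws.
    """

    baseline: float = 170.0
    trend_log_range: float = 0.0
    steps: tuple = ()  # ((year_label, factor), ...)
    flu_mean_size: float = 0.0  # mean peak log-rate increment of yearly epidemics
    flu_sd_size: float = 0.0
    flu_duration: float = 42.0  # SD (days) of the Gaussian epidemic pulse
    harvest: HarvestConfig = field(default_factory=HarvestConfig)
    seed: int = 0
    expectation_mode: bool = False


def simulate_temperature(config: TempSimConfig) -> pd.Series:
    """Simulate a daily mean temperature series; reproducible given the seed."""
    n_days = int(np.ceil(config.n_years * DAYS_PER_YEAR)) + 7
    dates = pd.date_range(config.start, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = config.a0 + config.a1 * np.cos(2 * np.pi * (doy - config.phase) / DAYS_PER_YEAR)
    rng = np.random.default_rng(config.seed)
    innov = rng.normal(0.0, config.sigma, n_days)
    noise = np.empty(n_days)
    # stationary start
    scale0 = 1.0 / np.sqrt(1 - config.rho**2) if config.sigma > 0 else 1.0
    noise[0] = innov[0] * scale0
    for d in range(1, n_days):
        noise[d] = config.rho * noise[d - 1] + innov[d]
    return pd.Series(seasonal + noise, index=dates, name="tmean")


def _trailing_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Mean of x over the trailing ``window`` days (shorter at the start)."""
    c = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    lo = np.maximum(np.arange(n) - window + 1, 0)
    return (c[np.arange(n) + 1] - c[lo]) / (np.arange(n) + 1 - lo)


def simulate_mortality(
    tmean: pd.Series,
    config: MortSimConfig,
    threshold: float = 18.0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate daily deaths over a temperature series; returns (daily, truth).

    Mechanism, per day d:

    * baseline  m_d = b0 * exp(trend_d + step_d)
    * excess    a_d = m_d * (exp(beta_c * cbar_d + beta_h * hbar_d + flu_d) - 1)
      with cbar/hbar the trailing lag-window means of cold-/heat-degrees
    * deficit   r_d = f * sum_delta a_{d-delta} / D  (delta = 1..D), floored so
      that m_d - r_d >= 0.1 m_d, the shortfall carried to the next day
    * rate      lambda_d = m_d + a_d - r_d
    * deaths ~ Poisson(lambda_d), or lambda_d itself in expectation mode.

    Influenza-coded deaths are drawn from the flu share of the excess so the
    annual influenza proportion covariate can be computed downstream.
    """
    hv = config.harvest
    n = len(tmean)
    if n <= hv.displacement_days:
        raise ValueError("series shorter than the displacement horizon")
    dates = tmean.index
    tm = tmean.to_numpy(dtype=float)
    cold = np.maximum(threshold - tm, 0.0)
    heat = np.maximum(tm - threshold, 0.0)
    cbar = _trailing_mean(cold, hv.lag_cold)
    hbar = _trailing_mean(heat, hv.lag_heat)

    rng = np.random.default_rng(config.seed)

    # smooth secular trend: half-cosine sweep over the series on the log scale
    u = np.arange(n) / max(n - 1, 1)
    trend = config.trend_log_range * 0.5 * (1 - np.cos(np.pi * u)) if config.trend_log_range else np.zeros(n)

    step_log = np.zeros(n)
    year_label = np.where(dates.month >= 10, dates.year, dates.year - 1)
    for year, factor in config.steps:
        step_log[year_label >= year] += np.log(factor)

    flu = np.zeros(n)
    if config.flu_mean_size > 0:
        years = np.unique(year_label)
        for year in years:
            size = max(rng.normal(config.flu_mean_size, config.flu_sd_size), 0.0)
            if size == 0.0:
                continue
            # epidemic peak mid-winter (early January of year+1), jittered
            peak = pd.Timestamp(year=year + 1, month=1, day=10) + pd.Timedelta(
                days=int(rng.integers(-20, 21))
            )
            offs = (dates - peak).days.to_numpy(dtype=float)
            flu += size * np.exp(-0.5 * (offs / config.flu_duration) ** 2)

    m = config.baseline * np.exp(trend + step_log)
    rel = np.exp(hv.beta_cold * cbar + hv.beta_heat * hbar + flu)
    a = m * (rel - 1.0)

    # displaced load: convolution of the excess with a uniform 1..D delay
    f, D = hv.displaced_fraction, hv.displacement_days
    lam = m + a
    deficit_applied = np.zeros(n)
    if f > 0:
        kernel = np.full(D, f / D)
        r = np.convolve(a, kernel)[:n]
        r = np.concatenate([[0.0], r[:-1]])  # delay starts at 1 day
        leaked = f * a.sum() - r.sum()
        if leaked > 0:
            logger.info("displacement tail beyond series end: %.1f expected deaths", leaked)
        # floor the deficit at 90% of baseline, carrying shortfall forward
        cap = 0.9 * m
        if np.any(r > cap):
            carry = 0.0
            for d in range(n):
                want = r[d] + carry
                take = min(want, cap[d])
                deficit_applied[d] = take
                carry = want - take
            if carry > 0:
                logger.info("deficit shortfall of %.1f deaths unapplied at series end", carry)
        else:
            deficit_applied = r
        lam = m + a - deficit_applied

    flu_excess = m * np.exp(hv.beta_cold * cbar + hv.beta_heat * hbar) * (np.exp(flu) - 1.0)
    flu_excess = np.minimum(flu_excess, lam)  # deficit cannot make flu exceed total

    if config.expectation_mode:
        deaths_flu = flu_excess
        deaths_all = lam
    else:
        deaths_flu = rng.poisson(flu_excess).astype(float)
        deaths_other = rng.poisson(np.maximum(lam - flu_excess, 0.0)).astype(float)
        deaths_all = deaths_flu + deaths_other

    daily = pd.DataFrame(
        {"tmean": tm, "deaths_all": deaths_all, "deaths_flu": deaths_flu}, index=dates
    )
    daily.index.name = "date"
    truth = {
        "beta_cold": hv.beta_cold,
        "beta_heat": hv.beta_heat,
        "lag_cold": hv.lag_cold,
        "lag_heat": hv.lag_heat,
        "displaced_fraction": f,
        "displacement_days": D,
        "threshold": threshold,
        "baseline": config.baseline,
        "trend_log_range": config.trend_log_range,
        "steps": [list(s) for s in config.steps],
        "expected_attributable_excess": float(a.sum()),
        "expected_net_excess": float(a.sum() - deficit_applied.sum()),
        "acute_cold_pct_per_degC": 100.0 * float(np.expm1(hv.beta_cold)),
        "acute_heat_pct_per_degC": 100.0 * float(np.expm1(hv.beta_heat)),
    }
    return daily, truth


def generate_dataset(
    temp_config: TempSimConfig,
    mort_config: MortSimConfig,
    out_csv=None,
    truth_json=None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate temperature + mortality; optionally write CSV and truth JSON.

    Output is byte-identical for a fixed pair of config seeds.
    """
    tmean = simulate_temperature(temp_config)
    daily, truth = simulate_mortality(tmean, mort_config)
    truth["temp_config"] = asdict(temp_config)
    truth["mort_seed"] = mort_config.seed
    truth["expectation_mode"] = mort_config.expectation_mode
    if out_csv is not None:
        daily.round(6).to_csv(out_csv, float_format="%.6f")
    if truth_json is not None:
        with open(truth_json, "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
    return daily, truth
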