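"""Primary analysis: annual quasi-Poisson regression of deaths on annual
cold- and heat-degrees, with spline trend, influenza and step adjustment,
plus the sensitivity grid over distributional family, spline flexibility,
extra steps, threshold and influenza control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import series_builder
from .glm_engine import FitResult, fit_loglinear, natural_spline_basis

logger = logging.getLogger(__name__)

EXPOSURE_TERMS = ("annual_cold", "annual_heat")


@dataclass
class AnnualModelConfig:
    """Configuration of the annual model; defaults reproduce the main model:
    18 degC threshold, 5-df natural-spline trend (one df per decade), influenza
    proportion covariate, and the administrative boundary step pair."""

    threshold: float = 18.0
    spline_df: int = 5
    family: str = "quasipoisson"
    include_flu: bool = True
    steps: tuple = (1965, 1966)
    extra_steps: tuple = ()
    stream: str = "deaths_all"

    @property
    def all_steps(self) -> tuple:
        return tuple(self.steps) + tuple(self.extra_steps)


def build_annual_design(
    annual: pd.DataFrame, config: AnnualModelConfig | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Assemble (response, design) for the annual model.

    Columns: intercept, annual_cold, annual_heat, spline basis of the year
    index, influenza proportion (if included), step indicators.
    """
    config = config or AnnualModelConfig()
    T = len(annual)
    n_terms = 3 + config.spline_df + int(config.include_flu) + len(config.all_steps)
    if T < n_terms + 3:
        raise ValueError(f"{T} years is too few for {n_terms} model terms")
    X = pd.DataFrame(index=annual.index)
    X["const"] = 1.0
    X["annual_cold"] = annual["annual_cold"].to_numpy()
    X["annual_heat"] = annual["annual_heat"].to_numpy()
    t = annual["year_index"].to_numpy(dtype=float)
    basis = natural_spline_basis(t, config.spline_df)
    for j in range(config.spline_df):
        X[f"spline_{j + 1}"] = basis[:, j]
    if config.include_flu:
        if "flu_prop" not in annual.columns:
            raise ValueError("annual table has no flu_prop column but include_flu=True")
        X["flu_prop"] = annual["flu_prop"].to_numpy()
    for y in config.all_steps:
        col = f"step_{y}"
        if col in annual.columns:
            X[col] = annual[col].to_numpy()
        else:
            X[col] = (annual["year_label"].to_numpy() >= y).astype(float)
    y = annual[config.stream].to_numpy(dtype=float)
    return y, X


def fit_annual(annual: pd.DataFrame, config: AnnualModelConfig | None = None) -> FitResult:
    """Fit the annual model; exposure effects are reported per degC of annual
    mean degree-days via ``FitResult.percent_increase``."""
    config = config or AnnualModelConfig()
    y, X = build_annual_design(annual, config)
    return fit_loglinear(y, X, family=config.family)


def annual_estimates(fit: FitResult) -> pd.DataFrame:
    """Cold/heat rows of a fitted annual (or weekly) model on the percent scale."""
    rows = []
    for term in fit.params.index:
        if term in ("annual_cold", "annual_heat", "week_cold_lagged", "week_heat"):
            pct, lo, hi = fit.percent_increase(term)
            rows.append({"term": term, "pct": pct, "pct_lo": lo, "pct_hi": hi})
    out = pd.DataFrame(rows)
    out["phi"] = fit.dispersion
    out["aic"] = fit.aic
    return out


def default_variants(config: AnnualModelConfig) -> list[tuple[str, AnnualModelConfig]]:
    """The sensitivity grid: alternative family, spline flexibility, extra
    steps, threshold, and influenza control, each a one-knob change from the
    main configuration."""
    return [
        ("main", config),
        ("simple_regression", replace(config, family="simple")),
        ("negative_binomial", replace(config, family="negbin")),
        ("spline_3knot_df2", replace(config, spline_df=2)),
        ("spline_9knot_df8", replace(config, spline_df=8)),
        ("threshold_15", replace(config, threshold=15.0)),
        ("threshold_21", replace(config, threshold=21.0)),
        ("no_influenza", replace(config, include_flu=False)),
    ]


def sensitivity_grid(
    daily: pd.DataFrame | None = None,
    annual: pd.DataFrame | None = None,
    config: AnnualModelConfig | None = None,
    variants: list[tuple[str, AnnualModelConfig]] | None = None,
    start_date=None,
) -> pd.DataFrame:
    """Run the sensitivity grid; one row per variant with cold and heat
    percent estimates and AIC.

    Threshold variants need the daily series (exposures are rebuilt); if only
    an annual table is supplied they are skipped with a warning.  Variants
    never alter the week/year calendar — only exposures and model terms.
    """
    config = config or AnnualModelConfig()
    if daily is None and annual is None:
        raise ValueError("need a daily or an annual table")
    variants = variants if variants is not None else default_variants(config)

    annual_cache: dict[float, pd.DataFrame] = {}

    def annual_for(threshold: float) -> pd.DataFrame:
        if threshold in annual_cache:
            return annual_cache[threshold]
        if daily is None:
            raise KeyError(threshold)
        _, tab = series_builder.build_tables(
            daily, start_date=start_date, threshold=threshold, steps=()
        )
        annual_cache[threshold] = tab
        return tab

    if annual is not None:
        annual_cache[config.threshold] = annual

    rows = []
    for label, vcfg in variants:
        try:
            tab = annual_for(vcfg.threshold)
        except KeyError:
            logger.warning("variant %s needs the daily series; skipped", label)
            continue
        try:
            fit = fit_annual(tab, vcfg)
        except ValueError as e:
            logger.warning("variant %s failed: %s", label, e)
            continue
        cold = fit.percent_increase("annual_cold")
        heat = fit.percent_increase("annual_heat")
        rows.append(
            {
                "variant": label,
                "cold_pct": cold[0],
                "cold_lo": cold[1],
                "cold_hi": cold[2],
                "heat_pct": heat[0],
                "heat_lo": heat[1],
                "heat_hi": heat[2],
                "aic": fit.aic,
            }
        )
    return pd.DataFrame(rows)
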