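"""Comparative conventional analysis: conditional quasi-Poisson regression of
weekly deaths on degree-day exposures, stratified by calendar year x month of
the week's start date (a time-stratified case-crossover).

Cold enters as the mean of daily cold-degrees over the index week and the
previous one (a two-week window, reflecting the lag of cold effects on
mortality); heat enters unlagged, its effects appearing within days.  The
stratification absorbs seasonality, secular trend, influenza winters and
administrative steps, so the model needs no further covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .glm_engine import FitResult, fit_conditional_poisson

EXPOSURES = ("week_cold_lagged", "week_heat")


def build_weekly_design(
    weeks: pd.DataFrame, stream: str = "deaths_all"
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """(response, exposures, strata) for the weekly conditional model.

    The first week of the series has no lagged cold value and is dropped.
    """
    usable = weeks[np.isfinite(weeks["week_cold_lagged"])]
    y = usable[stream].to_numpy(dtype=float)
    X = usable[list(EXPOSURES)].astype(float)
    strata = usable["stratum"].to_numpy()
    return y, X, strata


def fit_weekly(weeks: pd.DataFrame, stream: str = "deaths_all") -> FitResult:
    """Fit the month-stratified conditional quasi-Poisson weekly model."""
    y, X, strata = build_weekly_design(weeks, stream)
    return fit_conditional_poisson(y, X, strata)
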