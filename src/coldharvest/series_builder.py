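"""Build weekly and annual analysis tables from a daily mortality/temperature series.

The analysis calendar is anchored in autumn: weeks of seven consecutive days
are numbered sequentially from a start date (an early-October Sunday in the
London application), grouped into analysis years that begin with the first
week starting on or after 1 October, and any 53rd week in a year is dropped so
that every analysis year covers exactly 52 weeks (364 days).  Exposures are
degree-day summaries around a common cold/heat threshold: for each day,
``cold_degrees = max(0, threshold - tmean)`` and
``heat_degrees = max(0, tmean - threshold)``.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Minimum-mortality temperature used as the common cold/heat threshold (degC).
DEFAULT_THRESHOLD = 18.0

#: Death-count columns recognised in daily input CSVs, in reporting order.
DEATH_STREAMS = (
    "deaths_all",
    "deaths_cvd",
    "deaths_resp",
    "deaths_65plus",
    "deaths_under65",
)
FLU_COLUMN = "deaths_flu"


class MissingTemperatureError(ValueError):
    """Raised when the daily temperature series has missing values."""

    def __init__(self, dates: Sequence[pd.Timestamp]):
        self.dates = list(dates)
        preview = ", ".join(str(d.date()) for d in self.dates[:10])
        more = "" if len(self.dates) <= 10 else f" (+{len(self.dates) - 10} more)"
        super().__init__(
            f"{len(self.dates)} day(s) with missing mean temperature: {preview}{more}. "
            "Impute upstream; no silent imputation is performed."
        )


def read_daily_csv(path) -> pd.DataFrame:
    """Read a daily series CSV with columns ``date,tmean,deaths_all[,...]``.

    Returns a frame indexed by date.  Validates that dates are strictly
    consecutive, death counts are non-negative, and (when present)
    influenza-coded deaths never exceed all-cause deaths.
    """
    daily = pd.read_csv(path, parse_dates=["date"]).set_index("date")
    validate_daily(daily)
    return daily


def validate_daily(daily: pd.DataFrame) -> None:
    if "tmean" not in daily.columns or "deaths_all" not in daily.columns:
        raise ValueError("daily series must have 'tmean' and 'deaths_all' columns")
    if len(daily) == 0:
        raise ValueError("daily series is empty")
    expected = pd.date_range(daily.index[0], daily.index[-1], freq="D")
    if not daily.index.equals(expected):
        raise ValueError("daily series dates must be strictly consecutive with no gaps")
    streams = [c for c in daily.columns if c.startswith("deaths")]
    for c in streams:
        if (daily[c].dropna() < 0).any():
            raise ValueError(f"negative death counts in column {c!r}")
    if FLU_COLUMN in daily.columns:
        if (daily[FLU_COLUMN] > daily["deaths_all"] + 1e-9).any():
            raise ValueError("influenza deaths exceed all-cause deaths on some days")


def compute_degree_exposures(tmean: pd.Series, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Daily cold-degrees and heat-degrees around a common threshold.

    Parameters
    ----------
    tmean
        Daily mean temperature (degC), indexed by date.
    threshold
        Apex of the V-shaped temperature-mortality relation (degC).

    Returns
    -------
    DataFrame with columns ``cold_degrees`` and ``heat_degrees``; for every day
    the two are non-negative, at most one is nonzero, and they sum to
    ``|tmean - threshold|``.

    Raises
    ------
    MissingTemperatureError
        If any day has a missing temperature (dates are listed).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    missing = tmean.index[~np.isfinite(tmean.to_numpy(dtype=float, na_value=np.nan))]
    if len(missing):
        raise MissingTemperatureError(missing)
    delta = tmean.astype(float) - float(threshold)
    return pd.DataFrame(
        {"cold_degrees": np.maximum(-delta, 0.0), "heat_degrees": np.maximum(delta, 0.0)},
        index=tmean.index,
    )


def build_weeks(
    daily: pd.DataFrame,
    start_date,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Collapse a daily series into sequential 7-day weeks from ``start_date``.

    Each week row carries summed death counts for every ``deaths_*`` column,
    the week mean of daily cold-/heat-degrees, the two-week lagged cold mean
    (mean of the 14 daily cold values of this week and the previous one; NaN
    for the first week), and a ``stratum`` label ``YYYY-MM`` taken from the
    week's start date.  A trailing partial week is discarded.
    """
    start = pd.Timestamp(start_date)
    if start < daily.index[0]:
        raise ValueError("start_date precedes the daily series")
    sub = daily.loc[start:]
    n_weeks = len(sub) // 7
    if n_weeks < 1:
        raise ValueError("daily series covers less than one week from start_date")
    n_discard = len(sub) - 7 * n_weeks
    if n_discard:
        logger.warning("discarding %d trailing day(s) not forming a complete week", n_discard)
    sub = sub.iloc[: 7 * n_weeks]

    expo = compute_degree_exposures(sub["tmean"], threshold)
    starts = sub.index[::7]

    out = pd.DataFrame({"week_index": np.arange(1, n_weeks + 1), "start_date": starts})
    for c in sub.columns:
        if c.startswith("deaths"):
            out[c] = np.add.reduceat(sub[c].to_numpy(dtype=float), np.arange(0, 7 * n_weeks, 7))
    cold = np.add.reduceat(expo["cold_degrees"].to_numpy(), np.arange(0, 7 * n_weeks, 7)) / 7.0
    heat = np.add.reduceat(expo["heat_degrees"].to_numpy(), np.arange(0, 7 * n_weeks, 7)) / 7.0
    out["week_cold"] = cold
    out["week_heat"] = heat
    # 14-day mean over this week and the previous one; the two 7-day means
    # have equal weight so the average of weekly means is exact.
    lagged = np.full(n_weeks, np.nan)
    lagged[1:] = (cold[1:] + cold[:-1]) / 2.0
    out["week_cold_lagged"] = lagged
    out["stratum"] = [f"{d.year}-{d.month:02d}" for d in starts]
    return out


def assign_years(weeks: pd.DataFrame) -> pd.DataFrame:
    """Label each week with its autumn-anchored analysis year.

    A new analysis year begins at the first week whose start date falls on or
    after 1 October; the year is labelled by that starting calendar year.
    Weeks are numbered 1.. within each year; years naturally contain 52 or 53
    weeks.
    """
    weeks = weeks.copy()
    starts = pd.DatetimeIndex(weeks["start_date"])
    labels = np.where(starts.month >= 10, starts.year, starts.year - 1)
    weeks["year_label"] = labels
    weeks["week_in_year"] = weeks.groupby("year_label").cumcount() + 1
    return weeks


def make_step_indicators(year_labels: Sequence[int], step_years: Iterable[int]) -> pd.DataFrame:
    """Indicator matrix of administrative/coding discontinuities.

    Column ``step_<y>`` is 0 for analysis years before ``y`` and 1 from ``y``
    onward.  A step at the first year is retained but flagged, since it is
    collinear with the intercept.
    """
    years = np.asarray(year_labels)
    step_years = list(step_years)
    if len(step_years) != len(set(step_years)):
        raise ValueError("duplicate step years")
    out = pd.DataFrame(index=pd.Index(years, name="year_label"))
    for y in step_years:
        col = (years >= y).astype(float)
        if col.all():
            warnings.warn(
                f"step at first year {y} is collinear with the intercept", stacklevel=2
            )
        out[f"step_{y}"] = col
    return out


def aggregate_annual(
    weeks: pd.DataFrame,
    steps: Iterable[int] = (),
    flu_annual: pd.Series | None = None,
) -> pd.DataFrame:
    """Aggregate year-labelled weeks into the annual analysis table.

    Week 53 of any year is dropped first, so each retained year sums exactly
    52 weeks (364 days).  Annual cold/heat are the means of the daily degree
    exposures over those 364 days; the influenza proportion divides
    influenza-coded deaths by all-cause deaths over the same days.  Years with
    fewer than 52 weeks (truncated series ends) are excluded with a warning.

    Parameters
    ----------
    weeks
        Output of :func:`assign_years`.
    steps
        Analysis-year labels at which step indicators switch on.
    flu_annual
        Optional pre-computed annual influenza proportion (indexed by
        year_label); overrides computation from ``deaths_flu``.
    """
    if "year_label" not in weeks.columns:
        raise ValueError("run assign_years before aggregate_annual")
    kept = weeks[weeks["week_in_year"] <= 52]
    counts = kept.groupby("year_label").size()
    short = counts[counts < 52].index.tolist()
    if short:
        logger.warning("excluding %d year(s) with <52 weeks: %s", len(short), short)
    full_years = counts[counts == 52].index
    kept = kept[kept["year_label"].isin(full_years)]

    g = kept.groupby("year_label")
    annual = pd.DataFrame(index=full_years)
    for c in kept.columns:
        if c.startswith("deaths"):
            annual[c] = g[c].sum()
    annual["annual_cold"] = g["week_cold"].mean()  # equal 7-day weeks: mean of means is exact
    annual["annual_heat"] = g["week_heat"].mean()
    if flu_annual is not None:
        annual["flu_prop"] = flu_annual.reindex(annual.index)
    elif FLU_COLUMN in kept.columns:
        annual["flu_prop"] = annual[FLU_COLUMN] / annual["deaths_all"]
    steps = list(steps)
    if steps:
        ind = make_step_indicators(annual.index.to_numpy(), steps)
        annual = pd.concat([annual, ind], axis=1)
    annual.index.name = "year_label"
    annual = annual.reset_index()
    annual.insert(0, "year_index", np.arange(1, len(annual) + 1))
    return annual


def build_tables(
    daily: pd.DataFrame,
    start_date=None,
    threshold: float = DEFAULT_THRESHOLD,
    steps: Iterable[int] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily frame -> (weekly table, annual table) in one call.

    ``start_date`` defaults to the first day of the series.
    """
    if start_date is None:
        start_date = daily.index[0]
    weeks = assign_years(build_weeks(daily, start_date, threshold))
    annual = aggregate_annual(weeks, steps=steps)
    return weeks, annual
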