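"""Spatio-temporal aggregation of gridded pollutant concentrations.

Modelled concentrations live on a regular grid (12 km in the study this
package was built around), while the health data live on irregular areal
units; a representative concentration per area and month must therefore be
constructed.  Crossing a spatial summary over the grid cells inside an area
(mean or max) with a temporal summary over the days in a month (monthly
mean of daily means, or monthly mean of daily maxima) gives four metrics:

    mean_s.mean_t   mean_s.max_t   max_s.mean_t   max_s.max_t

Note that ``max_t`` is the monthly MEAN of the daily MAXIMA — both daily
summaries are averaged over the days of the month; the max/mean distinction
at the temporal level is within-day.

Health effects are reported per one standard deviation of the metric over
the whole K x T panel, so standardisation stores the SD it divides by.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "METRICS",
    "hourly_to_daily",
    "daily_to_monthly",
    "spatial_aggregate",
    "aggregate_metrics",
    "standardize_metric",
]

METRICS = ("mean_s.mean_t", "mean_s.max_t", "max_s.mean_t", "max_s.max_t")


def hourly_to_daily(hourly: pd.DataFrame) -> pd.DataFrame:
    """Daily mean and daily maximum per cell from hourly concentrations.

    Parameters
    ----------
    hourly : DataFrame with columns (cell_id, pollutant, time, value);
        ``time`` must be datetime-like, ``value`` in ug m^-3.

    Returns
    -------
    DataFrame (cell_id, pollutant, date, daily_mean, daily_max).
    """
    df = hourly.copy()
    vals = df["value"].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)):
        raise ValueError("non-finite hourly concentration")
    if np.any(vals < 0):
        raise ValueError("negative hourly concentration")
    df["date"] = pd.to_datetime(df["time"]).dt.normalize()
    out = (
        df.groupby(["cell_id", "pollutant", "date"], observed=True)["value"]
        .agg(daily_mean="mean", daily_max="max")
        .reset_index()
    )
    return out


def _month_indexer(dates: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Map dates to contiguous 1-based month indices (and calendar months)."""
    d = pd.to_datetime(dates)
    code = d.dt.year * 12 + (d.dt.month - 1)
    idx = (code - code.min() + 1).to_numpy()
    return idx, d.dt.month.to_numpy()


def daily_to_monthly(daily: pd.DataFrame) -> pd.DataFrame:
    """Per-cell monthly temporal summaries.

    Both daily summaries are aggregated by the arithmetic mean over the
    days present in each month: ``mean_t`` is the monthly mean of daily
    means, ``max_t`` the monthly mean of daily maxima.

    Returns DataFrame (cell_id, pollutant, month_index, calendar_month,
    mean_t, max_t).  Month indices are 1-based and contiguous from the
    earliest month in the data.
    """
    dm = daily["daily_mean"].to_numpy(dtype=float)
    dx = daily["daily_max"].to_numpy(dtype=float)
    if len(daily) == 0:
        raise ValueError("empty daily table")
    if np.any(dx < dm - 1e-12):
        raise ValueError("daily_max < daily_mean for some cell-day")
    df = daily.copy()
    df["month_index"], df["calendar_month"] = _month_indexer(df["date"])
    out = (
        df.groupby(["cell_id", "pollutant", "month_index", "calendar_month"], observed=True)
        .agg(mean_t=("daily_mean", "mean"), max_t=("daily_max", "mean"))
        .reset_index()
    )
    return out


def spatial_aggregate(
    cell_monthly: pd.DataFrame,
    cell_map: pd.DataFrame,
    mode: str,
) -> pd.DataFrame:
    """Aggregate per-cell monthly summaries to areas (spatial mean or max).

    Cells not present in ``cell_map`` are silently dropped; an area in the
    map with no cell values is an error.

    Parameters
    ----------
    cell_monthly : output of :func:`daily_to_monthly`.
    cell_map : DataFrame (cell_id, area_id); each cell maps to one area.
    mode : "mean" or "max".

    Returns DataFrame (area_id, month_index, calendar_month, pollutant,
    mean_t, max_t) where the temporal summaries have been aggregated over
    the area's cells with the requested spatial statistic.
    """
    if mode not in ("mean", "max"):
        raise ValueError("mode must be 'mean' or 'max'")
    if cell_map.groupby("cell_id", observed=True)["area_id"].nunique().gt(1).any():
        raise ValueError("a grid cell may map to exactly one area")
    merged = cell_monthly.merge(cell_map[["cell_id", "area_id"]], on="cell_id", how="inner")
    present = set(merged["area_id"].unique())
    for a in cell_map["area_id"].unique():
        if a not in present:
            raise ValueError(f"area {a!r} has no mapped grid cells with data")
    out = (
        merged.groupby(
            ["area_id", "month_index", "calendar_month", "pollutant"], observed=True
        )
        .agg(mean_t=("mean_t", mode), max_t=("max_t", mode))
        .reset_index()
    )
    return out


def aggregate_metrics(daily: pd.DataFrame, cell_map: pd.DataFrame) -> pd.DataFrame:
    """All four area-month aggregation metrics from daily gridded data.

    Returns a long DataFrame (area_id, month_index, calendar_month,
    pollutant, metric_name, value) with one row per metric.
    """
    cm = daily_to_monthly(daily)
    frames = []
    for smode, sname in (("mean", "mean_s"), ("max", "max_s")):
        agg = spatial_aggregate(cm, cell_map, smode)
        for tcol, tname in (("mean_t", "mean_t"), ("max_t", "max_t")):
            f = agg[["area_id", "month_index", "calendar_month", "pollutant"]].copy()
            f["metric_name"] = f"{sname}.{tname}"
            f["value"] = agg[tcol].to_numpy()
            frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["pollutant", "metric_name", "area_id", "month_index"], ignore_index=True
    )


def standardize_metric(values) -> tuple[np.ndarray, float]:
    """Centre and scale a metric panel; return (standardised values, SD).

    The SD is the population (ddof = 0) standard deviation over the full
    K x T panel, stored so that regression coefficients on the standardised
    scale read directly as log relative risks per 1-SD increase.
    """
    x = np.asarray(values, dtype=float).reshape(-1)
    if np.unique(x).size < 2:
        raise ValueError("metric has fewer than 2 distinct values (zero variance)")
    sd = float(np.std(x))
    if sd == 0.0:
        raise ValueError("metric has zero variance")
    return (x - x.mean()) / sd, sd
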