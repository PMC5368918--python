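"""Indirect standardisation, seasonal correction and SMRs.

Expected admission counts are built by indirect standardisation: national
stratum-specific rates gamma_r (admissions per person per month) applied to
the local age-sex stratum populations,

    E_kt = sum_r N_ktr * gamma_r .

The standardised morbidity ratio SMR_kt = Y_kt / E_kt is the exploratory
risk measure: an SMR of 1.2 is a 20% excess risk relative to the national
average.  A monthly correction factor (national observed/expected ratio per
calendar month) can be folded into E to make it seasonal, so that the SMR
measures departure from the typical seasonal profile rather than from the
annual average.

All tables are long-format pandas DataFrames; see the column-name constants
below for the schemas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "compute_strata_rates",
    "compute_expected_counts",
    "seasonal_adjust_expected",
    "compute_smr",
    "validate_panel",
]

#: required columns of a strata population table
POP_COLUMNS = ("area_id", "month_index", "stratum_id", "population")
#: required columns of an area-month panel
PANEL_COLUMNS = ("area_id", "month_index", "calendar_month", "observed", "expected")


def _as_counts_frame(strata_counts) -> pd.DataFrame:
    if isinstance(strata_counts, pd.Series):
        return strata_counts.rename("count").rename_axis("stratum_id").reset_index()
    df = pd.DataFrame(strata_counts)
    if not {"stratum_id", "count"}.issubset(df.columns):
        raise ValueError("strata counts need columns 'stratum_id' and 'count'")
    return df[["stratum_id", "count"]]


def compute_strata_rates(strata_counts, strata_pop: pd.DataFrame) -> pd.DataFrame:
    """National stratum-specific rates gamma_r = total admissions / person-months.

    Parameters
    ----------
    strata_counts : DataFrame with columns (stratum_id, count) or Series
        Total admissions per stratum, summed over all areas and months.
    strata_pop : DataFrame with columns (area_id, month_index, stratum_id,
        population).

    Returns
    -------
    DataFrame with columns (stratum_id, rate).
    """
    counts = _as_counts_frame(strata_counts)
    if np.any(counts["count"].to_numpy() < 0):
        raise ValueError("admission counts must be non-negative")
    if np.any(strata_pop["population"].to_numpy() < 0):
        raise ValueError("populations must be non-negative")
    pop = strata_pop.groupby("stratum_id", observed=True)["population"].sum()
    merged = counts.set_index("stratum_id").join(pop, how="left")
    missing = merged.index[merged["population"].isna()]
    if len(missing):
        raise ValueError(f"stratum {missing[0]!r} has no population rows")
    zero = merged.index[merged["population"] == 0]
    if len(zero):
        raise ValueError(f"stratum {zero[0]!r} has zero total population")
    rates = (merged["count"] / merged["population"]).rename("rate")
    return rates.reset_index()


def compute_expected_counts(strata_pop: pd.DataFrame, rates: pd.DataFrame) -> pd.DataFrame:
    """Indirectly standardised expected counts E_kt = sum_r N_ktr gamma_r.

    Returns a DataFrame (area_id, month_index, expected).  When the rates
    were estimated from the same data, sum_kt E_kt = sum_kt Y_kt (the
    standardisation calibration identity).
    """
    rate_map = rates.set_index("stratum_id")["rate"]
    strata = pd.Index(strata_pop["stratum_id"].unique())
    missing = strata.difference(rate_map.index)
    if len(missing):
        raise ValueError(f"no rate supplied for stratum {missing[0]!r}")
    r = strata_pop["stratum_id"].map(rate_map).to_numpy(dtype=float)
    contrib = strata_pop.assign(_e=strata_pop["population"].to_numpy(dtype=float) * r)
    out = (
        contrib.groupby(["area_id", "month_index"], observed=True, sort=True)["_e"]
        .sum()
        .rename("expected")
        .reset_index()
    )
    return out


def seasonal_adjust_expected(panel: pd.DataFrame) -> pd.DataFrame:
    """Apply the monthly seasonal correction to the expected counts.

    The correction factor for calendar month m is the national ratio
    f_m = (sum of Y over cells in month m) / (sum of E), and E*_kt =
    f_m(k,t) E_kt.  Afterwards each calendar month's total expected count
    equals its total observed count, and the grand total is preserved
    (sum E* = sum Y).  The operation is idempotent.
    """
    panel = panel.copy()
    g = panel.groupby("calendar_month", observed=True)
    totals = g.agg(y=("observed", "sum"), e=("expected", "sum"))
    bad = totals.index[totals["e"] <= 0]
    if len(bad):
        raise ValueError(f"calendar month {bad[0]} has non-positive total expected count")
    factors = totals["y"] / totals["e"]
    panel["expected"] = panel["expected"].to_numpy(dtype=float) * panel[
        "calendar_month"
    ].map(factors).to_numpy(dtype=float)
    return panel


def compute_smr(panel: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardised morbidity ratios SMR_kt = Y_kt / E_kt.

    Returns
    -------
    smr : DataFrame (area_id, month_index, smr)
    area_mean : DataFrame (area_id, smr_mean) — time-averaged SMR per area,
        the quantity usually mapped.
    """
    e = panel["expected"].to_numpy(dtype=float)
    if np.any(e <= 0):
        k = panel.loc[e <= 0, "area_id"].iloc[0]
        raise ValueError(f"non-positive expected count (area {k!r})")
    smr = panel[["area_id", "month_index"]].copy()
    smr["smr"] = panel["observed"].to_numpy(dtype=float) / e
    area_mean = (
        smr.groupby("area_id", observed=True)["smr"].mean().rename("smr_mean").reset_index()
    )
    return smr, area_mean


def validate_panel(panel: pd.DataFrame) -> None:
    """Check the area-month panel invariants; raise ValueError on failure.

    A valid panel has the required columns, a complete K x T rectangle with
    contiguous 1-based month indices, non-negative integer observed counts
    and strictly positive expected counts.
    """
    for col in PANEL_COLUMNS:
        if col not in panel.columns:
            raise ValueError(f"panel is missing required column '{col}'")
    obs = panel["observed"].to_numpy()
    if np.any(obs < 0):
        row = int(np.flatnonzero(obs < 0)[0])
        raise ValueError(f"negative observed count at row {row}")
    if not np.allclose(obs, np.round(obs)):
        row = int(np.flatnonzero(~np.isclose(obs, np.round(obs)))[0])
        raise ValueError(f"non-integer observed count at row {row}")
    if np.any(panel["expected"].to_numpy(dtype=float) <= 0):
        row = int(np.flatnonzero(panel["expected"].to_numpy(dtype=float) <= 0)[0])
        raise ValueError(f"non-positive expected count at row {row}")
    months = np.sort(panel["month_index"].unique())
    T = len(months)
    if not np.array_equal(months, np.arange(1, T + 1)):
        raise ValueError("month_index must be contiguous 1..T")
    cm = panel["calendar_month"].to_numpy()
    if np.any((cm < 1) | (cm > 12)):
        raise ValueError("calendar_month must lie in 1..12")
    counts = panel.groupby(["area_id", "month_index"], observed=True).size()
    if (counts != 1).any():
        cell = counts.index[(counts != 1).to_numpy().argmax()]
        raise ValueError(f"duplicate panel cell {cell}")
    areas = panel["area_id"].nunique()
    if len(panel) != areas * T:
        by_area = panel.groupby("area_id", observed=True)["month_index"].apply(set)
        full = set(range(1, T + 1))
        for a, s in by_area.items():
            miss = full - s
            if miss:
                raise ValueError(f"panel cell (area {a!r}, month {min(miss)}) is missing")
        raise ValueError("panel is not a complete K x T rectangle")
    if areas < 2:
        raise ValueError("panel needs at least 2 areas")
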