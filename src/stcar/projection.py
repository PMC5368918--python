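"""Attributable-burden projection under alternative concentration scenarios.

Given the fitted present-day pollution coefficient beta^(p) and a paired
panel of present (x) and future (z) concentrations per area-month, the
relative risk of admission comparing the two eras is

    RR_kt = exp( (z_kt - x_kt) * beta^(p) ),

with socio-economic and temperature covariates (and the random effects,
which cancel in the ratio) held at their present-day values.  The annual
average change in admissions over the study window of n_years years is

    n_hat = (1 / n_years) * sum_k sum_t (RR_kt - 1) * Y_kt ,

negative when the future scenario is cleaner.  Because Table-style
reporting counts *reductions* as positive numbers, results also expose the
``reductions`` view -n_hat.  Uncertainty propagates by pushing every
retained posterior draw of beta^(p) through the two formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProjectionResult",
    "relative_risk_change",
    "attributable_change",
    "percent_of_present",
    "emissions_percent",
    "project_scenario",
]

SCENARIO_COLUMNS = ("area_id", "month_index", "present_value", "future_value", "observed")


@dataclass
class ProjectionResult:
    """Posterior summary of the projected change in admissions.

    n_hat_draws : one draw of the annual change per posterior coefficient
        draw (admissions/year; negative = fewer future admissions).
    per_area_draws : (n_draws, K) per-area annual changes, which sum across
        areas to n_hat_draws draw by draw.
    """

    n_hat_draws: np.ndarray
    per_area_draws: np.ndarray
    area_ids: list
    n_years: float

    @property
    def n_hat(self) -> float:
        """Posterior median annual change in admissions."""
        return float(np.median(self.n_hat_draws))

    @property
    def ci(self) -> tuple:
        return (
            float(np.quantile(self.n_hat_draws, 0.025)),
            float(np.quantile(self.n_hat_draws, 0.975)),
        )

    @property
    def reductions(self) -> float:
        """Median annual number of *reduced* admissions (positive = fewer)."""
        return -self.n_hat

    @property
    def reductions_ci(self) -> tuple:
        lo, hi = self.ci
        return (-hi, -lo)

    @property
    def per_area_annual(self) -> pd.Series:
        """Posterior median annual change per area."""
        return pd.Series(
            np.median(self.per_area_draws, axis=0), index=self.area_ids, name="annual_change"
        )

    def percent_of_present(self, mean_annual_admissions: float) -> float:
        return percent_of_present(self.reductions, mean_annual_admissions)


def _sorted_scenario(scenario: pd.DataFrame) -> pd.DataFrame:
    for col in SCENARIO_COLUMNS:
        if col not in scenario.columns:
            raise ValueError(f"scenario is missing required column '{col}'")
    counts = scenario.groupby(["area_id", "month_index"], observed=True).size()
    if (counts != 1).any():
        raise ValueError("scenario has duplicate (area, month) cells")
    K = scenario["area_id"].nunique()
    T = int(scenario["month_index"].max())
    if len(scenario) != K * T:
        raise ValueError("scenario is not a complete K x T rectangle")
    return scenario.sort_values(["area_id", "month_index"], ignore_index=True)


def relative_risk_change(
    scenario: pd.DataFrame,
    beta_draws: np.ndarray,
    *,
    per_sd: bool = False,
    sd_units: float | None = None,
) -> tuple[np.ndarray, list]:
    """Relative-risk draws per area-month comparing future to present.

    Parameters
    ----------
    scenario : DataFrame with columns (area_id, month_index, present_value,
        future_value, observed); concentrations on the raw ug m^-3 scale.
    beta_draws : coefficient draws.  If ``per_sd`` is True they are per-SD
        log relative risks and ``sd_units`` (the stored panel SD) is
        required to convert them to the per-unit scale.

    Returns
    -------
    rr : ndarray (n_draws, K, T) with RR = exp((z - x) beta); identically 1
        wherever the future equals the present.
    area_ids : row order of the K axis.
    """
    beta_draws = np.atleast_1d(np.asarray(beta_draws, dtype=float))
    if per_sd:
        if sd_units is None:
            raise ValueError("per-SD coefficient draws need sd_units to rescale")
        beta_draws = beta_draws / float(sd_units)
    s = _sorted_scenario(scenario)
    K = s["area_id"].nunique()
    T = int(s["month_index"].max())
    delta = (
        s["future_value"].to_numpy(dtype=float) - s["present_value"].to_numpy(dtype=float)
    ).reshape(K, T)
    rr = np.exp(beta_draws[:, None, None] * delta[None, :, :])
    area_ids = list(s["area_id"].unique())
    return rr, area_ids


def attributable_change(
    rr_draws: np.ndarray,
    observed: np.ndarray,
    n_years: float,
    area_ids: list | None = None,
) -> ProjectionResult:
    """Annual change in admissions n_hat = (1/n_years) sum (RR - 1) Y.

    ``rr_draws`` has shape (n_draws, K, T) and ``observed`` shape (K, T);
    the per-area decomposition applies the same formula restricted to each
    area, so per-area draws sum exactly to the national draw.
    """
    rr_draws = np.asarray(rr_draws, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if rr_draws.ndim != 3 or rr_draws.shape[1:] != observed.shape:
        raise ValueError(
            f"shape mismatch: rr draws {rr_draws.shape} vs observed {observed.shape}"
        )
    if n_years <= 0:
        raise ValueError("n_years must be positive")
    per_area = np.sum((rr_draws - 1.0) * observed[None, :, :], axis=2) / n_years
    n_hat = per_area.sum(axis=1)
    ids = list(area_ids) if area_ids is not None else list(range(observed.shape[0]))
    return ProjectionResult(n_hat, per_area, ids, float(n_years))


def percent_of_present(n_hat_reductions: float, mean_annual_admissions: float) -> float:
    """Reduction as a percentage of present-day annual admissions (1 dp)."""
    if mean_annual_admissions <= 0:
        raise ValueError("mean annual admissions must be positive")
    return round(100.0 * n_hat_reductions / mean_annual_admissions, 1)


def emissions_percent(future_total: float, present_total: float) -> float:
    """Future emission total as a percentage of the present-day total (2 dp)."""
    if present_total <= 0:
        raise ValueError("present-day emission total must be positive")
    return round(100.0 * future_total / present_total, 2)


def project_scenario(results, scenario: pd.DataFrame, covariate: str, n_years=None):
    """Push a fitted model's posterior coefficient through a scenario.

    ``results`` is an :class:`stcar.model.STCARResults`; the coefficient
    draws for ``covariate`` are per-SD (covariates enter standardised) and
    are rescaled by the SD stored in the design.  ``n_years`` defaults to
    T / 12.
    """
    sd = results.design_info.sd_used.get(covariate)
    if sd is None:
        raise ValueError(f"{covariate!r} has no stored SD (not a linear term)")
    draws = results.beta_draws(covariate)
    rr, area_ids = relative_risk_change(scenario, draws, per_sd=True, sd_units=sd)
    s = _sorted_scenario(scenario)
    K, T = len(area_ids), int(s["month_index"].max())
    y = s["observed"].to_numpy(dtype=float).reshape(K, T)
    if n_years is None:
        n_years = T / 12.0
    return attributable_change(rr, y, n_years, area_ids)
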