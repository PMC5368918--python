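"""Bayesian Poisson log-linear disease model with spatio-temporal CAR effects.

The model for observed counts Y_kt in area k and month t, with indirectly
standardised expected counts E_kt as offsets, is

    Y_kt | E_kt, R_kt ~ Poisson(E_kt R_kt),
    ln(R_kt) = x_kt' beta + phi_kt,

where x_kt collects the covariates (a pollution metric, temperature, and
natural cubic splines of the deprivation proxies) and phi_kt is a
spatio-temporal random effect following a multivariate first-order
autoregressive Gaussian Markov random field:

    phi_1 ~ N(0, tau^2 Q(W, rho)^{-1}),
    phi_t | phi_{t-1} ~ N(gamma phi_{t-1}, tau^2 Q(W, rho)^{-1}),

with the Leroux precision Q(W, rho) = rho[diag(W1) - W] + (1 - rho)I.
gamma in [0, 1] is the temporal autocorrelation, rho in [0, 1] the spatial
dependence, tau^2 > 0 the conditional variance.  Optionally the adjacency
weights w_kj of neighbouring pairs are themselves estimated (adaptive
smoothing), allowing the field to stop smoothing across some borders.

Inference is by Metropolis-within-Gibbs MCMC (see :mod:`stcar.sampler`).
Continuous covariates are centred and scaled by their panel standard
deviation before fitting, so each coefficient is a log relative risk per
1-SD increase of its covariate, matching the usual reporting convention.

Usage follows the model/results pattern::

    model = STCARModel(panel, adjacency, spec)
    res = model.fit()
    res.summary()
    res.rr_summary("pollution")
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import gammaln

from .adjacency import AdjacencyStructure, build_precision
from .areal import validate_panel
from .splines import natural_cubic_spline_basis

__all__ = [
    "Priors",
    "MCMCSettings",
    "ModelSpec",
    "DesignInfo",
    "ParameterState",
    "RiskSummary",
    "STCARModel",
    "STCARResults",
    "build_design",
    "prior_sample_phi",
    "summarize_rr",
]


@dataclass
class Priors:
    """Weakly informative defaults, all configurable.

    beta ~ N(0, beta_sd^2) per coefficient; tau^2 ~ inverse-gamma(a, b);
    rho, gamma ~ U(0, 1).  For the adaptive model, logit(w_kj) has a
    Gaussian shrinkage prior centred near w = 1.
    """

    beta_sd: float = 100.0
    tau2_shape: float = 1.0
    tau2_rate: float = 0.01
    w_logit_mean: float = 4.6  # expit(4.6) ~ 0.99: prior mass near w = 1
    w_logit_sd: float = 1.5


@dataclass
class MCMCSettings:
    """Protocol defaults: 120,000 iterations, 20,000 burn-in, thin 10."""

    n_iter: int = 120_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_keep(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class ModelSpec:
    """Covariate structure, priors and sampler configuration.

    linear_terms enter standardised (coefficients are per-SD); spline_terms
    get a natural cubic spline basis on the raw covariate, columns then
    standardised.  Temperature enters linearly by default (add it to
    spline_terms to change that).  Setting fix_rho / fix_gamma / fix_tau2
    pins a hyperparameter instead of sampling it; include_random_effects =
    False drops phi entirely (plain Poisson regression, used for sanity
    bridges).
    """

    linear_terms: tuple = ("pollution", "temperature")
    spline_terms: dict = field(default_factory=lambda: {"jsa": 3, "mpp": 3})
    intercept: bool = True
    adaptive_w: bool = False
    include_random_effects: bool = True
    fix_rho: float | None = None
    fix_gamma: float | None = None
    fix_tau2: float | None = None
    priors: Priors = field(default_factory=Priors)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    keep_phi: bool = True

    def __post_init__(self) -> None:
        self.linear_terms = tuple(self.linear_terms)
        for term, df in self.spline_terms.items():
            if df < 1:
                raise ValueError(f"spline df for {term!r} must be >= 1")
        for name in ("fix_rho", "fix_gamma"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fix_tau2 is not None and self.fix_tau2 <= 0:
            raise ValueError("fix_tau2 must be positive")


@dataclass
class DesignInfo:
    """Bookkeeping for the standardised design matrix."""

    columns: list
    term_columns: dict  # term -> list of column indices
    col_means: np.ndarray
    col_sds: np.ndarray  # 1.0 for the intercept
    sd_used: dict  # linear term -> raw-scale SD (per-SD reporting units)
    spline_knots: dict  # spline term -> knot sequence


@dataclass
class ParameterState:
    """One point in parameter space (used by log_posterior_components)."""

    beta: np.ndarray
    phi: np.ndarray  # (K, T)
    rho: float
    gamma: float
    tau2: float
    weights: np.ndarray | None = None


@dataclass
class RiskSummary:
    """Posterior relative risk per 1-SD increase of a covariate."""

    covariate: str
    sd_used: float
    rr_median: float
    rr_ci: tuple

    def __post_init__(self) -> None:
        lo, hi = self.rr_ci
        if not lo <= self.rr_median <= hi:
            raise ValueError("credible interval must bracket the median")


def build_design(
    panel: pd.DataFrame,
    linear_terms: tuple,
    spline_terms: dict,
    intercept: bool = True,
) -> tuple[np.ndarray, DesignInfo]:
    """Standardised design matrix from a (row-ordered) panel.

    Column 0 is the intercept.  Each linear term is centred and divided by
    its population (ddof = 0) SD over the panel; spline terms are expanded
    with :func:`natural_cubic_spline_basis` on the raw covariate and each
    basis column is then standardised.  The same code path is used by the
    synthetic-data generator, so simulated effects are expressed in exactly
    the units the fitted coefficients report.
    """
    n = len(panel)
    cols = [np.ones(n)] if intercept else []
    names = ["const"] if intercept else []
    term_columns: dict = {}
    sd_used: dict = {}
    knots_used: dict = {}
    for term in linear_terms:
        if term not in panel.columns:
            raise ValueError(f"covariate {term!r} not found in panel")
        x = panel[term].to_numpy(dtype=float)
        sd = float(np.std(x))
        if sd == 0:
            raise ValueError(f"covariate {term!r} is constant")
        term_columns[term] = [len(cols)]
        sd_used[term] = sd
        cols.append((x - x.mean()) / sd)
        names.append(term)
    for term, df in spline_terms.items():
        if term not in panel.columns:
            raise ValueError(f"covariate {term!r} not found in panel")
        basis, knots = natural_cubic_spline_basis(panel[term].to_numpy(dtype=float), df)
        knots_used[term] = knots
        idxs = []
        for j in range(basis.shape[1]):
            b = basis[:, j]
            sd = float(np.std(b))
            if sd == 0:
                raise ValueError(f"degenerate spline column for {term!r}")
            idxs.append(len(cols))
            cols.append((b - b.mean()) / sd)
            names.append(f"{term}_ns{j + 1}")
        term_columns[term] = idxs
    X = np.column_stack(cols)
    col_means = X.mean(axis=0)
    col_sds = np.ones(X.shape[1])
    return X, DesignInfo(names, term_columns, col_means, col_sds, sd_used, knots_used)


def prior_sample_phi(
    adjacency: AdjacencyStructure,
    rho: float,
    gamma: float,
    tau2: float,
    T: int,
    seed=None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Exact draw of the K x T random-effect field from its GMRF prior.

    phi_1 ~ N(0, tau^2 Q^{-1}) and phi_t = gamma phi_{t-1} + innovation,
    innovation ~ N(0, tau^2 Q^{-1}).  Requires rho < 1 (proper prior).
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1) for a proper prior (Q singular at 1)")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = adjacency.K
    Q = np.asarray(build_precision(adjacency, rho, weights).todense())
    L = np.linalg.cholesky(Q)  # Q = L L'
    tau = np.sqrt(tau2)
    z = rng.standard_normal((K, T))
    # solve L' x = z  =>  cov(x) = Q^{-1}
    from scipy.linalg import solve_triangular

    innov = tau * solve_triangular(L.T, z, lower=False)
    phi = np.empty((K, T))
    phi[:, 0] = innov[:, 0]
    for t in range(1, T):
        phi[:, t] = gamma * phi[:, t - 1] + innov[:, t]
    return phi


class STCARModel:
    """Spatio-temporal CAR Poisson model bound to a panel and adjacency.

    Parameters
    ----------
    panel : DataFrame with columns (area_id, month_index, calendar_month,
        observed, expected) plus one column per covariate named in the spec.
    adjacency : AdjacencyStructure whose area_ids match the panel's areas.
    spec : ModelSpec (covariates, priors, MCMC protocol).
    """

    def __init__(
        self,
        panel: pd.DataFrame,
        adjacency: AdjacencyStructure,
        spec: ModelSpec | None = None,
    ) -> None:
        spec = spec if spec is not None else ModelSpec()
        validate_panel(panel)
        panel_areas = set(panel["area_id"].unique())
        adj_areas = set(adjacency.area_ids)
        if panel_areas != adj_areas:
            odd = (panel_areas ^ adj_areas).pop()
            raise ValueError(f"panel and adjacency areas differ (e.g. {odd!r})")
        self.adjacency = adjacency
        self.spec = spec
        rank = {a: i for i, a in enumerate(adjacency.area_ids)}
        df = panel.copy()
        df["_k"] = df["area_id"].map(rank)
        df = df.sort_values(["month_index", "_k"], ignore_index=True)
        self.panel = df.drop(columns="_k")
        self.K = adjacency.K
        self.T = int(df["month_index"].max())
        # month-major flattening: row n = t*K + k
        self.Y = df["observed"].to_numpy(dtype=float).reshape(self.T, self.K).T
        self.E = df["expected"].to_numpy(dtype=float).reshape(self.T, self.K).T
        self.X, self.design_info = build_design(
            self.panel, spec.linear_terms, dict(spec.spline_terms), spec.intercept
        )
        self.n_params = self.X.shape[1]

    # ------------------------------------------------------------------ fit

    def fit(self, progress: bool = False) -> "STCARResults":
        """Run the Metropolis-within-Gibbs sampler and wrap the draws."""
        from .sampler import MetropolisWithinGibbs

        draws = MetropolisWithinGibbs(self).run(progress=progress)
        return STCARResults(self, draws)

    # ----------------------------------------------------- likelihood pieces

    def linear_predictor(self, beta: np.ndarray, phi: np.ndarray | None = None) -> np.ndarray:
        """(K, T) linear predictor x'beta (+ phi)."""
        eta = (self.X @ np.asarray(beta, float)).reshape(self.T, self.K).T
        if phi is not None:
            eta = eta + phi
        return eta

    def log_likelihood(self, beta: np.ndarray, phi: np.ndarray | None = None) -> float:
        """Poisson log likelihood sum[Y(ln E + eta) - E e^eta], up to ln Y! terms."""
        eta = self.linear_predictor(beta, phi)
        if not np.all(np.isfinite(eta)):
            raise ValueError("non-finite linear predictor")
        with np.errstate(divide="ignore"):
            le = np.where(self.Y > 0, np.log(self.E), 0.0)
        return float(np.sum(self.Y * (le + eta) - self.E * np.exp(eta)))

    def log_posterior_components(self, state: ParameterState) -> dict:
        """Log likelihood and log priors at a parameter state.

        The GMRF prior term is fully normalised, using the log-determinant
        of Q; rho and gamma carry flat U(0, 1) priors (contributing 0).
        """
        beta = np.asarray(state.beta, float)
        phi = np.asarray(state.phi, float)
        K, T = self.K, self.T
        if phi.shape != (K, T):
            raise ValueError(f"phi must have shape {(K, T)}")
        ll = self.log_likelihood(beta, phi)
        Q = np.asarray(build_precision(self.adjacency, state.rho, state.weights).todense())
        sign, logdet = np.linalg.slogdet(Q)
        if sign <= 0:
            raise ValueError("Q is singular (rho = 1?)")
        lag = np.concatenate([np.zeros((K, 1)), phi[:, :-1]], axis=1)
        d = phi - state.gamma * lag
        qf = float(np.sum(d * (Q @ d)))
        lp_phi = (
            -0.5 * K * T * np.log(2 * np.pi * state.tau2)
            + 0.5 * T * logdet
            - qf / (2 * state.tau2)
        )
        sd = self.spec.priors.beta_sd
        lp_beta = float(
            -0.5 * len(beta) * np.log(2 * np.pi * sd**2) - np.sum(beta**2) / (2 * sd**2)
        )
        a, b = self.spec.priors.tau2_shape, self.spec.priors.tau2_rate
        lp_tau2 = float(
            a * np.log(b) - gammaln(a) - (a + 1) * np.log(state.tau2) - b / state.tau2
        )
        return {
            "log_likelihood": ll,
            "log_prior_phi": lp_phi,
            "log_prior_beta": lp_beta,
            "log_prior_tau2": lp_tau2,
            "log_posterior": ll + lp_phi + lp_beta + lp_tau2,
        }

    # ------------------------------------------------------------ GLM bridge

    def posterior_mode_beta(self, max_iter: int = 200, tol: float = 1e-12) -> np.ndarray:
        """Mode of the beta posterior with phi = 0 (ridge-penalised Poisson GLM).

        Newton / iteratively reweighted least squares with the Gaussian
        prior as an L2 penalty; with a diffuse prior this is the Poisson
        GLM maximum-likelihood fit on offset ln E.
        """
        X, E = self.X, self.E.T.reshape(-1)  # month-major flat, matches X rows
        y = self.Y.T.reshape(-1)
        v = self.spec.priors.beta_sd**2
        beta = np.zeros(self.n_params)
        if self.spec.intercept:
            beta[0] = np.log(max(y.sum(), 1.0) / E.sum())
        for _ in range(max_iter):
            eta = X @ beta
            mu = E * np.exp(np.clip(eta, -500, 50))
            grad = X.T @ (y - mu) - beta / v
            H = (X.T * mu) @ X + np.eye(self.n_params) / v
            step = np.linalg.solve(H, grad)
            beta_new = beta + step
            if np.max(np.abs(step)) < tol:
                beta = beta_new
                break
            beta = beta_new
        return beta


class STCARResults:
    """Posterior draws and summaries from a fitted :class:`STCARModel`.

    Attributes
    ----------
    beta : (n_draws, p) regression coefficient draws (per-SD log RRs for
        the standardised covariates).
    phi : (n_draws, K, T) random-effect draws (None if not kept).
    rho, gamma, tau2 : (n_draws,) hyperparameter draws.
    w : (n_draws, n_edges) adjacency weight draws (adaptive model only).
    acceptance : dict of post-burn-in acceptance rates per update block.
    """

    def __init__(self, model: STCARModel, draws: dict) -> None:
        self.model = model
        self.spec = model.spec
        self.design_info = model.design_info
        self.beta = draws["beta"]
        self.phi = draws.get("phi")
        self.rho = draws["rho"]
        self.gamma = draws["gamma"]
        self.tau2 = draws["tau2"]
        self.w = draws.get("w")
        self.acceptance = draws["acceptance"]
        self.deviance = draws.get("deviance")

    @property
    def n_draws(self) -> int:
        return len(self.beta)

    def beta_draws(self, covariate: str) -> np.ndarray:
        names = self.design_info.columns
        if covariate in names:
            return self.beta[:, names.index(covariate)]
        raise KeyError(f"unknown covariate {covariate!r}; have {names}")

    def rr_summary(self, covariate: str, sd_used: float | None = None) -> RiskSummary:
        return summarize_rr(self, covariate, sd_used)

    def summary(self) -> pd.DataFrame:
        """Posterior medians and central 95% credible intervals."""
        rows = []
        for j, name in enumerate(self.design_info.columns):
            d = self.beta[:, j]
            row = {
                "parameter": name,
                "median": np.median(d),
                "lower_95": np.quantile(d, 0.025),
                "upper_95": np.quantile(d, 0.975),
            }
            if name in self.design_info.sd_used:
                rr = np.exp(d)
                row["rr_median"] = np.median(rr)
                row["rr_lower_95"] = np.quantile(rr, 0.025)
                row["rr_upper_95"] = np.quantile(rr, 0.975)
                row["sd_used"] = self.design_info.sd_used[name]
            rows.append(row)
        for name, d in (("rho", self.rho), ("gamma", self.gamma), ("tau2", self.tau2)):
            rows.append(
                {
                    "parameter": name,
                    "median": np.median(d),
                    "lower_95": np.quantile(d, 0.025),
                    "upper_95": np.quantile(d, 0.975),
                }
            )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        with pd.option_context("display.float_format", "{:0.4f}".format):
            return (
                "Spatio-temporal CAR Poisson model "
                f"(K={self.model.K}, T={self.model.T}, draws={self.n_draws})\n"
                + self.summary().to_string(index=False)
            )

    # ------------------------------------------------------------ projection

    def project(self, scenario: pd.DataFrame, covariate: str, n_years: float | None = None):
        """Push the posterior pollution coefficient through a concentration
        scenario; see :func:`stcar.projection.project_scenario`."""
        from .projection import project_scenario

        return project_scenario(self, scenario, covariate, n_years=n_years)

    # -------------------------------------------------------------- plotting

    def plot_trace(self, parameter: str = "rho", ax=None):
        """Trace plot of a scalar parameter or a named beta column."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if parameter in ("rho", "gamma", "tau2"):
            d = getattr(self, parameter)
        else:
            d = self.beta_draws(parameter)
        ax.plot(d, lw=0.6)
        ax.set_xlabel("retained draw")
        ax.set_ylabel(parameter)
        return ax

    def plot_spline_effect(self, term: str, n_grid: int = 100, ax=None):
        """Posterior median and 95% band of a spline covariate's risk curve."""
        import matplotlib.pyplot as plt

        info = self.design_info
        if term not in info.spline_knots:
            raise KeyError(f"{term!r} is not a spline term")
        raw = self.model.panel[term].to_numpy(dtype=float)
        grid = np.linspace(raw.min(), raw.max(), n_grid)
        basis_panel, knots = natural_cubic_spline_basis(
            raw, len(info.term_columns[term]), None
        )
        basis_grid, _ = natural_cubic_spline_basis(
            grid, len(info.term_columns[term]), knots
        )
        # apply the same column standardisation the design used
        mean = basis_panel.mean(axis=0)
        sd = basis_panel.std(axis=0)
        bg = (basis_grid - mean) / sd
        coefs = self.beta[:, info.term_columns[term]]
        curves = bg @ coefs.T  # (n_grid, n_draws)
        curves -= curves.mean(axis=0, keepdims=True)
        med = np.median(curves, axis=1)
        lo = np.quantile(curves, 0.025, axis=1)
        hi = np.quantile(curves, 0.975, axis=1)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(grid, np.exp(med), "k-")
        ax.plot(grid, np.exp(lo), "k--", lw=0.8)
        ax.plot(grid, np.exp(hi), "k--", lw=0.8)
        ax.set_xlabel(term)
        ax.set_ylabel("relative risk")
        return ax

    # ---------------------------------------------------------------- export

    def to_archive(self, path) -> None:
        from .io import write_posterior

        write_posterior(path, self)


def summarize_rr(
    results,
    covariate: str,
    sd_used: float | None = None,
    standardized: bool = True,
) -> RiskSummary:
    """Posterior relative risk per 1-SD increase of a covariate.

    When the covariate entered the model standardised (the default here),
    the RR draws are simply exp(beta) and ``sd_used`` merely records the
    raw-scale SD those units refer to (taken from the design when not
    supplied).  With ``standardized=False`` the draws are per raw unit and
    the RR per SD is exp(beta * sd_used).

    ``results`` may be an :class:`STCARResults` or a plain 1-d array of
    coefficient draws.
    """
    if isinstance(results, STCARResults):
        if results.n_draws == 0:
            raise ValueError("no posterior draws")
        d = results.beta_draws(covariate)
        if sd_used is None:
            sd_used = results.design_info.sd_used.get(covariate, float("nan"))
    else:
        d = np.asarray(results, dtype=float).reshape(-1)
        if d.size == 0:
            raise ValueError("no posterior draws")
        if sd_used is None:
            raise ValueError("sd_used is required with raw coefficient draws")
    scale = 1.0 if standardized else float(sd_used)
    rr = np.exp(d * scale)
    return RiskSummary(
        covariate=covariate,
        sd_used=float(sd_used),
        rr_median=float(np.median(rr)),
        rr_ci=(float(np.quantile(rr, 0.025)), float(np.quantile(rr, 0.975))),
    )
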