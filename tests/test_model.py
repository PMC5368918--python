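"""The Poisson CAR model: likelihood, priors, sampler behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from scipy.stats import multivariate_normal, poisson

from stcar import (
    AdjacencyStructure,
    MCMCSettings,
    ModelSpec,
    ParameterState,
    STCARModel,
    build_precision,
    make_lattice,
    prior_sample_phi,
    summarize_rr,
)
from conftest import make_panel


def two_by_two_model(seed=0, **spec_kwargs):
    rng = np.random.default_rng(seed)
    adj = AdjacencyStructure(["A", "B"], np.array([[0, 1]]))
    E = np.array([[10.0, 12.0], [11.0, 9.0]])
    Y = rng.poisson(E)
    panel = make_panel(Y, E, ["A", "B"], 2, {"x": [[0.5, 1.0], [-0.5, -1.0]]})
    spec = ModelSpec(
        linear_terms=("x",),
        spline_terms={},
        mcmc=spec_kwargs.pop("mcmc", MCMCSettings(n_iter=400, burn_in=100, thin=2, seed=1)),
        **spec_kwargs,
    )
    return STCARModel(panel, adj, spec)


class TestLogPosterior:
    def test_null_state_closed_form(self):
        m = two_by_two_model()
        state = ParameterState(
            beta=np.zeros(m.n_params),
            phi=np.zeros((2, 2)),
            rho=0.5,
            gamma=0.5,
            tau2=1.0,
        )
        comp = m.log_posterior_components(state)
        expected = float(np.sum(m.Y * np.log(m.E) - m.E))
        assert comp["log_likelihood"] == pytest.approx(expected, rel=1e-12)

    def test_tiny_instance_term_by_term(self):
        m = two_by_two_model(seed=3)
        rng = np.random.default_rng(9)
        beta = rng.normal(size=m.n_params)
        phi = rng.normal(scale=0.3, size=(2, 2))
        rho, gamma, tau2 = 0.4, 0.7, 0.6
        comp = m.log_posterior_components(
            ParameterState(beta, phi, rho, gamma, tau2)
        )
        # independent brute-force evaluation
        eta = m.linear_predictor(beta, phi)
        ll = sum(
            poisson.logpmf(m.Y[k, t], m.E[k, t] * np.exp(eta[k, t]))
            for k in range(2)
            for t in range(2)
        ) + sum(gammaln(m.Y[k, t] + 1) for k in range(2) for t in range(2))
        assert comp["log_likelihood"] == pytest.approx(float(ll), rel=1e-10)
        cov = tau2 * np.linalg.inv(build_precision(m.adjacency, rho).toarray())
        lp = multivariate_normal(np.zeros(2), cov).logpdf(phi[:, 0])
        lp += multivariate_normal(gamma * phi[:, 0], cov).logpdf(phi[:, 1])
        assert comp["log_prior_phi"] == pytest.approx(float(lp), rel=1e-10)

    def test_gamma_zero_prior_factorises_over_months(self):
        adj = make_lattice(2, 2)
        rng = np.random.default_rng(4)
        T = 5
        panel = make_panel(
            np.ones((4, T)), np.ones((4, T)), adj.area_ids, T, {"x": rng.normal(size=(4, T))}
        )
        m = STCARModel(panel, adj, ModelSpec(linear_terms=("x",), spline_terms={}))
        phi = rng.normal(scale=0.5, size=(4, T))
        rho, tau2 = 0.3, 0.9
        comp = m.log_posterior_components(ParameterState(np.zeros(2), phi, rho, 0.0, tau2))
        cov = tau2 * np.linalg.inv(build_precision(adj, rho).toarray())
        mvn = multivariate_normal(np.zeros(4), cov)
        independent = sum(mvn.logpdf(phi[:, t]) for t in range(T))
        assert comp["log_prior_phi"] == pytest.approx(float(independent), rel=1e-10)


class TestPriorSamplePhi:
    def test_zero_variance_limit(self):
        adj = make_lattice(2, 2)
        phi = prior_sample_phi(adj, 0.5, 0.8, 0.0, 6, seed=0)
        assert np.allclose(phi, 0.0)

    def test_singular_rho_is_error(self):
        with pytest.raises(ValueError):
            prior_sample_phi(make_lattice(2, 2), 1.0, 0.5, 1.0, 3, seed=0)

    def test_gamma_zero_columns_independent(self):
        adj = make_lattice(2, 2)
        rng = np.random.default_rng(10)
        pairs = []
        for _ in range(1500):
            phi = prior_sample_phi(adj, 0.4, 0.0, 1.0, 2, seed=rng)
            pairs.append((phi[:, 0], phi[:, 1]))
        a = np.concatenate([p[0] for p in pairs])
        b = np.concatenate([p[1] for p in pairs])
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(a))

    def test_first_month_covariance_matches_prior(self):
        adj = make_lattice(2, 2)
        rho, tau2, n = 0.6, 0.8, 5000
        rng = np.random.default_rng(123)
        draws = np.stack(
            [prior_sample_phi(adj, rho, 0.9, tau2, 1, seed=rng)[:, 0] for _ in range(n)]
        )
        S = np.cov(draws.T, ddof=1)
        target = tau2 * np.linalg.inv(build_precision(adj, rho).toarray())
        se = np.sqrt(
            (np.outer(np.diag(target), np.diag(target)) + target**2) / n
        )
        assert np.all(np.abs(S - target) < 3.0 * se)


class TestGLMBridge:
    def test_posterior_mode_matches_statsmodels_glm(self, small_study):
        import statsmodels.api as sm

        spec = ModelSpec()
        spec.priors.beta_sd = 1e5  # effectively flat
        m = STCARModel(small_study.panel, small_study.adjacency, spec)
        mode = m.posterior_mode_beta()
        glm = sm.GLM(
            m.Y.T.reshape(-1),
            m.X,
            family=sm.families.Poisson(),
            offset=np.log(m.E.T.reshape(-1)),
        ).fit()
        assert np.max(np.abs(mode - glm.params)) < 1e-4

    def test_mcmc_without_random_effects_matches_glm(self, small_study):
        import statsmodels.api as sm

        spec = ModelSpec(
            include_random_effects=False,
            mcmc=MCMCSettings(n_iter=6000, burn_in=1000, thin=1, seed=5),
        )
        spec.priors.beta_sd = 1e5
        m = STCARModel(small_study.panel, small_study.adjacency, spec)
        res = m.fit()
        glm = sm.GLM(
            m.Y.T.reshape(-1),
            m.X,
            family=sm.families.Poisson(),
            offset=np.log(m.E.T.reshape(-1)),
        ).fit()
        import arviz as az

        for j in range(res.beta.shape[1]):
            d = res.beta[:, j]
            mcse = d.std() / np.sqrt(float(az.ess(d[None, :])))
            assert abs(d.mean() - glm.params[j]) < max(4 * mcse, 1e-4)


class TestSummarizeRR:
    def test_degenerate_raw_scale_draws(self):
        draws = np.full(100, np.log(1.016) / 9.56)
        rs = summarize_rr(draws, "pollution", sd_used=9.56, standardized=False)
        assert rs.rr_median == pytest.approx(1.016, rel=1e-12)
        assert rs.rr_ci == (pytest.approx(1.016), pytest.approx(1.016))

    def test_zero_draws_give_null_risk(self):
        rs = summarize_rr(np.zeros(50), "x", sd_used=1.0)
        assert rs.rr_median == 1.0
        assert rs.rr_ci == (1.0, 1.0)

    def test_symmetric_draws_median_one(self):
        draws = np.linspace(-0.3, 0.3, 101)  # symmetric about zero
        rs = summarize_rr(draws, "x", sd_used=1.0)
        assert rs.rr_median == pytest.approx(1.0)

    def test_unknown_covariate_is_error(self, small_fit):
        with pytest.raises(KeyError):
            small_fit.rr_summary("nonexistent")


class TestSampler:
    def test_reproducible_given_seed(self):
        r1 = two_by_two_model(seed=2).fit()
        r2 = two_by_two_model(seed=2).fit()
        assert np.array_equal(r1.beta, r2.beta)
        assert np.array_equal(r1.phi, r2.phi)
        assert np.array_equal(r1.tau2, r2.tau2)

    def test_draw_count_and_support(self, small_fit):
        spec = small_fit.spec.mcmc
        assert small_fit.n_draws == (spec.n_iter - spec.burn_in) // spec.thin
        assert np.all((small_fit.rho >= 0) & (small_fit.rho <= 1))
        assert np.all((small_fit.gamma >= 0) & (small_fit.gamma <= 1))
        assert np.all(small_fit.tau2 > 0)
        assert "beta" in small_fit.acceptance and "phi" in small_fit.acceptance

    def test_invalid_protocol_is_error(self):
        with pytest.raises(ValueError):
            MCMCSettings(n_iter=100, burn_in=100)

    def test_area_relabelling_leaves_log_posterior_invariant(self, small_study):
        m = STCARModel(small_study.panel, small_study.adjacency, ModelSpec())
        rng = np.random.default_rng(8)
        perm = rng.permutation(m.K)
        adj_p = small_study.adjacency.permute(perm)
        m_p = STCARModel(small_study.panel, adj_p, ModelSpec())
        beta = rng.normal(scale=0.1, size=m.n_params)
        phi = rng.normal(scale=0.2, size=(m.K, m.T))
        phi_p = np.empty_like(phi)
        phi_p[perm, :] = phi  # same field under the new labels
        s = m.log_posterior_components(ParameterState(beta, phi, 0.7, 0.6, 0.05))
        s_p = m_p.log_posterior_components(ParameterState(beta, phi_p, 0.7, 0.6, 0.05))
        for key in s:
            assert s[key] == pytest.approx(s_p[key], rel=1e-10)

    def test_independence_truth_identified(self):
        # data simulated with rho = gamma = 0 and a strong field: posterior
        # medians of both dependence parameters stay below 0.5
        hits = 0
        for rep in range(3):
            rng = np.random.default_rng(50 + rep)
            adj = make_lattice(3, 3)
            K, T = 9, 12
            phi = prior_sample_phi(adj, 0.0, 0.0, 0.25, T, rng)
            E = np.full((K, T), 300.0)
            Y = rng.poisson(E * np.exp(phi))
            panel = make_panel(Y, E, adj.area_ids, T)
            spec = ModelSpec(
                linear_terms=(),
                spline_terms={},
                mcmc=MCMCSettings(n_iter=3000, burn_in=500, thin=2, seed=rep),
            )
            res = STCARModel(panel, adj, spec).fit()
            if np.median(res.rho) < 0.5 and np.median(res.gamma) < 0.5:
                hits += 1
        assert hits >= 2

    def test_adaptive_w_concentrated_prior_matches_fixed_w(self, small_study, small_fit):
        spec = ModelSpec(
            adaptive_w=True,
            mcmc=MCMCSettings(n_iter=2500, burn_in=500, thin=4, seed=11),
        )
        spec.priors.w_logit_mean = 9.0  # prior essentially pinned at w = 1
        spec.priors.w_logit_sd = 0.1
        res = STCARModel(small_study.panel, small_study.adjacency, spec).fit()
        assert np.median(res.w) > 0.99
        fixed = small_fit
        for term in ("temperature", "pollution"):
            a = np.median(res.beta_draws(term))
            b = np.median(fixed.beta_draws(term))
            assert a == pytest.approx(b, abs=0.05)
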