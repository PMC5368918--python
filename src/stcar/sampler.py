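"""Metropolis-within-Gibbs sampler for the spatio-temporal CAR model.

Update blocks per iteration:

* beta — block random-walk Metropolis, proposal covariance from the
  curvature of the Poisson GLM fit, scalar scale adapted during burn-in.
* phi — single-site random-walk Metropolis.  Sites are grouped into
  conditional-independence colour classes (a proper colouring of the area
  graph crossed with month parity): within a class no two sites interact
  through the GMRF, so the whole class is proposed and accepted/rejected
  element-wise in one vectorised step.
* tau2 — conjugate inverse-gamma Gibbs draw.
* gamma, rho — random-walk Metropolis on the logit scale (flat U(0,1)
  priors); the rho update uses the eigenvalue form of log|Q(rho)|.
* w_kj (adaptive model only) — per-edge random-walk Metropolis on
  logit(w) under the Gaussian shrinkage prior.

Proposal scales adapt towards 40-50% acceptance (30% for the beta block)
during burn-in only, and are frozen afterwards to preserve detailed
balance.  Given (seed, spec, data) the chain is bit-reproducible.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import expit, logit

logger = logging.getLogger("stcar")

_ADAPT_EVERY = 50
_SCALE_BOUNDS = (1e-6, 1e4)


class _Block:
    """Acceptance bookkeeping and burn-in scale adaptation for one block."""

    def __init__(self, scale: float, target: float):
        self.scale = scale
        self.target = target
        self.accepts = 0
        self.attempts = 0
        self.post_accepts = 0.0
        self.post_attempts = 0

    def record(self, accepted, post_burn: bool, n: int = 1) -> None:
        acc = float(np.sum(accepted)) if not np.isscalar(accepted) else float(accepted)
        self.accepts += acc
        self.attempts += n
        if post_burn:
            self.post_accepts += acc
            self.post_attempts += n

    def maybe_adapt(self) -> None:
        if self.attempts == 0:
            return
        rate = self.accepts / self.attempts
        self.scale = float(
            np.clip(self.scale * np.exp(rate - self.target), *_SCALE_BOUNDS)
        )
        self.accepts = 0
        self.attempts = 0

    @property
    def rate(self) -> float:
        return self.post_accepts / max(self.post_attempts, 1)


class MetropolisWithinGibbs:
    def __init__(self, model) -> None:
        self.model = model
        self.spec = model.spec
        self.mcmc = model.spec.mcmc
        self.priors = model.spec.priors
        self.rng = np.random.default_rng(self.mcmc.seed)
        self.K, self.T = model.K, model.T
        self.X = model.X
        self.Y = model.Y  # (K, T)
        self.E = model.E
        self.yx = self.Y.T.reshape(-1) @ self.X  # sufficient stat for beta
        adj = model.adjacency
        self.edges = adj.edges
        self.weights = adj.weights.copy()
        if self.spec.adaptive_w:
            # start at the prior centre; exactly 1 is a boundary of the logit scale
            self.weights = np.full(len(self.edges), expit(self.priors.w_logit_mean))
        self.Lmat = self._laplacian()
        self._lap_eigvals = None  # cached for fixed W

        # colour classes: (spatial colour, month parity)
        spatial = adj.coloring()
        tpar = np.tile(np.arange(self.T) % 2, (self.K, 1))
        site_color = spatial[:, None] * 2 + tpar
        self.color_index = [np.nonzero(site_color == c) for c in np.unique(site_color)]
        # covariate columns as (K, T) fields, for the translation move
        self.Xfields = [
            self.X[:, j].reshape(self.T, self.K).T.copy() for j in range(self.X.shape[1])
        ]

    # ------------------------------------------------------------ utilities

    def _laplacian(self) -> np.ndarray:
        W = np.zeros((self.K, self.K))
        i, j = self.edges.T
        W[i, j] = self.weights
        W[j, i] = self.weights
        return np.diag(W.sum(axis=1)) - W

    def _set_Q(self, rho: float) -> None:
        self.Q = rho * self.Lmat + (1.0 - rho) * np.eye(self.K)
        self.qdiag = np.diag(self.Q).copy()

    def _logdet_Q(self, rho: float) -> float:
        if self.spec.adaptive_w:
            sign, ld = np.linalg.slogdet(rho * self.Lmat + (1 - rho) * np.eye(self.K))
            return ld
        if self._lap_eigvals is None:
            self._lap_eigvals = np.linalg.eigvalsh(self.Lmat)
        lam = np.clip(self._lap_eigvals, 0.0, None)
        return float(np.sum(np.log(rho * lam + (1.0 - rho))))

    def _loglik_beta(self, beta: np.ndarray) -> float:
        eta = (self.X @ beta).reshape(self.T, self.K).T + self.phi
        with np.errstate(over="ignore"):
            s = float(self.yx @ beta - np.sum(self.E * np.exp(eta)))
        return s

    def _quad_terms(self, M: np.ndarray) -> tuple[float, float, float]:
        """a = sum_{t>=2} phi_{t-1}'M phi_{t-1}-style pieces for M = Q phi.

        Returns (a, b, c) with a = sum_{t<T} <phi_t, M_t>, b = sum_{t<T}
        <phi_t, M_{t+1}>, c = sum_t <phi_t, M_t> (0-based t).
        """
        phi = self.phi
        per_t = np.einsum("kt,kt->t", phi, M)
        c = float(per_t.sum())
        a = float(per_t[:-1].sum())
        b = float(np.einsum("kt,kt->", phi[:, :-1], M[:, 1:]))
        return a, b, c

    def _qf(self, gamma: float) -> float:
        M = self.Q @ self.phi
        a, b, c = self._quad_terms(M)
        return c - 2 * gamma * b + gamma**2 * a

    # --------------------------------------------------------------- updates

    def _update_beta(self, post_burn: bool) -> None:
        blk = self.blocks["beta"]
        prop = self.beta + blk.scale * (self.beta_chol @ self.rng.standard_normal(len(self.beta)))
        v = self.priors.beta_sd**2
        ll_prop = self._loglik_beta(prop)
        delta = (
            ll_prop
            - self.cur_loglik_beta
            - (np.sum(prop**2) - np.sum(self.beta**2)) / (2 * v)
        )
        if np.log(self.rng.random()) < delta:
            self.beta = prop
            self.cur_loglik_beta = ll_prop
            self.xb = (self.X @ self.beta).reshape(self.T, self.K).T
            self.mu = self.E * np.exp(self.xb)
            blk.record(1, post_burn)
        else:
            blk.record(0, post_burn)

    def _update_phi(self, post_burn: bool) -> None:
        gamma, tau2 = self.gamma, self.tau2
        g2 = gamma * gamma
        for c, (kc, tc) in enumerate(self.color_index):
            blk = self.blocks[f"phi_{c}"]
            S = self.Q @ self.phi  # (K, T)
            D = S.copy()
            D[:, 1:] -= gamma * S[:, :-1]
            grad = -D
            grad[:, :-1] += gamma * D[:, 1:]
            grad /= tau2
            prec = np.repeat(self.qdiag[:, None], self.T, axis=1)
            prec[:, :-1] *= 1.0 + g2
            prec /= tau2
            m = self.phi + grad / prec

            cur = self.phi[kc, tc]
            prop = cur + blk.scale * self.rng.standard_normal(cur.size)
            mu_c = self.mu[kc, tc]
            y_c = self.Y[kc, tc]
            m_c = m[kc, tc]
            p_c = prec[kc, tc]
            with np.errstate(over="ignore"):
                delta = (
                    y_c * (prop - cur)
                    - mu_c * (np.exp(prop) - np.exp(cur))
                    - 0.5 * p_c * ((prop - m_c) ** 2 - (cur - m_c) ** 2)
                )
            accept = np.log(self.rng.random(cur.size)) < delta
            cur[accept] = prop[accept]
            self.phi[kc, tc] = cur
            blk.record(accept, post_burn, n=cur.size)

    def _update_translation(self) -> None:
        """Exact Gibbs move along the beta-phi ridge.

        The transformation (beta_j, phi) -> (beta_j + delta, phi - delta X_j)
        leaves the linear predictor (hence the likelihood) unchanged, so the
        conditional density of delta involves only the Gaussian priors and is
        itself Gaussian — sampled in closed form for each column.  This
        decorrelates the coefficients of smooth/seasonal covariates from the
        smooth modes of the random-effect field, which plain single-site
        updates traverse very slowly.
        """
        gamma, tau2 = self.gamma, self.tau2
        v = self.priors.beta_sd**2
        lag = np.concatenate([np.zeros((self.K, 1)), self.phi[:, :-1]], axis=1)
        d = self.phi - gamma * lag
        Qd = self.Q @ d
        for j in range(len(self.beta)):
            Xj = self.Xfields[j]
            c = Xj.copy()
            c[:, 1:] -= gamma * Xj[:, :-1]
            Qc = self.Q @ c
            A = np.sum(c * Qc) / tau2 + 1.0 / v
            B = np.sum(c * Qd) / tau2 - self.beta[j] / v
            delta = self.rng.normal(B / A, 1.0 / np.sqrt(A))
            self.beta[j] += delta
            self.phi -= delta * Xj
            d -= delta * c
            Qd -= delta * Qc
        self.xb = (self.X @ self.beta).reshape(self.T, self.K).T
        self.mu = self.E * np.exp(np.clip(self.xb, -500, 50))

    def _update_tau2(self) -> None:
        if self.spec.fix_tau2 is not None:
            return
        qf = self._qf(self.gamma)
        shape = self.priors.tau2_shape + 0.5 * self.K * self.T
        rate = self.priors.tau2_rate + 0.5 * qf
        self.tau2 = 1.0 / self.rng.gamma(shape, 1.0 / rate)

    def _update_gamma(self, post_burn: bool) -> None:
        if self.spec.fix_gamma is not None:
            return
        blk = self.blocks["gamma"]
        M = self.Q @ self.phi
        a, b, _ = self._quad_terms(M)
        v = logit(self.gamma)
        vp = v + blk.scale * self.rng.standard_normal()
        gp = expit(vp)
        delta = (
            -((gp**2 - self.gamma**2) * a - 2 * (gp - self.gamma) * b) / (2 * self.tau2)
            + np.log(gp * (1 - gp))
            - np.log(self.gamma * (1 - self.gamma))
        )
        if np.log(self.rng.random()) < delta:
            self.gamma = float(gp)
            blk.record(1, post_burn)
        else:
            blk.record(0, post_burn)

    def _update_rho(self, post_burn: bool) -> None:
        if self.spec.fix_rho is not None:
            return
        blk = self.blocks["rho"]
        ML = self.Lmat @ self.phi
        aL, bL, cL = self._quad_terms(ML)
        aI, bI, cI = self._quad_terms(self.phi)
        g = self.gamma
        qf_L = cL - 2 * g * bL + g * g * aL
        qf_I = cI - 2 * g * bI + g * g * aI
        v = logit(self.rho)
        vp = v + blk.scale * self.rng.standard_normal()
        rp = expit(vp)
        delta = (
            0.5 * self.T * (self._logdet_Q(rp) - self._logdet_Q(self.rho))
            - ((rp - self.rho) * qf_L + (self.rho - rp) * qf_I) / (2 * self.tau2)
            + np.log(rp * (1 - rp))
            - np.log(self.rho * (1 - self.rho))
        )
        if np.log(self.rng.random()) < delta:
            self.rho = float(rp)
            self._set_Q(self.rho)
            blk.record(1, post_burn)
        else:
            blk.record(0, post_burn)

    def _update_weights(self, post_burn: bool) -> None:
        blk = self.blocks["w"]
        lag = np.concatenate([np.zeros((self.K, 1)), self.phi[:, :-1]], axis=1)
        d = self.phi - self.gamma * lag
        i, j = self.edges.T
        s_e = np.sum((d[i, :] - d[j, :]) ** 2, axis=1)
        mu0, sd0 = self.priors.w_logit_mean, self.priors.w_logit_sd
        ld_cur = self._logdet_Q(self.rho)
        order = self.rng.permutation(len(self.edges))
        z = self.rng.standard_normal(len(order))
        u = np.log(self.rng.random(len(order)))
        for n, e in enumerate(order):
            k, l = self.edges[e]
            w = self.weights[e]
            v = logit(w)
            vp = v + blk.scale * z[n]
            wp = expit(vp)
            dw = wp - w
            # rank-2 symmetric edit of the Laplacian
            Lp = self.Lmat
            Lp[k, k] += dw
            Lp[l, l] += dw
            Lp[k, l] -= dw
            Lp[l, k] -= dw
            sign, ld_prop = np.linalg.slogdet(
                self.rho * Lp + (1 - self.rho) * np.eye(self.K)
            )
            delta = (
                0.5 * self.T * (ld_prop - ld_cur)
                - self.rho * dw * s_e[e] / (2 * self.tau2)
                - ((vp - mu0) ** 2 - (v - mu0) ** 2) / (2 * sd0**2)
            )
            if sign > 0 and u[n] < delta:
                self.weights[e] = wp
                ld_cur = ld_prop
                blk.record(1, post_burn)
            else:  # revert the edit
                Lp[k, k] -= dw
                Lp[l, l] -= dw
                Lp[k, l] += dw
                Lp[l, k] += dw
                blk.record(0, post_burn)
        self._set_Q(self.rho)

    # ------------------------------------------------------------------ run

    def run(self, progress: bool = False) -> dict:
        spec, mcmc = self.spec, self.mcmc
        K, T = self.K, self.T
        re = spec.include_random_effects

        self.beta = self.model.posterior_mode_beta()
        self.phi = np.zeros((K, T))
        self.rho = 0.5 if spec.fix_rho is None else float(spec.fix_rho)
        self.gamma = 0.5 if spec.fix_gamma is None else float(spec.fix_gamma)
        self.tau2 = 0.1 if spec.fix_tau2 is None else float(spec.fix_tau2)
        if re and self.rho >= 1.0:
            raise ValueError("rho = 1 gives a singular prior; use rho < 1")
        self._set_Q(self.rho)

        # beta proposal covariance factor from the GLM curvature
        mu0 = self.E.T.reshape(-1) * np.exp(np.clip(self.X @ self.beta, -500, 50))
        H = (self.X.T * mu0) @ self.X + np.eye(len(self.beta)) / self.priors.beta_sd**2
        self.beta_chol = np.linalg.cholesky(np.linalg.inv(H))

        self.blocks = {"beta": _Block(2.38 / np.sqrt(len(self.beta)), 0.30)}
        for c in range(len(self.color_index)):
            self.blocks[f"phi_{c}"] = _Block(0.1, 0.45)
        self.blocks["gamma"] = _Block(0.5, 0.45)
        self.blocks["rho"] = _Block(0.5, 0.45)
        self.blocks["w"] = _Block(0.5, 0.45)

        self.xb = (self.X @ self.beta).reshape(self.T, self.K).T
        self.mu = self.E * np.exp(self.xb)
        self.cur_loglik_beta = self._loglik_beta(self.beta)

        n_keep = mcmc.n_keep
        out_beta = np.empty((n_keep, len(self.beta)))
        out_rho = np.empty(n_keep)
        out_gamma = np.empty(n_keep)
        out_tau2 = np.empty(n_keep)
        out_phi = np.empty((n_keep, K, T)) if (spec.keep_phi and re) else None
        out_w = np.empty((n_keep, len(self.edges))) if spec.adaptive_w else None
        out_dev = np.empty(n_keep)

        kept = 0
        for it in range(1, mcmc.n_iter + 1):
            post_burn = it > mcmc.burn_in
            self._update_beta(post_burn)
            if re:
                self._update_phi(post_burn)
                self._update_translation()
                self._update_tau2()
                self._update_gamma(post_burn)
                self._update_rho(post_burn)
                if spec.adaptive_w:
                    self._update_weights(post_burn)
                # phi changed: refresh the beta-conditional likelihood cache
                self.cur_loglik_beta = self._loglik_beta(self.beta)
            if not np.isfinite(self.cur_loglik_beta):
                raise RuntimeError(f"non-finite posterior at iteration {it}")
            if not post_burn and it % _ADAPT_EVERY == 0:
                for blk in self.blocks.values():
                    blk.maybe_adapt()
            if post_burn and (it - mcmc.burn_in) % mcmc.thin == 0:
                out_beta[kept] = self.beta
                out_rho[kept] = self.rho
                out_gamma[kept] = self.gamma
                out_tau2[kept] = self.tau2
                if out_phi is not None:
                    out_phi[kept] = self.phi
                if out_w is not None:
                    out_w[kept] = self.weights
                eta = self.xb + self.phi
                out_dev[kept] = -2.0 * float(
                    np.sum(self.Y * (np.log(self.E) + eta) - self.E * np.exp(eta))
                )
                kept += 1
            if progress and it % 1000 == 0:
                rates = {k: f"{b.rate:.2f}" for k, b in self.blocks.items() if b.post_attempts}
                logger.info("iteration %d/%d acceptance=%s", it, mcmc.n_iter, rates)

        acceptance = {
            name: blk.rate for name, blk in self.blocks.items() if blk.post_attempts > 0
        }
        phi_rates = [v for k, v in acceptance.items() if k.startswith("phi_")]
        if phi_rates:
            acceptance["phi"] = float(np.mean(phi_rates))
        return {
            "beta": out_beta,
            "rho": out_rho,
            "gamma": out_gamma,
            "tau2": out_tau2,
            "phi": out_phi,
            "w": out_w,
            "deviance": out_dev,
            "acceptance": acceptance,
        }
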