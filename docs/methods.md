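# Methods

## Scope and data model

`stcar` implements a spatio-temporal ecological analysis pipeline for
monthly disease counts on K areal units over T months, with five stages:

1. **Indirect standardisation** (`stcar.areal`): national stratum rates
   γ_r = (total admissions in stratum r)/(total person-months in r) are
   applied to local stratum populations, E_kt = Σ_r N_ktr γ_r.  Rates may
   be supplied externally (e.g. published national rates) or estimated
   internally; the internal route satisfies the calibration identity
   Σ_kt E_kt = Σ_kt Y_kt exactly.  An optional monthly correction factor
   f_m = (Σ Y in calendar month m)/(Σ E in m) makes E seasonal, which is
   the unique multiplicative factor equating monthly E totals to monthly Y
   totals; it preserves the grand total and is idempotent.  Strata are an
   opaque categorical key — no age bands are hard-coded.
2. **Exposure aggregation** (`stcar.exposure`): daily mean and daily
   maximum concentrations per grid cell are averaged over the days of each
   month (both summaries — "max_t" is the monthly *mean of daily maxima*),
   then aggregated over the cells of each area by spatial mean or maximum,
   yielding four metrics.  Cell-to-area membership is an explicit map
   supplied by the caller (or the generator); the package does no polygon
   geometry.  Cells mapped to no area are dropped; an area with no cells
   is an error.  Per-SD reporting uses the population (ddof = 0) SD over
   the whole K x T panel.
3. **The disease model** (`stcar.model`, `stcar.sampler`): Poisson
   log-linear regression with offset ln E, standardised covariates, and an
   AR(1) Leroux-CAR Gaussian Markov random field φ (precision
   τ⁻²Q(W,ρ), Q = ρ[diag(W1)−W] + (1−ρ)I).
4. **Projection** (`stcar.projection`): RR_kt = exp((z−x)β̂) per posterior
   draw and n̂ = (1/n_years) Σ (RR−1)Y.
5. **Synthetic studies** (`stcar.simulate`): the generative direction of
   stages 1–3 with known truth.

## Priors and defaults

| parameter | prior / default | rationale |
|---|---|---|
| β (each) | N(0, 100²) | effectively flat on the log-RR scale |
| τ² | inverse-gamma(1, 0.01) | weakly informative, standard in this model family |
| ρ, γ | U(0, 1) | flat on the dependence parameters |
| logit(w_kj) | N(4.6, 1.5²) (adaptive model) | shrinkage towards w = 1; border decoupling must earn its keep |
| MCMC protocol | 120,000 iterations, 20,000 burn-in, thin 10 | reference protocol for production runs; tests use shorter chains |

Covariates are centred and scaled by their panel SD before fitting, so
coefficients read directly as per-SD log relative risks.  Spline terms get
a natural cubic basis (boundary knots at the data range, internal knots at
quantiles) built on the raw covariate, with each basis column then
standardised.  Temperature enters linearly by default; a spline option
exists (add it to `spline_terms`).  Two-pollutant and min/max-temperature
sensitivity fits are just `ModelSpec` variants with different
`linear_terms`, not separate code paths.

## Sampler design

Metropolis-within-Gibbs with the following blocks per iteration:

* **β**: block random-walk Metropolis; proposal covariance from the
  curvature of the ridge-penalised Poisson GLM at its mode, scalar scale
  adapted during burn-in (target 30%).
* **φ**: single-site random-walk Metropolis, vectorised over
  conditional-independence colour classes (a greedy proper colouring of
  the area graph crossed with month parity — within a class no two sites
  interact through the GMRF, so element-wise accept/reject of a whole
  class is valid).  Target acceptance 40–50% per class.
* **β–φ translation**: an exact Gibbs move along (β_j, φ) →
  (β_j + δ, φ − δX_j), which leaves the likelihood invariant; δ has a
  closed-form Gaussian conditional involving only the two Gaussian priors.
  Without it, coefficients of seasonal or spatially smooth covariates and
  the smooth modes of φ form a ridge that single-site updates traverse far
  too slowly, and credible intervals undercover.
* **τ²**: conjugate inverse-gamma Gibbs draw from the GMRF quadratic form.
* **γ, ρ**: random-walk Metropolis on the logit scale; the ρ conditional
  uses log|Q(ρ)| = Σ_i log(ρλ_i + 1 − ρ) with λ_i the Laplacian
  eigenvalues (precomputed when W is fixed).
* **w_kj** (adaptive model): per-edge random-walk Metropolis on logit(w)
  under the Gaussian shrinkage prior, with a full log-determinant
  recomputation per proposal — O(K³) per edge, intended for modest K.
  The update scheme is a faithful-in-spirit design choice, not a
  reconstruction of any particular published sampler; with the shrinkage
  prior concentrated at 1 it reproduces the fixed-W model.

Proposal scales freeze at the end of burn-in, preserving detailed balance
for the retained draws.  Chains are bit-reproducible given (seed, spec,
data).  Initialisation: β at the penalised GLM mode, φ = 0, ρ = γ = 0.5,
τ² = 0.1.  No sum-to-zero constraint is imposed on φ (the prior is proper
for ρ < 1); mild confounding between the intercept and φ's level is
accepted and resolved by the translation move.

## The synthetic-data generator

The default scenario is desk-scale: a 6 x 6 rook lattice (K = 36), T = 24
months, 4 grid cells per area, 2 population strata with per-person-month
rates (0.0008, 0.0035) and stratum populations of 10–30k per area, giving
expected counts around 90 per area-month.  Exposures emulate the
qualitative structure of modelled urban air quality: a winter-peaking
seasonal sinusoid shared across areas, a smooth spatial gradient, static
per-cell offsets, daily noise, and a positive within-day spread so daily
maxima exceed daily means.  The seasonal and spatial components are scaled
so the `mean_s.mean_t` panel SD is calibrated to 9.56 ug/m3 (60% of the
structural variance seasonal).  Temperature is an anti-phase sinusoid with
its own (orthogonal) gradient; JSA and MPP are static per area and
negatively correlated, entering the truth through fixed smooth functions
(increasing in log1p JSA, decreasing in log MPP) so the spline terms have
a recoverable shape.

Counts are drawn per stratum, Y_ktr ~ Poisson(N_ktr rate_r exp(x'β + φ)),
with the design standardised by the same code path the model uses, so the
true coefficients are exactly in the units the fit reports.  Effect-size
defaults are anchored to published magnitudes for this model family:
pollution RR 1.016 per SD, temperature RR 0.89 per SD, ρ = 0.98,
γ = 0.99.  The panel's expected counts are rebuilt from the realised
counts by the indirect-standardisation path (so Σ E = Σ Y holds); the
seasonal correction is *not* applied in the generator's default panel,
because the generative truth has no seasonal term in E — seasonality in
the counts comes entirely from the seasonal covariates, and folding it
into E would absorb covariate signal and bias recovery.  A real-data
pipeline would apply the correction to absorb seasonality *not* captured
by covariates.

τ² has no published anchor and defaults to 5e-3.  Two constraints drive
this: it must be a value the model's own τ² prior treats as plausible
(under IG(1, 0.01), P(τ² ≤ 5e-3) ≈ 0.13, whereas scales below ~1e-3 carry
essentially zero prior mass, which would make recovery impossible by
construction), and the implied conditional innovation sd (≈ 0.04 per cell
per month) should be comparable to the Poisson noise floor at the
generator's expected counts (≈ 0.1) so the field is identifiable.  A
known side effect of simulating exactly from the near-unit-root prior
(ρ = 0.98, γ = 0.99): the spatially-constant mode of φ has innovation
variance τ²/(1−ρ) and drifts more over two years than real standardised
admission series would.  Passing recovery tests therefore demonstrates
correctness of the inference under the stated model, not robustness to
the milder misspecifications of real data.

What the generator does *not* emulate: atmospheric chemistry, real
geography, realistic age-sex pyramids, reporting artefacts, or
exposure-measurement error (concentrations are treated as fixed and known,
as in the model itself).

## Numerical choices

* Precision matrices are kept sparse; prior field draws use a dense
  Cholesky factor of Q (adequate for the areal K this package targets).
* log|Q| via Laplacian eigenvalues for fixed W; `slogdet` per proposal
  when W is adaptive.
* The Poisson log-likelihood omits the ln Y! constant; reported deviance
  includes the Y ln E term.
* Exponential overflow in proposals is handled by rejecting (−inf log
  ratios); a non-finite *current* state raises with the iteration index.
* Degenerate inputs fail loudly: zero stratum population, zero metric
  variance, constant covariates, non-rectangular panels, ρ = 1 in the
  proper prior, n_iter ≤ burn-in.
* Value ties in spatial maxima need no tie-break (values, not cell
  identities, are returned).

## Test-suite problem sizes

Deliberately desk-scale so the full suite runs in minutes on one CPU: the
shared fixtures use 3 x 3 and 6 x 6 lattices with 12–24 months; the
parameter-recovery check runs 20 replicates of the default scenario at
6,000 iterations (1,000 burn-in, thin 5); the tiny-instance oracle
compares MCMC against dense numerical integration on K = 2, T = 2 with a
121 x 41⁴ grid.  The production-scale protocol (120k iterations, K in the
hundreds) is configuration, not code: nothing in the implementation is
specialised to the small sizes.

## Known limitations

* The adaptive-W update is O(K³) per edge proposal; for K in the hundreds
  a determinant-update scheme would be needed.
* No WAIC/DIC machinery beyond a deviance trace; no ANOVA/interaction
  CAR variants; no INLA-style approximations.
* Projection holds populations, E, deprivation and temperature at
  present-day values by design; only pollutant concentrations change.
* The no-change identity (z = x ⟹ RR ≡ 1, n̂ = 0) is exact in floating
  point because the implementation evaluates exp(0) literally.
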