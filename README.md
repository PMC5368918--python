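# stcar

Bayesian spatio-temporal modelling of air pollution and respiratory
hospital admissions: indirect standardisation, exposure aggregation,
Leroux-CAR Poisson regression by MCMC, and projection of future
attributable admissions under alternative concentration scenarios.

## Who this is for

Spatio-temporal ecological studies relate monthly disease counts in areal
units (e.g. local authorities) to aggregated air-pollutant concentrations,
after adjusting for population structure, deprivation and temperature.
`stcar` implements that full pipeline for count panels indexed by area
`k = 1..K` and month `t = 1..T`, together with a synthetic-data generator
with known ground truth, so every stage can be exercised and validated
without access to restricted health records.

## The model

Observed counts are modelled against indirectly standardised expected
counts `E_kt = Σ_r N_ktr γ_r` (stratum populations times national stratum
rates):

```
Y_kt | E_kt, R_kt ~ Poisson(E_kt R_kt)
ln R_kt = x_kt' β + φ_kt
```

`x_kt` holds a pollution metric, temperature (linear) and natural cubic
splines (3 df) of two deprivation proxies; continuous covariates are
standardised so each β is a log relative risk per 1-SD increase.  The
random effects follow a multivariate first-order autoregressive Gaussian
Markov random field,

```
φ_1 ~ N(0, τ² Q(W,ρ)⁻¹),   φ_t | φ_{t-1} ~ N(γ φ_{t-1}, τ² Q(W,ρ)⁻¹)
Q(W,ρ) = ρ [diag(W1) − W] + (1−ρ) I
```

with binary (or optionally estimated, "adaptive") border-sharing weights
W.  Inference is Metropolis-within-Gibbs MCMC.  Exposure metrics cross a
spatial summary over the grid cells in an area (mean/max) with a temporal
summary over the days of a month (monthly mean of daily means / of daily
maxima), giving `mean_s.mean_t`, `mean_s.max_t`, `max_s.mean_t`,
`max_s.max_t`.  Given a fitted pollution coefficient and paired
present/future concentrations, the projected annual change in admissions
is

```
RR_kt = exp((z_kt − x_kt) β̂),    n̂ = (1/n_years) Σ_kt (RR_kt − 1) Y_kt .
```

## Worked example

```python
import numpy as np
from stcar import (SyntheticScenario, simulate_study, STCARModel,
                   ModelSpec, MCMCSettings)

study = simulate_study(SyntheticScenario(), seed=1)   # 6x6 lattice, 24 months
spec = ModelSpec(mcmc=MCMCSettings(n_iter=6000, burn_in=1000, thin=5, seed=1))
res = STCARModel(study.panel, study.adjacency, spec).fit()

rr = res.rr_summary("pollution")
print(rr.rr_median, rr.rr_ci)

sc = study.panel[["area_id", "month_index", "observed"]].copy()
sc["present_value"] = study.panel["pollution"]
sc["future_value"] = study.panel["pollution"] - 9.56   # 1 SD cleaner future
proj = res.project(sc, "pollution")
print(proj.reductions, proj.reductions_ci)
```

Output (this exact run):

```
pollution RR per 1 SD (9.49 ug/m3): 1.018 (0.953, 1.087)
temperature RR per 1 SD (4.60 C): 0.901 (0.861, 0.946)
rho median 0.973, gamma median 0.974, tau2 median 0.0061
reduced admissions/year under a 1-SD cleaner future: 654 (95% CrI -1,814, 2,948)
percent of present-day annual admissions (36,538): 1.8%
```

The study was generated with pollution RR 1.016 per SD, temperature RR
0.890, ρ = 0.98, γ = 0.99 and τ² = 0.005: the posterior medians land close
to all of them and every 95% interval covers its truth.  The projection
says that if the (synthetic) study region's concentrations fell by one
panel SD everywhere, roughly 650 of its ~36,500 annual admissions (1.8%)
would be avoided, with an interval that includes zero because this short
desk-scale fit leaves the pollution effect uncertain.

A command-line pipeline mirrors the library:

```
stcar simulate --seed 5 --out study/
stcar fit --panel study/panel.csv --adjacency study/adjacency.csv --seed 1 --out fit/
stcar project --posterior fit/posterior --scenario scenario.csv --out projection.csv
```

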