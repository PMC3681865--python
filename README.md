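# lhfi — Latent Health Factor Index models for estuarine benthic surveys

`lhfi` implements a hierarchical Bayesian health index for estuaries.  It is
aimed at biomonitoring statisticians and benthic ecologists who have grab-
sample counts of the five AMBI ecological groups (pollution-sensitive
through first-order opportunist taxa) at a set of sites, plus per-site
abiotic covariates (salinity, depth, silt–clay fraction, distance
downstream, ...), and who want site health scores, driver effects, and
honest uncertainty for all of them from one integrated model instead of a
multi-step multimetric index.

## The model

Metric counts are *indicators*, not measures, of a latent site health
factor `H_i`.  For each grab replicate, each metric group contributes a
multinomial over its metrics plus the remainder of the sample, with a
generalized-logit link on

```
eta_{g,m,i} = delta_g + gamma_{g,m} + s_g * H_i
```

where `s_g = +1` for metrics positively associated with health (AMBI groups
1–2) and `-1` for the negatively associated groups 3–5, `delta_g` is a
fixed group effect (`delta_plus = 0` for identifiability) and `gamma_{g,m}`
are random metric effects (iid, block-diagonal, or unstructured covariance).
Latent health is regressed on centered covariates,

```
H_i = beta_0 + x_i' beta + eps_i,      eps_i ~ N(0, sigma_eps^2),
```

and the two-level extension adds a regression of (centered) salinity on
(centered) distance downstream,

```
s_i = b_0 + b_1 d_i + e_i,             e_i ~ N(0, sigma_s^2),
```

with salinity replacing distance in the health regression.  Marginalising
salinity collapses the two levels into a single regression on distance with
total error variance `sigma_eps^2 + beta_sal^2 sigma_s^2`; the ratio
`sigma_eps^2 / (sigma_eps^2 + beta_sal^2 sigma_s^2)` measures how much of
the latent error variation is *not* explained by salinity as an implicit
covariate.  This structure lets two strongly collinear drivers (distance
and salinity, sample correlation ≈ 0.88 in the system the synthetic
generator emulates) be simultaneously credible instead of eclipsing each
other.

Fitting is by Metropolis-within-Gibbs MCMC (conjugate updates for all
coefficients, variances and covariance blocks; adaptive random-walk updates
with hierarchical centering and ridge-translation moves for the latent
block), with interval-based Brooks–Gelman–Rubin convergence diagnostics,
equal-tailed credible intervals, the CI-excludes-zero significance rule,
and DIC for model comparison.  Five named presets `model1`..`model5` cover
the distance-only, salinity-only, and three two-level variants.

## Worked example

```python
from lhfi import (simulate_dataset, build_centered_design, model_preset,
                  run_chains, MCMCConfig, posterior_summary,
                  variance_ratio_posterior)
from lhfi.synthetic import model3_recovery_scenario

scenario = model3_recovery_scenario(seed=1)        # true variance ratio 0.5
data, cov, truth = simulate_dataset(scenario)      # 18 sites, 45 grabs
spec = model_preset("model3")                      # salinity-on-distance
design = build_centered_design(cov, spec.health_covariates)
draws = run_chains(data, design, cov, spec, config=MCMCConfig(n_iter=6000, seed=1))

print(posterior_summary(draws).loc[["beta[salinity]", "b1", "sigma_eps", "sigma_s"]].round(3))
print(variance_ratio_posterior(draws).round(3))
```

prints

```
                 mean  median  ci_lower  ci_upper  credible
parameter
beta[salinity]  0.987   0.988     0.646     1.325      True
b1              0.769   0.769     0.609     0.927      True
sigma_eps       0.832   0.811     0.597     1.183      True
sigma_s         0.482   0.470     0.351     0.688      True
                 mean  median  ci_lower  ci_upper  credible
parameter
variance_ratio  0.742   0.752     0.501     0.921      True
```

Both the salinity effect on health (`beta[salinity]`, generating value 1.0)
and the distance effect on salinity (`b1`, generating value 0.77) are
recovered with CIs excluding zero — the two collinear drivers are
simultaneously credible under the two-level structure.  The variance-ratio
posterior mean for this particular dataset sits above its generating value
of 0.5; across seeded replications it centres near 0.5 (see the recovery
study below).  `health_table(draws)` gives per-site LHFI scores with CIs
and ranks, and `draws.metadata["max_rhat"]` (1.009 here) confirms
convergence.

The same pipeline is available from the shell:

```
lhfi simulate --seed 1 --out sim/
lhfi fit --counts sim/counts.csv --covariates sim/covariates.csv --model model3 --out fit3/
lhfi compare fit1/ fit3/
lhfi recover --model model1 --runs 40 --seed 7 --out rec/
```

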