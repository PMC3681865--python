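# Methods

## Model

`lhfi` fits a multilevel analysis-of-covariance GLMM in which benthic
metric counts indicate a latent, site-level health factor.

**Observation level.**  Each grab replicate `r` at site `i` has a total of
`n_{ir}` organisms, of which the five AMBI ecological groups account for
counts `y_1..y_5` (a nonnegative remainder of unclassified organisms is
allowed and is carried explicitly).  Metrics are split by their
preconceived association with health: the plus group {1, 2} and the minus
group {3, 4, 5}.  Each group contributes a multinomial over its metrics
plus the remainder-of-grab baseline, with generalized-logit probabilities
driven by

    eta_{g,m,i} = delta_g + gamma_{g,m} + s_g H_i ,   s_plus = +1, s_minus = -1.

The minus group's sign flip realises the "inverted" logit: abundant
opportunist taxa lower the linear predictor's dependence on health.
`delta_plus = 0` fixes the baseline group (which group is constrained is an
arbitrary identifiability choice, recorded in fit metadata).  The two
multinomials share the remainder category and therefore overlap; the joint
likelihood deliberately includes both terms, accepting the double-counted
overlap, with `delta` and `gamma` crudely absorbing the dependency.  This
is a modelling compromise, not an oversight: no coherent six-category joint
distribution reproduces both group multinomials in the typical probability
regime (their category probabilities sum to more than 1).

**Latent level.**  `H_i = beta_0 + x_i' beta + eps_i`, `eps_i ~ N(0,
sigma_eps^2)`.  Covariates are transformed (natural log for depth,
silt–clay fraction and organic content) then centered at stored constants
(sample means by default); interaction columns are products of centered
parents.  Centering constants persist with the design so a fit can score
new sites consistently.  A month-specific error variance (September /
October) is implemented but off in all presets.

**Two-level extension.**  Centered salinity is regressed on centered
distance downstream: `s_i = b_0 + b_1 d_i + e_i`, `e_i ~ N(0, sigma_s^2)`,
and salinity replaces distance in the health regression.  Marginalising
salinity collapses the two levels to intercept `beta_0 + beta_sal b_0`,
distance slope `beta_sal b_1`, and total error variance `sigma_eps^2 +
beta_sal^2 sigma_s^2`; the reported variance ratio is `sigma_eps^2 /
(sigma_eps^2 + beta_sal^2 sigma_s^2)`, the fraction *not* attributable to
salinity as an implicit covariate (smaller = two-level structure explains
more).

**Priors.**  N(0, 100) on `delta_minus`, `beta_0`, `beta`, `b_0`, `b_1`;
inverse-gamma(1, 1) on every error variance and on the iid metric-effect
variance; inverse-Wishart(dim + 1, I) on metric-effect covariance blocks
(the smallest integer degrees of freedom giving a uniform marginal
correlation prior); optionally a bivariate normal on `(b_0, b_1)` with
correlation `rho ~ Uniform(-1, 1)`.  For the unstructured metric-effect
case a single inverse-Wishart(6, I_5) is placed on the assembled 5×5
covariance so prior and Gibbs update are coherent.

**Presets.**  `model1` distance only; `model2` salinity only; `model3`
two-level salinity-on-distance; `model4` = model3 with correlated
`(b_0, b_1)`; `model5` = model3 plus log-depth, log-silt-clay and their
interaction.  All presets use iid metric effects and a single
`sigma_eps`.

## Sampler

Metropolis-within-Gibbs, one chain per seed stream
(`default_rng([seed, chain])`), two chains by default:

- `H` (per-site), `delta_minus`, `gamma` (per-metric): adaptive random-walk
  Metropolis; step sizes tuned toward 44% acceptance during burn-in only,
  frozen afterwards.  `H` proposals are made and accepted per site in
  parallel (the conditional target factorises over sites).
- `beta_0, beta | H`: exact multivariate-normal Gibbs update; all variances
  and covariance blocks: exact inverse-gamma / inverse-Wishart updates; the
  salinity regression block `(b_0, b_1, sigma_s)` is conjugate given the
  observed covariates; `rho` gets a scalar random-walk update on (-1, 1).
- Ridge translations: the likelihood is exactly invariant under
  `(H, beta_0, delta_minus, gamma_plus) -> (H + c, beta_0 + c,
  delta_minus + c, gamma_plus - c)` and under trading `delta_minus` against
  the minus-group `gamma`s; only the shrinkage priors constrain these
  directions.  Two dedicated joint Metropolis moves propose along them
  (acceptance needs only the prior ratio), which is what makes the chain
  mix in a few thousand iterations — sampling `H` in its hierarchically
  centered form (around the regression mean, with the coefficients
  Gibbs-updated given `H`) handles the remaining coupling.

Burn-in `"auto"` discards the first half and then requires the maximum
interval-based BGR across parameters to be below 1.1; violations are
flagged in metadata (and by a nonzero CLI exit status), never silently
extended.  Summaries use every post-burn-in draw; traces persisted to disk
are thinned (default 100).  Identical seed and inputs give bit-identical
draws.

## Diagnostics and comparison

- **BGR**: on successive windows (second half of draws 1..t), the central
  80% interval width of pooled draws over the mean within-chain width.
  Widths use inverted-CDF (type-1) quantiles, which depend only on the
  empirical distribution — identical chains therefore give exactly 1 — and
  the ratio is floored at 1 against sampling noise.  The classic
  ratio-of-variances PSRF is reported alongside.
- **Summaries**: equal-tailed quantile CIs (numpy linear/type-7 estimator);
  a slope or correlation is "credible" when its 95% CI excludes 0.
- **DIC**: deviance focused on the observed data — metric counts, plus the
  salinity regression in two-level models — conditional on latent
  quantities (`H`, `gamma`, `delta`, `b_0`, `b_1`, `sigma_s`) plugged in at
  posterior means; `pD = Dbar - D(posterior means)`, `DIC = Dbar + pD`.
  Marginal-likelihood DIC is out of scope.
- **Health table**: per-site posterior mean of `H` (the LHFI score) with
  CI and rank (rank 1 = lowest health); a pairwise CI-overlap fraction
  summarises distinguishability.

## Synthetic data generator

The generator reproduces the survey design the model targets: 18 sites
(13 September, 5 October), replicates alternating 3/2 per site (45 grabs),
grab totals uniform on 150–400 (plausible soft-bottom macrofauna totals;
a scenario parameter, as real totals are not published), the published
distance-downstream values for the 18 sites (equally spaced on the same
span otherwise), salinity generated as `20 + b_0 + b_1 d + noise` with the
noise s.d. derived so the expected distance–salinity correlation is 0.88,
and log-depth / log-silt-clay with weak target correlations to distance
(0.16, -0.47).  Default generating values sit in the regime the model is
designed for: slopes 0.5–1, error s.d.s 0.6–1.1, group effect 0.3, metric
effects a few tenths.  `model3_recovery_scenario()` sets
`sigma_eps = |beta_sal| sigma_s` so the generating variance ratio is
exactly 0.5.

Counts are drawn plus-group-first: a multinomial over (metric 1, metric 2,
remainder), then the minus-group metrics are allocated from within that
remainder using the minus-group's model probabilities.  The fitted
likelihood instead evaluates both group multinomials against the full grab
total.  Consequences, measured at near-infinite totals: inferred `H` is a
mildly stretched (~6%) version of the generating values and `sigma_eps`
posteriors sit somewhat above the generating 0.7 in the default scenario;
the minus-group intercept `delta_minus` absorbs the allocation's scale
offset and is not a recovery target.  Recovery of the scientifically
relevant parameters is the arbiter: across 120 seeded simulate-then-fit
runs of the distance-only model, 95%-CI coverage is ~0.95 for `beta_dd`
and ~0.87 for `sigma_eps`.

What the generator does *not* emulate: spatial autocorrelation in
covariates or errors, over-dispersion / taxonomic misclassification in
counts, month effects on covariates, and ITI trophic-group metrics.
Passing recovery tests therefore demonstrates internal consistency of
model and algorithm under the assumed design, not robustness to these
real-data features.

## Numerical choices

- Generalized-logit probabilities via max-subtracted softmax; finite inputs
  never yield NaN.
- Non-positive-definite covariance proposals raise a catchable error and
  count as rejected Metropolis proposals, not crashes; out-of-support
  states have log-prior -inf by contract.
- Inverse-gamma sampling as `scale / Gamma(shape)`; multivariate normal
  draws via Cholesky factors.
- Degenerate inputs: zero grab totals contribute zero log-likelihood (the
  chain then targets the prior — used as a validation); a degenerate
  distance axis (coincident end sites) and log transforms of non-positive
  covariates are errors.

## Problem sizes

Tests and the acceptance script use 2 chains of 4,000–12,000 iterations
(first half burn-in) on 18-site datasets — enough for max BGR ≈ 1.01–1.03
on every preset — and 40-run recovery studies.  Longer chains (tested to
10,000 iterations per fit) leave recovery coverage unchanged.

## Known limitations

- The double-counted group overlap means the observation model is a
  composite, not a joint, likelihood for a single grab; absolute values of
  the log-likelihood and DIC are comparable across models fitted to the
  same data but not interpretable singly.
- Health values are interpretable only relatively (ANOCOVA structure);
  ranks and contrasts are meaningful, absolute levels are not.
- `delta_minus` and the overall `H` level are identified only through
  shrinkage priors (see ridge moves above); their marginal posteriors are
  prior-sensitive.
- With 18 sites and 2–3 replicates, site-health CIs mutually overlap under
  realistic effect sizes; the model ranks sites but cannot sharply separate
  them.
- No spatial random effects or point-referenced modelling; distance
  downstream is the only spatial structure.
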