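# Methods

## Model

Subjects i = 1..n_j are nested in clusters j = 1..J. With a single
continuous predictor x and binary outcome y,

    logit(p_ij) = β₀ + β₁ x_ij + u_j,   u_j ~ N(0, σ²_u),   y_ij ~ Bern(p_ij).

The latent-scale intraclass correlation is ICC = σ²_u / (σ²_u + π²/3); the
π²/3 term is the variance of the standard logistic residual, so ICC and
σ²_u are interchangeable parameterisations (`icc_to_variance` /
`variance_to_icc`, mutual inverses to 1e-10). Development clusters and new
clusters are assumed exchangeable — the new cluster's u comes from the same
N(0, σ²_u).

## Data generator

The generator's defaults are the default study conditions: J = 50 clusters
of n_j = 100 subjects (n = 5000), β₁ = 1.5, ICC = 0.20 (σ²_u ≈ 0.822),
marginal prevalence 50%. x ~ N(0, 1) i.i.d.; u_j ~ N(0, σ²_u); y from the
Bernoulli risk. The intercept β₀ is solved so that the *marginal*
prevalence E[expit(β₀ + Z)], Z ~ N(0, β₁² + σ²_u) (valid because x and u
are independent zero-mean normals), equals the target: 64-node
Gauss–Hermite quadrature inside a bracketed Brent root search, tolerance
1e-6. This replaces manual trial-and-error adjustment with a deterministic
procedure; a Monte-Carlo oracle test confirms it.

Randomness is organised as named substreams of a single master seed:
role (development vs prediction), then predictor / random-effect / outcome
draws within a role. Regenerating one stage never perturbs another, and a
(config, seed) pair is bit-reproducible. Only equal cluster sizes are
generated (unequal sizes are accepted on read).

What the generator does *not* emulate: multiple or correlated predictors,
random slopes, non-normal random effects, informative cluster sizes,
measurement error, or real elicitation behaviour (the simulated expert is
positionally perfect or exactly one region off). Passing tests therefore
demonstrate the machinery under the stated generating model, not
performance on real registry data.

## Frequentist estimation and prediction

`RandomInterceptLogit.fit()` maximises the marginal likelihood obtained by
integrating u out of each cluster's contribution with **adaptive**
Gauss–Hermite quadrature (15 nodes by default): per likelihood evaluation,
each cluster's integrand mode and curvature are found by vectorised Newton
iterations and the Hermite rule is centred and scaled there. 15 nodes
matches the accuracy class of standard mixed-model software; moving 7 → 25
nodes shifts β̂₁ by < 1e-3 on default-scale data, and the fit agrees with
lme4's `glmer` (nAGQ = 15) to ~1e-3 on a test fixture. Optimisation is
L-BFGS-B over (β, σ_u) with σ_u ≥ 1e-6; standard errors come from the
numerical Hessian at the optimum. Prediction for a new cluster zeroes the
random effect: p̂ = expit(β̂₀ + β̂₁ x).

**Expert opinion as a categorical covariate (FREQ.2/3/5).** Development
clusters' true random effects are binned at their empirical m-quantiles
(cutpoints from the development clusters; a value exactly on a cutpoint
goes to the lower bin). Reference categories: lower half (m = 2), second
tertile (m = 3), third quintile (m = 5). New clusters are placed in the
same development-data cutpoints. The development fit *retains* the random
intercept alongside the dummies — whether the original analyses dropped it
is not documented, so retention (the conservative choice: the dummies
absorb what they can, the intercept mops up the rest) is this package's
recorded decision; at prediction the random effect is zeroed exactly as in
FREQ.

## Bayesian estimation

Priors: β₀, β₁ ~ N(0, 1000); σ²_u ~ inverse-gamma(0.001, 0.001) — weakly
informative defaults, configurable via `PriorSpec`.

Sampling is Gibbs with Pólya-Gamma augmentation: ω_ij ~ PG(1, η_ij) given
the linear predictor η, then (β, u) jointly Gaussian given ω (a dense
(2+J)-dimensional solve, assembled from per-cluster sufficient statistics),
then σ²_u | u ~ IG(0.001 + J/2, 0.001 + Σu²/2) — exact conjugacy at every
step, no tuning. The PG(1, z) draws use Devroye's alternating-series
rejection sampler (numba-jitted; acceptance ≈ 0.9998), validated against
the analytic mean tanh(z/2)/(2z) and, through the sampler, against a dense
numerical-integration posterior oracle on a small dataset.

Chains: 2 by default, thinned by 10, 100 saved draws per chain after
burn-in → 200 saved draws of (β̃₀, β̃₁, σ̃²_u); saved iteration indices are
burn_in + thin·(1..n_save). Initial values are deterministic (β at the
plain-logistic MLE, u = 0, σ²_u = 1). The library default burn-in is 5000;
because the conjugate sampler mixes quickly from those starting values, the
test suite and the acceptance script use 1000 (and 300 in the
100-replicate coverage study, with fewer, less-thinned saves) — every run
is checked with the Gelman–Rubin potential scale reduction factor, pass
threshold 1.1, flagged (never silently ignored) on failure. One master
seed is split into per-chain substreams.

## Prediction in new clusters

For each saved draw k and new cluster c, a random effect û_c⁽ᵏ⁾ is sampled
and the subject risks p̂_sc⁽ᵏ⁾ = expit(β̃₀⁽ᵏ⁾ + β̃₁⁽ᵏ⁾ x_sc + û_c⁽ᵏ⁾)
computed; all subjects of a cluster share its û draws. The point prediction
is the per-subject median over the K draws (the full draw vector is kept —
a risk *distribution* per subject is itself useful output).

- **Weakly informative:** û_c⁽ᵏ⁾ ~ N(0, σ̃²_u⁽ᵏ⁾).
- **Truncated (expert) priors:** the N(0, σ²_u) distribution is divided
  into m equal-probability regions; region r spans standard-normal
  probabilities ((r−1)/m, r/m). Given the expert's region r_c,
  û_c⁽ᵏ⁾ = σ̃_u⁽ᵏ⁾ · Φ⁻¹((r_c−1)/m + U/m), U ~ Uniform(0,1) — exact
  inverse-CDF sampling, efficient even in the outer-quintile tails, and
  σ-invariant on the probability scale so the expert's positional statement
  is honoured for every posterior draw of σ. Both paths share one code
  route (the weakly informative model is the m = 1 degenerate case), so
  they coincide draw-for-draw under the same seed.

**Simulated elicitation.** The optimal expert names the region of the
*generating* σ_u-scaled distribution containing the cluster's true u
(boundary values resolve to the lower region, consistently with the region
bounds). The discrepant expert names an adjacent region: edge regions have
one neighbour; interior regions go left/right on a seeded fair coin. In
discrepancy studies, the affected clusters (10/30/50% of new clusters,
drawn uniformly without replacement) are drawn once per percentage and
shared across the three scales, so scale comparisons see the same
misjudged clusters.

## Evaluation

- **Brier score**: mean (y − p̂)², pooled over subjects.
- **C-index** = AUC, Mann–Whitney tie convention (0.5 credit), via
  scikit-learn, cross-checked against exhaustive pair enumeration.
- **Calibration slope, simulation mode**: OLS slope of the true latent risk
  on the predicted risk (truth is available in simulation).
- **Calibration slope, empirical mode**: logistic recalibration slope of
  the observed outcome on the predicted linear predictor (intercept
  included). The mode is always chosen explicitly.
- **Within-cluster versions**: computed per cluster and summarised as mean
  and SD (n−1 denominator) over clusters. A cluster where a metric is
  undefined — single-class outcome or constant predictions, relevant for
  small-cluster scenarios — is excluded from that summary and counted in
  `n_clusters_excluded` rather than failing the run.
- **Calibration-plot data** are exported as long-format tables
  (cluster_id, p̂, p_true); plotting aesthetics are out of scope.

## Experiments

`run_scenario` generates one development and one independent prediction
dataset from the same configuration (distinct named substreams) and runs
every requested model on that same pair, so between-model differences are
never confounded with sampling variation. The Bayesian variants reuse one
set of posterior draws — they differ only at prediction time.
`run_discrepancy_suite` adds the 10/30/50% discrepant-opinion grid;
`run_sensitivity_suite` runs the eight one-feature-at-a-time scenarios
(ICC 0.05 and 0.50; prevalence 10% and 25%; J = 20; n_j = 20; β₁ 0.5 and
3.0). Tables report the metric rows at 3 decimals with within-cluster
entries formatted "mean [sd]".

Because single-dataset results vary seed to seed, replication across seed
bundles is built in; the package's own reproduction and ordering checks use
means over 10 replicate bundles (and 100 replicates for the
parameter-recovery coverage study, with the shortened MCMC settings above —
sizes chosen as a sensible desk-scale default).

## Numerical choices and edge cases

- Intercept solving: quadrature + Brent, tolerance 1e-6.
- σ_u lower bound 1e-6 in ML (boundary estimates are genuine: on truly
  independent data about half of replicates estimate σ̂_u at the boundary,
  where the fit collapses to plain logistic regression, as theory says).
- Quantile cutpoints use linear-interpolation empirical quantiles; ties at
  a cutpoint resolve to the lower bin, deterministically.
- Degenerate configs: σ²_u = 0 is accepted (ICC recorded as 0) for
  no-clustering simulations; ICC strictly inside (0,1) otherwise.
- The logistic risk is evaluated overflow-safely (`expit`, `log_expit`).
- PSRF with identical chains evaluates to √((n−1)/n) ≈ 1; threshold 1.1.

## Known limitations

- One predictor, random intercepts only; no random slopes or multiple
  covariates.
- The elicitation model is positional and stylised; real experts err in
  richer ways than "adjacent region".
- Equal-probability regions only; equal-width division of the
  random-effects distribution is deliberately not implemented.
- ML standard errors are Wald-type from a numerical Hessian; no profile
  likelihood intervals. Interval estimates for the variance component are
  slightly sub-nominal at 50 clusters (the coverage study finds roughly 90%
  frequentist coverage for both the Wald log-σ interval and the equal-tailed
  credible interval, the latter cross-validated against an independent JAGS
  fit); slope intervals are nominal.
- Empirical-mode calibration is exposed but the simulation studies use
  true-risk calibration throughout.
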