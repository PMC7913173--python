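# Methods

## Model

`bwsum` fits the weighted-sum mixture regression

g(E[y_i]) = θ₀ + Σ_g θ_g Σ_{k∈g} w_{gk} x_{ik} + z_i′γ,

with g the identity (Gaussian errors, residual SD σ) or the logit
(Bernoulli outcomes).  Each exposure group's weight vector lies on the
probability simplex under a Dirichlet(α) prior (default α_k = 1, the flat
prior: all weights equally likely a priori), so θ_g is identified as the
total effect of the group's weighted sum and w_{gk} as the fraction of that
effect carried by exposure k.  The model is a reparameterization of an
ordinary multi-exposure regression whose coefficients are β_k = θ w_k; it
answers a different question (one summed effect plus percent contributions)
rather than estimating K independent effects, which is the better-posed
question when exposures co-occur and are strongly collinear.

Assumptions worth keeping in mind:

- All components of a group act in the same direction.  The Dirichlet
  support truncates negative weights; if the true component effects have
  mixed signs the weights are biased and components should be placed in
  separate positive/negative groups.
- Under a null summed effect (θ = 0) the weights are not identified and
  revert to the Dirichlet prior mean 1/K; `null_effect_probe` demonstrates
  this, and single replicates can additionally tilt with chance
  noise–exposure correlation.
- Exposures outside every group, and covariates, enter linearly with
  independent N(0, 100) priors.

## Priors and parameters

| parameter | prior | default | notes |
|---|---|---|---|
| θ_g (summed effect, per unit of weighted sum) | N(μ, σ²) | N(0, 100) | very weakly informative; configurable per spec |
| w_g (weights, unitless fractions) | Dirichlet(α) | α_k = 1 | α configurable per group |
| θ₀, γ | N(0, 100) | — | symmetric with the θ prior |
| σ (Gaussian residual SD, outcome units) | half-Cauchy(scale) | scale 2.5 | weakly informative and proper; `inverse_gamma(shape, rate)` on σ² available for precision-parameterised-Gibbs comparability; `fixed(value)` supports conjugate checks |

The half-Cauchy default and the N(0, 100) intercept/covariate priors are
package choices where the published specification is silent; both are
standard weakly-informative defaults and are configurable.

## Sampler

Adaptive random-walk Metropolis-within-Gibbs with three block types per
sweep: (1) the location block (intercept, all θ_g, γ) jointly; (2) each
group's weights in additive-log-ratio (ALR) coordinates v_k = log(w_k/w_K),
with the exact Jacobian Σ log w_k added to the log-target so the Dirichlet
density on the simplex is preserved while the sampler works on an
unconstrained space; (3) log σ.  Step sizes follow Robbins–Monro adaptation
(rate t^−0.6) toward acceptance 0.44 for scalar and 0.234 for vector blocks
during burn-in only; the post-burn-in kernel is fixed, so the stationary
distribution is exact.

Two numerical choices matter in practice:

- **Centered design.** Design columns are mean-centered internally and the
  intercept draw is mapped back to the raw scale at recording time, with
  the prior evaluated on the raw intercept (a unit-Jacobian linear
  reparameterization, so the posterior is unchanged).  Without this, an
  uncentered covariate such as maternal age makes the intercept–slope ridge
  nearly degenerate and chains mix orders of magnitude more slowly.
- **Covariance adaptation.** During burn-in the location block learns its
  empirical covariance (Welford updates, Cholesky refresh every 50
  iterations once 300 iterations and enough draws have accrued; only when
  burn-in ≥ 600) and proposes along it, Haario-style, frozen afterwards.

The per-chain loop is numba-compiled.  The Gaussian likelihood is evaluated
through the Gram statistics (X′X, X′y, y′y), algebraically identical to the
per-observation normal density sum but O(p²) per evaluation regardless of
n; the logit likelihood is the guarded per-observation sum.  Chains are
initialized overdispersed (location ~ N(0,1), weights ~ Dirichlet(α),
σ = |N(0,1)| + 0.1), per-chain seeds derive from one `SeedSequence`, and a
run is bit-reproducible given (data, model, config including seed).
Convergence is diagnosed (split-chain Gelman–Rubin, autocorrelation, trace
plots) but never silently "fixed" by rerunning or extending — the harness
records diagnostics so simulation tables stay reproducible.  A binary
outcome that a diverging maximum-likelihood logit flags as (quasi-)separable
produces a warning, not a failure.

Defaults mirror the simulation-study settings: 30 000 iterations, burn-in
3000, thinning 2, three chains.

## Summaries

Point estimates are posterior medians (pooled across chains); means are
reported alongside — for weights they sum to one, which the median does not
guarantee.  Interval estimates are 95% highest-posterior-density intervals
computed by the sorted-window algorithm: the shortest contiguous window
containing ⌈mass·n⌉ sorted draws, ties broken toward the lower window
start.  This assumes a unimodal posterior; split HPD regions are out of
scope.  For the logit link, θ is also reported as exp(θ) with the θ-scale
HPD endpoints exponentiated (the map is monotone; computing the HPD
directly on the odds-ratio scale would differ slightly and is not done).

## Simulation harness

`simulate_dataset` draws K = 5 exposures from a multivariate normal with
zero mean, unit variances and one of two correlation regimes, then
y = θ·Σ w_k x_k + ε with ε ~ N(0, sd²) and intercept 0 (a Bernoulli-logit
variant is available).  Truth defaults: weights (0.1, 0.3, 0.2, 0.1, 0.3),
θ ∈ {1.0, 0.2}, residual SD ∈ {0.5, 0.1}, n ∈ {250, 500, 1000},
500 replicates.

Open design points resolved as package choices:

- The low-to-moderate regime is described only as pairwise correlations
  0.1–0.5, so the package fixes a deterministic matrix whose off-diagonals
  cycle through {0.1, …, 0.5} by pair index (positive definite as built);
  the high regime is exchangeable 0.9.  Comparisons of harness output to
  external reference values therefore carry scenario-construction
  uncertainty on top of Monte-Carlo error — visible as, e.g., average
  posterior SD of θ near 0.049 rather than 0.053 in the low-moderate cell.
- Exposure marginals are standard normal and the generating intercept is 0.
- The per-replicate point estimate for bias/MSE/coverage is the posterior
  median, and "95% interval" means the 95% HPD.
- "Average bias" is the mean (not median) of replicate errors; the reported
  estimate is the median of per-replicate medians; "average SD" is the mean
  of per-fit posterior SDs; coverage is the fraction of replicates whose
  HPD contains the truth.  Per-parameter Gelman–Rubin values are averaged
  across replicates, mirroring how convergence was monitored in bulk.

Desk-scale settings used by the test suite and the acceptance script —
150–300 replicates with 6000 iterations / burn-in 1000 / thinning 2 /
three chains — keep one scenario cell under a minute on one CPU; the
full-scale settings remain available through `SamplerConfig` and
`ScenarioSpec.n_replicates`.  Replicate data and sampler seeds derive from
`SeedSequence(base_seed, spawn_key=(replicate, ...))`, so scenario results
are exactly reproducible and resumable per replicate.

## Synthetic cohort

`make_earli_like_cohort` is a synthetic stand-in for a restricted
autism-risk pregnancy cohort and emulates published structure only: n = 166
with ~25% binary-outcome prevalence and strong male excess; five log-normal
serum PBDE-like exposures, four mutually correlated (latent r = 0.88) and
the fifth weakly (r = 0.25); per-exposure detection limits set at the 15th
percentile; a z-scored continuous outcome; and covariates shaped like the
published adjustment set (maternal age, ordinal income, 5-level
race/ethnicity, 4-level site, child sex, gestational age).  It reproduces
no individual-level feature of any real dataset, so pipeline tests on it
demonstrate mechanics (preprocessing → fit → reporting), not real-data
effect sizes.

## Preprocessing

Fixed, logged order: (1) below-LOD imputation at LOD/√2 (explicit 0/1 flag
columns win over value-below-LOD detection), (2) natural-log transform,
(3) optional z-scoring (sample SD, n−1) of exposures and/or outcome.
Missing covariate handling is complete-case with a logged drop count.  The
applied order is part of each output's provenance header because changing
it changes results.

## Known limitations

- Random-walk blocks, no gradient information: posteriors with hundreds of
  covariates will mix slowly; the intended regime is low-dimensional
  mixtures.
- HPD intervals are single-interval (unimodal) by construction.
- Weight inference degrades to the prior as θ → 0 and is biased when true
  component effects have opposing signs (model property, not an
  implementation artifact).
- The split Gelman–Rubin statistic is below 1 by O(1/L) for identical
  chains, as with any within/between variance estimator; it is reported
  unclamped.
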