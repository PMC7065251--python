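# Methods

## Models

All three models share the Daniels–Hughes likelihood for aggregate
randomized-trial data. Study *i* (in class *j*) supplies estimated
treatment effects on the surrogate and final outcomes, `y1` and `y2` on a
log scale (logHR/logOR), their standard errors `se1`, `se2`, and the
within-study correlation `rho_w` between the two estimates (induced by
both being computed on the same patients; it must be supplied, e.g. from
an IPD bootstrap — this package does not estimate it). Within study,

    (y1, y2) ~ N2((mu1, mu2), [[se1^2, se1*se2*rho_w], [., se2^2]]),

and between studies the true effects follow the linear surrogacy
regression `mu2 | mu1 ~ N(lambda0_j + lambda1_j*mu1, psi_j^2)` with the
true surrogate effects `mu1` as *fixed effects* (no distributional
assumption, one vague normal prior each).

- **Subgroup / standard**: each class analyzed independently;
  `lambda0_j, lambda1_j ~ N(0, a^2)`.
- **F-EX**: `lambda0_j ~ N(beta0, xi0^2)`, `lambda1_j ~ N(beta1, xi1^2)`
  with vague priors on the hyper-means and half-normal priors on the
  between-class sds. Class estimates shrink toward the common means; the
  shrinkage grows as classes get smaller or more similar.
- **P-EX**: as F-EX, but each slope is a two-component mixture: with
  prior probability `pi_j` it is exchangeable, otherwise it has its own
  vague prior (the subgroup model's). A per-class Bernoulli indicator is
  sampled inside the chain; its posterior mean — the *mixture weight* —
  measures how much the class participates in the borrowing. Intercepts
  remain fully exchangeable (mixing the intercepts or the conditional
  variances is deliberately out of scope).

## Priors and tunable parameters

| parameter | meaning | default |
|---|---|---|
| `loc_sd` (a) | sd of vague normal priors on all locations | `sqrt(1000) ≈ 31.6` |
| `scale_sd` (b) | sd of half-normal priors on `xi0`, `xi1` (and on `psi_j` when no Bayes factor is needed) | 10 |
| `psi_bf_sd` | sd of the half-normal prior on `psi_j` for Bayes-factor-ready fits | 2 |
| `pi_j` | prior exchangeability probability per class (P-EX) | 0.5 |
| `n_iter` / `burn_in` | chain length / discarded iterations | 50 000 / 20 000 |
| `bf_threshold` | Savage–Dickey evidence threshold | 3.3 |

All effects live on log-ratio scales where values beyond ±3 are extreme,
so these priors are effectively flat. `loc_sd` follows the BUGS-family
convention `dnorm(0, 0.001)` (variance 1000). One caveat documented
because it matters: the P-EX mixture weights are *Lindley-sensitive* to
the vague-prior sd of the non-exchangeable component (the weight of a
genuinely outlying class moves from ≈0.4 at sd 10 to ≈0.8 at sd 100 on
the same data). The weight is interpretable only jointly with that
constant; the package fixes it to the same `loc_sd` as the subgroup
model's slope prior, so the `pi_j = 0` limit coincides exactly with
subgroup analysis.

`pi_j = 1` reduces P-EX to F-EX; `pi_j = 0` makes every slope
non-exchangeable. Note the second limit equals subgroup analysis in the
slopes only — the intercepts stay exchangeable by construction — so the
exact-equivalence test also disables intercept borrowing.

## Sampler

A deterministic-scan Metropolis-within-Gibbs sampler (`surromix.mcmc`):
location parameters (`mu1`, `lambda0_j`, `lambda1_j`, `beta0`, `beta1`)
have normal full conditionals and are drawn exactly; positive scales
(`psi_j`, `xi0`, `xi1`) use multiplicative random-walk Metropolis on the
log scale, step sizes adapted toward 0.44 acceptance during burn-in and
frozen afterwards; the P-EX indicators are exact Bernoulli draws.

Two numerical choices matter:

1. **The latent final-outcome effects `mu2` are integrated out
   analytically.** Given `mu1` and the regression parameters,
   `y2 | y1 ~ N(lambda0 + lambda1*mu1 + k*(y1 - mu1), c + psi^2)` with
   `k = rho_w*se2/se1` and `c = se2^2*(1 - rho_w^2)`. Keeping `mu2` in
   the state creates a funnel as `psi -> 0` (all `mu2` must collapse onto
   the regression line) that mis-explores exactly the boundary region the
   Bayes factor depends on; the collapsed chain matches an exact
   quadrature oracle, and an independent rjags refit of the uncollapsed
   model, to three decimals in the `psi` quantiles. `mu2` is drawn each
   iteration from its exact conditional as a generated quantity (this is
   what cross-validation monitors).
2. **The Savage–Dickey numerator is Rao–Blackwellized.** The marginal
   posterior density of `psi_j` at 0 is computed as the posterior mean of
   its *normalized full conditional* at 0 (Gelfand–Smith identity), a
   one-dimensional quadrature per retained draw, vectorized. A reflected
   Gaussian-kernel estimate on the `psi` chain (Silverman bandwidth) is
   also provided for raw chains, but at a boundary point in the far tail
   it is both biased and noisy (on a validation dataset: exact 0.72,
   kernel 0.26–0.55 across seeds; the Rao–Blackwellized estimate is
   0.715–0.725). `assess_surrogacy` uses the Rao–Blackwellized estimate
   whenever the fit carries its latent chains.

Initialization uses weighted-least-squares moment starts; convergence is
flagged (not fatal) when any split-chain potential scale reduction factor
exceeds 1.05. Identical seeds give bit-identical chains; per-chain,
per-replication and per-held-out-study streams are derived from one root
seed.

## Surrogacy criteria

A class shows a *strong* surrogate relationship when (i) the 95% credible
interval of `lambda0_j` contains 0, (ii) the interval of `lambda1_j`
excludes 0, and (iii) the Bayes factor for `H1: psi_j^2 = 0` exceeds 3.3
(substantial evidence on the Jeffreys-type scale). Criterion (iii)
requires the proper, moderately informative half-normal(2) prior on
`psi_j`; fits record which prior they used and `assess_surrogacy` relies
on that record.

## Cross-validation

Leave-one-out: each study's `y2` is hidden in turn (its likelihood
contribution reduces to the marginal of `y1`; its standard error `se2`
remains available, as the predictive-variance formula requires), the
model is refit, and `mu2` of the held-out study is predicted. The
predictive variance is `se2^2 + var(mu2 | data)` and the 95% interval is
the normal form `mean ± 1.96*sd` (posterior-predictive quantiles are not
used; the normal form matches the variance decomposition above). On real
data the interval is compared with the observed `y2`; in simulations,
with the simulated true `mu2`. For the subgroup model each refit uses
only the held-out study's class; the hierarchical models refit the full
dataset.

## Simulation study

The generator is the product-normal bivariate random-effects formulation:
`mu1 ~ N(eta1_j, psi1_j^2)`, `mu2 | mu1 ~ N(lambda0_j +
lambda1_j*mu1, psi2_j^2)`, observed effects bivariate normal around the
truth with sd `sigma` and correlation `rho_w`. The spread of true
surrogate effects is pinned by the between-study correlation:
`psi1 = psi2 / (|lambda1| * sqrt(1/rho_b^2 - 1))`, the unique positive
root of `corr(mu1, mu2) = rho_b` (unit-tested against a 10^6-draw Monte
Carlo correlation check). Note the generator differs deliberately from
the fitted models (random vs fixed `mu1`): that mismatch, plus data
sparsity, makes interval coverage run above nominal in the small-class
scenarios — a feature of the study design, not a defect.

Nine presets = three designs × three study-count patterns (16 per class,
8 per class, unbalanced 4/8/6/10/7), five classes each, `eta1 = 0.3`,
`sigma = 0.1`, `rho_w = 0.4`, `lambda0_j = 0`:

- design 1 — five similar, strong classes (slopes 0.40–0.60,
  `rho_b` 0.89–0.93, `psi2 = 0.08`);
- design 2 — one outlying slope (0.60 vs 1.55–1.70, `rho_b` 0.93 vs
  0.99);
- design 3 — strong and weak classes mixed (classes 2 and 4 weak:
  `rho_b` 0.70/0.75, `psi2 = 0.30`).

Reported operating characteristics per scenario × model: coverage of the
95% credible intervals of `lambda1_j` (mean over classes); absolute bias
(mean over replications and classes of |error|; the per-class
|bias-of-the-mean| is emitted alongside); per-class RMSE averaged over
classes; mean per-replication interval-width ratio versus subgroup
analysis on the same replication; the largest Monte Carlo error; and the
probability of declaring a strong association (overall and per class).
Replications that fail outright are excluded and counted; convergence
flags are recorded but do not exclude.

## Problem sizes used by the tests and the acceptance script

The full-scale study (1000 replications × 50 000 iterations × 2 chains
per fit) is reproduced here at reduced scale as the package's default
verification size: 50–100 replications per scenario and single chains of
4000–6000 iterations (1500–2000 burn-in), cross-validation on 5
replications of the unbalanced scenario. At this scale every
deterministic property is exact and the stochastic surfaces carry a few
points of Monte Carlo noise, which the quoted tolerances absorb.

## What matches and what deviates

At the scale above the package reproduces the published coverage
(±0.01–0.02), absolute bias and RMSE (within 1–2 points), the
credible-interval width ratios of both the slopes (e.g. 0.75 vs 0.72 and
0.59 vs 0.60 in the first two similar-classes scenarios) and the
cross-validation predictive intervals (0.71 vs 0.67), the P-EX mixture
weight pattern (non-outlying classes ≈0.98 vs printed ≈0.97; outlier
≈0.64 vs printed 0.56, within its Lindley sensitivity), and the
qualitative design-3 pattern (weak classes never declared strong; the
hierarchical models rescue sparse strong classes that subgroup analysis
misses).

The one systematic deviation: **strong-association probabilities run
8–15 percentage points below the published values** (e.g. ≈0.61 vs 0.81
for subgroup analysis in the first scenario) because they are dominated
by the Bayes-factor criterion. Our Savage–Dickey numerator is exact for
the model (validated against quadrature and an independent sampler); the
original analysis post-processed OpenBUGS chains with an unstated density
estimator, and every plausible reconstruction we tried either
under-shoots (boundary-uncorrected or Silverman kernels) or requires an
inconsistent convention (e.g. an untruncated-normal prior density at
zero, which multiplies every Bayes factor by two and lands almost exactly
on the published rates). We report the exact quantity and leave the
discrepancy visible rather than emulate an unverifiable convention; the
ordering of models (F-EX ≈ P-EX > subgroup, gap widening with sparsity)
reproduces regardless.

## Known limitations

- `rho_w` is an input; no IPD bootstrap.
- Only slopes are mixture-modeled in P-EX; `pi_j` is fixed (no Beta
  hyperprior).
- No DIC or alternative surrogacy frameworks; no network or
  multi-surrogate extensions; likelihoods are normal-approximation only.
- The simulation emulates effect estimates with known, equal standard
  errors and a common within-study correlation; real meta-analytic data
  have heterogeneous, estimated standard errors, so passing these tests
  does not certify behavior under severe se heterogeneity.
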