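# Methods

This note records the models, conventions, and numerical choices behind
`krigknn`, and the reasoning where the design was genuinely open.

## Spatial linear model

The model is `z = X beta + e`, `Cov(e) = Sigma(theta)` with an
isotropic exponential autocovariance

    C(d) = sigma1^2 exp(-d / alpha) + sigma0^2 1{d = 0},

where `sigma0^2` is the nugget, `sigma1^2` the partial sill, and
`alpha` the range. Two conventions are fixed and used consistently:

* **Nugget as measurement error.** The nugget contributes only on the
  diagonal of the covariance matrix. Consequently kriging does *not*
  reproduce an observed datum when predicting at an observed coordinate
  with `sigma0^2 > 0`, and the prediction variance at an unsampled site
  includes the nugget of the datum being predicted (we predict the
  noisy value, which is what coverage is scored against).
* **Exponential argument scaling.** The correlation decays as
  `exp(-d/alpha)` (not `exp(-3d/alpha)`); the choice is immaterial to
  fit quality but fixes the meaning of the reported range.

**REML.** Covariance parameters minimize
`log|Sigma| + log|X' Sigma^-1 X| + r' Sigma^-1 r` with `r` the GLS
residual at the candidate `theta`; the additive constant is dropped, so
reported objective values are comparable only within this package. The
optimizer is a coarse grid over (partial-sill fraction) x (range at
distance quantiles) — with the *total* sill profiled out in closed form
(`s = q/(n-p)`) — followed by Nelder-Mead on the log-parameters from
the best grid start (objective tolerance 1e-8, max 200 evaluations).
The returned value is never above any grid start, which is asserted in
tests. All solves use Cholesky factorizations; on factorization failure
a diagonal jitter of `1e-10 x sill` is added, escalating tenfold at
most three times. REML surfaces are multimodal in the range, hence the
grid; profiling the sill makes the grid effectively three-dimensional
at two-dimensional cost.

**Prediction.** Universal-kriging weights satisfy
`lambda' X_s = x_u'`; pointwise variance is the usual kriging variance
plus the trend-uncertainty term. The finite-population block predictor
sums observed values exactly and kriges only the remainder, so its
variance is exactly zero at a census and reduces to the classical
simple-random-sampling formula `N^2 sigma^2 (1-f)/n` when
`Sigma = sigma^2 I` with an intercept-only trend (asserted in tests).
The independence regression (LM) is implemented as the special case
`Sigma = sigma^2 I` with `sigma^2 = r'r/(n-p)`, reusing the same
prediction code paths.

## k-NN

Neighbor search happens in covariate space with metric `W`; ties in
distance break to the lowest observed-site index (stable sort), so
results are platform-independent. Weight rows are convex: `1/k` each
for the mean scheme, inverse-distance-normalized otherwise, with an
exact covariate match short-circuiting to weight one. For MSN with a
scalar response the canonical analysis has rank one and
`W = g lam^2 g'` with `g` the canonical vector normalized to unit
predictor variance and `lam` the canonical (= multiple) correlation.

Leave-one-out cross-validation holds `W` fixed (estimated once from all
`n` observed sites) and removes only the deleted site from the
candidate pool; this keeps the CV quadratic in `n` and matches common
practice. The constant CV standard error is the root mean squared LOO
error (divisor `n`); the block SE scales it by the finite-population
factor, `|sum(b)| sqrt((1-f)/n)`, so one formula serves totals
(`sum b = N`) and means (`sum b = 1`).

`bstNN` searches {Mahalanobis, MSN} x k in {1..5} (the tried k values
are configurable) for the smallest LOO RMSPE, breaking ties toward the
smaller k and then Mahalanobis — parsimony, then determinism.

## Spatially explicit k-NN uncertainty

**kNNGeo** is exact given the fitted SLM: for weights `lambda` summing
to one, `RMSPE^2 = lambda' Sigma_ss lambda - 2 lambda' sigma_su +
sigma_uu + ((lambda' X_s - x_u') betahat)^2`. Because the k-NN weights
satisfy only the sum-to-one constraint and add a bias term, this can
never fall below the kriging SE at the same covariance (asserted on
simulated instances). The bias-squared component is deterministic but
enters the interval as if stochastic, which makes the intervals
conservative.

**IterVar.** Parts of the original iterated-variogram recipe are
specified here as package conventions:

* Standardized residuals `eps_i = (z_i - zhat_i,cv)/sigma_i` use a
  10-bin equal-interval empirical semivariogram over geographic
  distance, mean-of-member-distances bin representatives
  (median/midpoint available), and an exponential semivariogram fit by
  WLS with Cressie weights `N(h)/gamma(h)^2` (plain `N(h)` available),
  grid-started (10x10x10) Nelder-Mead.
* The implied autocorrelation is `rho(h) = psill exp(-h/range)/sill`.
* Local-variance update: each squared CV residual is deflated by the
  model-implied ratio `E(z_i - mean of k neighbors)^2 / sigma^2`
  (computed from the fitted `rho` over the site's covariate-space
  neighborhood, floored at 0.05), then averaged over the site and its k
  neighbors. This is the "local in covariate space" smoothing that
  makes per-site variances estimable from single residuals.
* Convergence: maximum relative change in local standard deviations
  below 1e-3; divergence: any local SD beyond 1e6 times the initial
  constant CV SE; at most 30 iterations. The final per-site prediction
  variance combines the neighbor SDs with the fitted autocorrelation:
  `sigma_u^2 + k^-2 sum_jl rho_jl s_j s_l - (2/k) sigma_u sum_j rho_uj
  s_j`, with `sigma_u` the mean neighbor SD. The estimator requires the
  mean-of-k scheme with `k >= 2`; with one neighbor there is nothing to
  average and the construction is rejected.

## Synthetic populations

All scenarios live on a 20x20 grid evenly spaced on [-1, 1]^2. Eight
covariates form two groups of four; within a group
`x_j = rho x_{j-1} + w_j + delta_j` with `x_1` and `x_5` starting
fresh, so the groups are mutually independent while columns within a
group are cross-correlated. Each `w_j` is a zero-mean Gaussian field
with a spherical autocovariance; each `delta_j` is i.i.d. The response
latent field is `X beta + w_0 + delta_0` with `w_0` spherical;
families: Gaussian (identity), Poisson of the exponentiated latent
(zero-inflated counts), and the indicator `1{latent > 0}` (binary).
Every predictor uses six of the eight covariates — the two null
covariates (x1, x5) are included and two covariates with real effects
(x4, x8) are excluded — and the SLM fits an exponential model to
spherical-truth data, so the whole exercise runs under deliberate
mis-specification.

**Parameter defaults and their provenance.** The qualitative design is
fixed (two covariate groups, the second with smaller sill and range;
strong response autocorrelation for the Gaussian scenario; smaller
coefficients and variances for the count scenario so that
`exp(latent)` stays in a realistic range while the latent still dips
below zero over patches). The exact variance/range values are this
package's own calibration of that design, chosen once from
magnitude-consistency arguments and then frozen:

| parameter | value | rationale |
| --- | --- | --- |
| `rho_x` | 0.9 | strong within-group cross-correlation, so covariate selection matters |
| group 1 `w` (x1..x4) | psill 1.0, range 1.5 | spherical; smooth at the domain scale |
| group 2 `w` (x5..x8) | psill 0.5, range 0.75 | half the sill and range of group 1 |
| `delta_j` variance | 0.1 | weak site-level covariate noise |
| S1 response | psill 12, range 2, nugget 2 | strongly autocorrelated error; total error SD ~ 3.7 against covariate signal SD ~ 3.5 |
| S1 `mu`, `beta` | (0.25,...,2), 0.5 on six slots | arithmetic mean offsets; two null, two excluded-but-real coefficients |
| S2/S3 response | psill 0.8, range 2, nugget 0.1 | latent SD ~ 1 around mean ~ 0.75 |
| S2/S3 `mu`, `beta` | (0.5,...,4), 0.05 on six slots | keeps counts in a 0–40 range, ~20% zeros; binary classes ~ 78/22 |
| sample size | 100 of 400 | 25% sampling fraction |
| unbalanced design | split at (0,0); 52 quadrant + 48 elsewhere of 100 | preferential geographic sampling, scaled from a 200+186-of-386 design |

The generator emulates the statistical structure of skewed,
autocorrelated survey responses with partial covariate information; it
does not emulate irregular plot geometry, anisotropy, measurement
protocols, or covariates observed with error. Tests passing on these
surfaces therefore demonstrate internal correctness and the relative
behavior of the methods under spatial autocorrelation — not performance
on any particular real inventory.

## Evaluation

Per replicate the harness simulates a population, draws the sample,
runs every requested method, and accumulates point errors, interval
indicators, and block errors. Summaries: RMSPE (root of the grand mean
squared error), SRB (`sign(bias) x bias^2 / error variance`, so
`bias^2 + variance = MSPE` identically), PIC90/PIC95 (fraction of
`+/- 1.645 se` / `+/- 1.96 se` intervals covering), PCC (predictions
rounded at 0.5) for the binary scenario, and Kendall tau-b between
estimated SEs and realized absolute errors (tau-b because IterVar SEs
tie heavily; a constant SE vector returns tau 0 with a degeneracy
flag). The binary scenario's block target is the mean — the estimated
proportion — rather than the total. Every cell carries a Monte-Carlo
standard error from the per-replicate values, which is what makes
reduced-replicate acceptance checks principled. Replicates run on
independent seeded streams spawned from one root seed, so results are
independent of execution order and parallelization.

**Problem sizes.** The bundled experiments use 500 replicates per
scenario for the performance table and 300 for the calibration
experiment (the published reference values come from 2000 and 1000
replicates, respectively); Monte-Carlo
standard errors are reported alongside every quantity so the
replication level is explicit. The calibration experiment uses the MSN
k=5 mean-of-k predictor, the best-performing k-NN variant in the
Gaussian scenario and a configuration the iterated-variogram estimator
supports.

## Known limitations

* The simulation-parameter defaults above are reconstructions of a
  study design whose exact values were not available; absolute RMSPE
  scales depend on them (interval coverages and method orderings are
  much less sensitive).
* The IterVar local-variance update is one defensible reading of a
  partially specified algorithm; its convergence rate and coverage
  depend on that reading. It remains unusable for k = 1 and for
  distance-weighted schemes.
* No anisotropy, no covariance families beyond exponential/spherical,
  no Bayesian propagation of covariance-parameter uncertainty, no
  co-kriging, and no small-area (zero-weight) block objectives.
* `reml_value` omits the REML constant; compare objective values only
  within this package.
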