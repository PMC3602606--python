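# krigknn

Finite-population spatial prediction for survey data: the **spatial
linear model** (universal kriging with REML-estimated covariance)
head-to-head against **k-nearest-neighbor imputation**, the workhorse of
forest-inventory mapping.

## The problem

A forest inventory observes a response (biomass, productivity, a
species indicator, ...) at `n` sampled plot locations out of a finite
population of `N` sites, with covariates known everywhere. Two goals:

1. **Point prediction** of the response at every unsampled site.
2. **Block prediction** of the population total `T = sum_i b_i z_i`
   (or mean, with `b_i = 1/N`), with a variance that shrinks to zero as
   the sample approaches a census.

Both families studied here are *linear* predictors
`zhat_u = lambda' z_s`; they differ in how the weights `lambda` are
chosen.

**k-NN imputation** measures distance in covariate ("variable") space,

    d(x_i, x_j) = sqrt( (x_i - x_j)' W (x_i - x_j) ),

and averages the responses of the `k` nearest observed sites. The
weight matrix `W` gives the classic variants: identity (raw), inverse
empirical variances (normalized), inverse empirical covariance
(Mahalanobis), or `W = G L^2 G'` from canonical correlation between
covariates and response — the *most similar neighbor* (MSN) distance.
Uncertainty comes from a leave-one-out cross-validation standard error,
constant across sites, scaled by the classical finite-population factor
for totals.

**The spatial linear model (SLM)** assumes `z = X beta + e` with
`Cov(e)` built from an isotropic exponential autocovariance
(nugget `sigma0^2`, partial sill `sigma1^2`, range `alpha`), estimated
by minimizing the restricted likelihood

    L_R(theta) = log|Sigma| + log|X' Sigma^-1 X| + r' Sigma^-1 r .

Prediction is the (E)BLUP — universal kriging — whose weights minimize
the prediction error variance subject to the unbiasedness constraints
`lambda' X_s = x_u'`, with closed-form pointwise variances and a
finite-population block predictor that sums observed values exactly.

The package also implements two *spatially explicit* variance
estimators for k-NN predictors:

* **IterVar** — an iterated standardized-residual variogram: alternate
  between standardizing CV residuals by per-site standard deviations,
  fitting an exponential semivariogram to them by weighted least
  squares (10 equal bins, 10x10x10 grid start + Nelder-Mead, Cressie
  weights), and updating the local variances with the fitted
  autocorrelation; capped at 30 iterations.
* **kNNGeo** — the RMSPE of the k-NN weights evaluated *under the SLM*:
  `lambda' Sigma_ss lambda - 2 lambda' sigma_su + sigma_uu` plus the
  squared trend bias `((lambda' X_s - x_u') beta)^2`, at REML
  covariance and GLS coefficients.

A synthetic-data module generates the study populations: a 20x20 grid
on [-1, 1]^2 with eight cross-correlated spherical-covariance Gaussian
covariate fields (an autoregressive-like recursion within two groups of
four), and Gaussian, zero-inflated-count, or binary responses; sampling
is simple random (100 of 400) or spatially unbalanced (one quadrant
oversampled). An evaluation harness replicates the experiment and
reports RMSPE, signed relative bias, interval coverage, percent
correctly classified, and Kendall-tau SE calibration, with Monte-Carlo
standard errors on every cell.

## Worked example

```python
import numpy as np
import krigknn as kk

pop = kk.simulate_population(kk.scenario_s1(), seed=1)   # 400 sites, 100 observed
s, u = pop.observed_idx, pop.unobserved_idx
cols = np.array(kk.FITTED_COVARIATES)                    # the 6-covariate design
X_s, X_u = pop.X[np.ix_(s, cols)], pop.X[np.ix_(u, cols)]
ds = np.column_stack([np.ones(s.size), X_s])
du = np.column_stack([np.ones(u.size), X_u])
z_s, z_u = pop.z[s], pop.z[u]

fit = kk.fit_reml(pop.coords[s], ds, z_s)                # exponential REML
out = kk.eblup_point(fit, du, pop.coords[u])             # universal kriging
tot = kk.eblup_block(fit, pop, np.ones(pop.n_total), X_u=du)

spec = kk.build_weight_matrix("msn", X_s, z_s)           # MSN distance, k = 5
model = kk.KnnModel(spec=spec, k=5, scheme="mean", X_s=X_s, z_s=z_s)
preds = kk.knn_predict(model, z_s, X_u)
se_cv = kk.knn_se_cv(z_s, kk.cv_predictions(spec, 5, "mean", X_s, z_s))
```

which prints, for this seed:

```
REML: nugget=0.929  psill=18.877  range=1.185
SLM point RMSPE = 2.127   PIC90 = 0.853
SLM total = 1666.0 +/- 62.7   (true total 1500.1)
MSN5 point RMSPE = 2.941   constant CV SE = 3.172
MSN5 total = 1742.8 +/- 109.9
```

The kriging predictor is closer to the truth site-by-site (RMSPE 2.13
vs 2.94) and for the total (error 166 vs 243, with a smaller standard
error), because it exploits the strong spatial autocorrelation that the
covariate-space neighbor search ignores. The fitted covariance says
most variance (18.9 of 19.8) is spatially structured, with a range
comparable to the domain. The k-NN interval half-width `1.645 * 3.17`
is the same at every site; the kriging SEs vary by location.

A thin CLI wraps the same functions:

```sh
krigknn simulate --scenario S1 --seed 3 --out pop.csv
krigknn slm pop.csv --block total
krigknn knn pop.csv --metric msn --k 5
krigknn knn-uq pop.csv --method itervar --k 5
krigknn evaluate --scenario S1 --reps 100 --seed 7
```

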