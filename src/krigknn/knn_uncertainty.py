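"""Spatially explicit uncertainty estimators for k-NN predictors.

Two estimators beyond the constant cross-validation standard error:

* **IterVar** — an iterated standardized-residual variogram.  Starting
  from the constant CV standard error, residuals are standardized by
  current per-site standard deviations, an empirical semivariogram of
  the standardized residuals is fit by weighted least squares
  (exponential model, grid start plus Nelder-Mead), and the fitted
  spatial autocorrelation is used to update each site's local variance
  from the correlation-corrected squared CV residuals of its covariate-
  space neighbors.  The loop runs to convergence or a 30-iteration cap;
  the final per-site prediction variance combines the local standard
  deviations with the fitted autocorrelation over the k neighbors of
  each prediction site (mean-of-k only, k >= 2).

* **kNNGeo** — the model-based root-mean-squared prediction error of a
  k-NN predictor evaluated under the spatial linear model: for weights
  lambda (summing to one) the error variance lambda' Sigma_ss lambda
  - 2 lambda' sigma_su + sigma_uu plus the squared trend bias
  ((lambda' X_s - x_u') beta)^2, at REML-estimated covariance
  parameters and GLS beta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist, pdist, squareform

from .knn import DistanceSpec, cv_predictions, knn_predict, knn_se_cv, KnnModel
from .simulate import AutocovParams
from .slm import SlmFit

__all__ = [
    "EmpiricalSemivariogram",
    "IterVarState",
    "standardized_residuals",
    "empirical_semivariogram",
    "semivariogram_model",
    "wls_fit_semivariogram",
    "itervar",
    "knngeo_rmspe",
]

MAX_ITER_DEFAULT = 30
CONVERGENCE_TOL = 1e-3     # max relative change in local sd between iterations
DIVERGENCE_FACTOR = 1e6    # any local sd beyond this multiple of the CV SE
_CORR_FLOOR = 0.05         # floor on the CV-variance correction factor


@dataclass(frozen=True)
class EmpiricalSemivariogram:
    """Binned semivariance estimates gamma_hat(h_k) with pair counts."""

    bin_edges: np.ndarray
    h: np.ndarray
    gamma_hat: np.ndarray
    counts: np.ndarray

    @property
    def nonempty(self) -> np.ndarray:
        return self.counts > 0


@dataclass
class IterVarState:
    """State of the iterated-variogram algorithm after its last iteration."""

    iteration: int
    local_sd: np.ndarray
    semivar_params: AutocovParams
    converged: bool
    diverged: bool


def standardized_residuals(z_s, cv_preds, local_sd) -> np.ndarray:
    """(z_i - zhat_i,cv) / sigma_i, elementwise."""
    local_sd = np.asarray(local_sd, dtype=float)
    if np.any(local_sd <= 0):
        raise ValueError("local standard deviations must be strictly positive")
    return (np.asarray(z_s, dtype=float) - np.asarray(cv_preds, dtype=float)) / local_sd


def empirical_semivariogram(
    coords_s: np.ndarray,
    eps: np.ndarray,
    n_bins: int = 10,
    representative: str = "mean",
) -> EmpiricalSemivariogram:
    """Equal-interval binned semivariogram of a site-indexed variable.

    Bins partition (0, max pairwise distance] into ``n_bins`` equal
    intervals; per bin gamma_hat is the average of half squared
    differences and h the mean (or median/midpoint) of member distances.
    Empty bins keep count zero and are excluded from fitting.
    """
    coords_s = np.asarray(coords_s, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if coords_s.shape[0] < 2:
        raise ValueError("need at least two sites for a semivariogram")
    if representative not in ("mean", "median", "midpoint"):
        raise ValueError(f"unknown representative distance: {representative!r}")
    d = pdist(coords_s)
    g = 0.5 * pdist(eps[:, None], metric="sqeuclidean")
    max_d = float(np.max(d))
    edges = np.linspace(0.0, max_d, n_bins + 1)
    # right-inclusive bins over (0, max]; searchsorted('left') maps a
    # distance equal to an edge into the lower bin
    which = np.clip(np.searchsorted(edges, d, side="left") - 1, 0, n_bins - 1)
    h = np.zeros(n_bins)
    gamma = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for k in range(n_bins):
        mask = which == k
        counts[k] = int(np.sum(mask))
        if counts[k]:
            gamma[k] = float(np.mean(g[mask]))
            if representative == "mean":
                h[k] = float(np.mean(d[mask]))
            elif representative == "median":
                h[k] = float(np.median(d[mask]))
            else:
                h[k] = 0.5 * (edges[k] + edges[k + 1])
        else:
            h[k] = 0.5 * (edges[k] + edges[k + 1])
    return EmpiricalSemivariogram(bin_edges=edges, h=h, gamma_hat=gamma, counts=counts)


def semivariogram_model(h, params: AutocovParams):
    """Exponential semivariogram gamma(h) = nugget + psill (1 - exp(-h/range)), h>0."""
    h = np.asarray(h, dtype=float)
    gamma = params.nugget + params.psill * (1.0 - np.exp(-h / params.range))
    return np.where(h > 0, gamma, 0.0)


def _wls_criterion(c0, c1, a, h, gamma_hat, counts, weighting):
    model = c0 + c1 * (1.0 - np.exp(-h / a))
    if weighting == "cressie":
        w = counts / np.maximum(model, 1e-12) ** 2
    else:
        w = counts.astype(float)
    return float(np.sum(w * (gamma_hat - model) ** 2))


def wls_fit_semivariogram(
    emp: EmpiricalSemivariogram,
    n_grid: int = 10,
    weighting: str = "cressie",
) -> AutocovParams:
    """Weighted-least-squares exponential fit to an empirical semivariogram.

    Start values come from an n_grid^3 search over (nugget, partial
    sill, range); a Nelder-Mead simplex refines the best start on a
    square-root/log parameterization.  Cressie weights N(h)/gamma(h)^2
    by default, plain pair counts optionally.
    """
    keep = emp.nonempty
    if np.sum(keep) < 3:
        raise ValueError("need at least three nonempty bins to fit a semivariogram")
    h = emp.h[keep]
    gamma_hat = emp.gamma_hat[keep]
    counts = emp.counts[keep]
    g_max = float(np.max(gamma_hat))
    if g_max <= 0:
        # no variation at all: degenerate pure-zero fit
        return AutocovParams(nugget=0.0, psill=0.0, range=float(np.max(h)))

    c0s = np.linspace(0.0, g_max, n_grid)
    c1s = np.linspace(g_max / n_grid, 1.5 * g_max, n_grid)
    aas = np.geomspace(max(h[0] / 4.0, 1e-6), 2.0 * float(np.max(h)), n_grid)
    # vectorized grid evaluation: params on axis 0, bins on axis 1
    C0, C1, A = [arr.ravel() for arr in np.meshgrid(c0s, c1s, aas, indexing="ij")]
    model = C0[:, None] + C1[:, None] * (1.0 - np.exp(-h[None, :] / A[:, None]))
    if weighting == "cressie":
        w = counts[None, :] / np.maximum(model, 1e-12) ** 2
    else:
        w = np.broadcast_to(counts.astype(float), model.shape)
    crit = np.sum(w * (gamma_hat[None, :] - model) ** 2, axis=1)
    best = int(np.argmin(crit))
    x0 = np.array([np.sqrt(C0[best]), np.sqrt(C1[best]), np.log(A[best])])

    def neg(x):
        c0, c1, a = x[0] ** 2, x[1] ** 2, np.exp(x[2])
        if not np.isfinite(a) or a <= 0:
            return np.inf
        return _wls_criterion(c0, c1, a, h, gamma_hat, counts, weighting)

    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"fatol": 1e-10, "xatol": 1e-8, "maxfev": 400})
    if np.isfinite(res.fun) and res.fun <= crit[best]:
        x = res.x
    else:
        x = x0
    return AutocovParams(nugget=float(x[0] ** 2), psill=float(x[1] ** 2),
                         range=float(np.exp(x[2])))


def _spatial_correlation(dist: np.ndarray, sv: AutocovParams) -> np.ndarray:
    """Autocorrelation implied by a fitted semivariogram: C(h)/sill for h>0."""
    sill = sv.sill
    if sill <= 0 or sv.psill <= 0:
        return np.where(np.asarray(dist) == 0, 1.0, 0.0)
    rho = (sv.psill / sill) * np.exp(-np.asarray(dist, dtype=float) / sv.range)
    return np.where(np.asarray(dist) == 0, 1.0, rho)


def itervar(
    coords_s: np.ndarray,
    X_s: np.ndarray,
    z_s: np.ndarray,
    spec: DistanceSpec,
    k: int,
    coords_u: np.ndarray | None = None,
    X_u: np.ndarray | None = None,
    max_iter: int = MAX_ITER_DEFAULT,
    tol: float = CONVERGENCE_TOL,
    n_bins: int = 10,
):
    """Iterated-variogram local variances for a mean-of-k k-NN predictor.

    Returns ``(state, var_u)`` where ``var_u`` holds per-prediction-site
    variances (None when no prediction sites are given).  Only the
    mean-of-k scheme with k >= 2 is supported: with a single neighbor
    the standardization has no averaging to exploit.
    """
    if k < 2:
        raise ValueError("the iterated variogram estimator requires mean-of-k with k >= 2")
    coords_s = np.asarray(coords_s, dtype=float)
    z_s = np.asarray(z_s, dtype=float)
    n = z_s.size
    cv_preds, cv_neighbors = cv_predictions(spec, k, "mean", X_s, z_s, return_neighbors=True)
    se0 = knn_se_cv(z_s, cv_preds)
    if se0 <= 0:
        se0 = max(float(np.std(z_s)), 1e-12)
    geo = squareform(pdist(coords_s))
    resid_sq = (z_s - cv_preds) ** 2

    local_sd = np.full(n, se0)
    sv = AutocovParams(nugget=1.0, psill=0.0, range=1.0)
    converged = False
    diverged = False
    it = 0
    for it in range(1, max_iter + 1):
        eps = standardized_residuals(z_s, cv_preds, local_sd)
        emp = empirical_semivariogram(coords_s, eps, n_bins=n_bins)
        try:
            sv = wls_fit_semivariogram(emp)
        except ValueError:
            diverged = True
            break
        # correlation-corrected local variances: for each observed site,
        # average the squared CV residuals of its covariate-space
        # neighborhood, each deflated by the model-implied ratio
        # E(z_i - mean of k neighbors)^2 / sigma^2 at the fitted rho
        corr_factor = np.empty(n)
        for i in range(n):
            nb = cv_neighbors[i]
            rho_in = _spatial_correlation(geo[i, nb], sv)
            rho_nn = _spatial_correlation(geo[np.ix_(nb, nb)], sv)
            corr_factor[i] = 1.0 - (2.0 / k) * float(np.sum(rho_in)) \
                + float(np.sum(rho_nn)) / k ** 2
        corr_factor = np.maximum(corr_factor, _CORR_FLOOR)
        s_raw = resid_sq / corr_factor
        new_var = np.empty(n)
        for i in range(n):
            nb = cv_neighbors[i]
            new_var[i] = (s_raw[i] + float(np.sum(s_raw[nb]))) / (k + 1)
        new_sd = np.sqrt(np.maximum(new_var, (1e-6 * se0) ** 2))
        if not np.all(np.isfinite(new_sd)) or np.max(new_sd) > DIVERGENCE_FACTOR * se0:
            diverged = True
            break
        rel = float(np.max(np.abs(new_sd - local_sd) / local_sd))
        local_sd = new_sd
        if rel < tol:
            converged = True
            break

    state = IterVarState(iteration=it, local_sd=local_sd, semivar_params=sv,
                         converged=converged, diverged=diverged)
    var_u = None
    if coords_u is not None and X_u is not None:
        var_u = _itervar_prediction_variance(
            state, coords_s, X_s, z_s, spec, k, np.asarray(coords_u, float), X_u
        )
    return state, var_u


def _itervar_prediction_variance(state, coords_s, X_s, z_s, spec, k, coords_u, X_u):
    """Per-site variance of the mean-of-k predictor from local sds and rho.

    Var(zhat_u - z_u) = sigma_u^2 + (1/k^2) sum_jl rho_jl s_j s_l
                        - (2/k) sum_j rho_uj sigma_u s_j,
    with sigma_u taken as the mean local sd of u's k neighbors.
    """
    _, _, neighbors = knn_predict(
        KnnModel(spec=spec, k=k, scheme="mean", X_s=np.asarray(X_s, float), z_s=z_s),
        z_s, X_u, return_weights=True,
    )
    sv = state.semivar_params
    m = coords_u.shape[0]
    var_u = np.empty(m)
    for i in range(m):
        nb = neighbors[i]
        s_nb = state.local_sd[nb]
        sigma_u = float(np.mean(s_nb))
        d_un = np.linalg.norm(coords_s[nb] - coords_u[i], axis=1)
        rho_un = _spatial_correlation(d_un, sv)
        d_nn = cdist(coords_s[nb], coords_s[nb])
        rho_nn = _spatial_correlation(d_nn, sv)
        cross = float(s_nb @ (rho_nn @ s_nb)) / k ** 2
        var_u[i] = sigma_u ** 2 + cross - (2.0 / k) * sigma_u * float(rho_un @ s_nb)
    return np.maximum(var_u, (1e-6 * float(np.mean(state.local_sd))) ** 2)


def knngeo_rmspe(
    lam: np.ndarray,
    fit: SlmFit,
    X_s: np.ndarray,
    X_u: np.ndarray,
    coords_u: np.ndarray,
) -> np.ndarray:
    """Model-based RMSPE of a k-NN predictor with weights ``lam``.

    Per prediction site: sqrt(error variance at the REML covariance plus
    squared trend bias at the GLS coefficients).  Each lambda row must
    sum to one (the k-NN convexity constraint).
    """
    lam = np.atleast_2d(np.asarray(lam, dtype=float))
    sums = lam.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-8):
        raise ValueError("each k-NN weight row must sum to 1")
    X_u = np.atleast_2d(np.asarray(X_u, dtype=float))
    coords_u = np.atleast_2d(np.asarray(coords_u, dtype=float))
    S_ss = fit.sigma_ss()
    C_su = fit.sigma_su(coords_u)            # n x m
    sill = fit.params.sill
    var = (
        np.sum((lam @ S_ss) * lam, axis=1)
        - 2.0 * np.sum(lam * C_su.T, axis=1)
        + sill
    )
    bias = (lam @ np.asarray(X_s, dtype=float) - X_u) @ fit.beta_gls
    return np.sqrt(np.clip(var + bias ** 2, 0.0, None))
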