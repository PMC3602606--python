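"""The spatial linear model: REML estimation and (E)BLUP prediction.

The model is z = X beta + e with Cov(e) built from an isotropic
exponential autocovariance (nugget sigma0^2, partial sill sigma1^2,
range alpha).  Covariance parameters are estimated by minimizing the
restricted likelihood

    L_R(theta) = log|Sigma| + log|X' Sigma^-1 X| + r' Sigma^-1 r,

with r the GLS residual at theta (the additive constant is dropped).
Point prediction at unsampled sites is universal kriging (BLUP with the
estimated covariance plugged in, i.e. EBLUP); block prediction of a
finite-population total or mean sums the observed values exactly and
kriges the remainder, so its variance vanishes at a census.

The nugget is treated as measurement error: it appears on the diagonal
of the covariance matrix only, and predictions target the noisy datum
(so the prediction variance at an unsampled site includes the nugget).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.stats import norm

from .simulate import AutocovParams, SurveyPopulation, cov_matrix, _chol_with_jitter

__all__ = [
    "SlmFit",
    "SlmFitError",
    "PredictorOutput",
    "block_weights_total",
    "block_weights_mean",
    "reml_objective",
    "fit_reml",
    "eblup_point",
    "eblup_block",
    "lm_fit_predict",
    "slm_interval",
    "BlockPrediction",
]

# tolerance on the REML objective for the simplex refinement
_REML_FATOL = 1e-8
_VAR_FLOOR = 1e-8  # relative floor for variance components on the log scale


class SlmFitError(RuntimeError):
    """REML optimization failed; carries the best parameters found."""

    def __init__(self, message: str, best_params: AutocovParams | None = None):
        super().__init__(message)
        self.best_params = best_params


@dataclass(frozen=True)
class PredictorOutput:
    """Pointwise predictions, standard errors and (optional) linear weights."""

    pred: np.ndarray
    se: np.ndarray
    lam: np.ndarray | None = None


@dataclass(frozen=True)
class BlockPrediction:
    estimate: float
    se: float


@dataclass
class SlmFit:
    """A fitted spatial linear model tied to its training data."""

    params: AutocovParams
    beta_gls: np.ndarray
    reml_value: float
    converged: bool
    coords_s: np.ndarray
    X_s: np.ndarray
    z_s: np.ndarray

    def sigma_ss(self) -> np.ndarray:
        return cov_matrix(self.coords_s, None, self.params)

    def sigma_su(self, coords_u: np.ndarray) -> np.ndarray:
        return cov_matrix(self.coords_s, coords_u, self.params)

    def sigma_uu(self, coords_u: np.ndarray) -> np.ndarray:
        return cov_matrix(coords_u, None, self.params)


def block_weights_total(n_sites: int) -> np.ndarray:
    """Block-definition weights for a population total (all ones)."""
    return np.ones(n_sites)


def block_weights_mean(n_sites: int) -> np.ndarray:
    """Block-definition weights for a population average (all 1/N)."""
    return np.full(n_sites, 1.0 / n_sites)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

class _RemlProblem:
    """Caches the distance matrix and data for repeated REML evaluations."""

    def __init__(self, coords_s, X_s, z_s):
        self.X = np.asarray(X_s, dtype=float)
        self.z = np.asarray(z_s, dtype=float)
        self.n, self.p = self.X.shape
        if self.n <= self.p:
            raise ValueError("REML needs n > p observed sites")
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("design matrix is rank deficient")
        self.D = cdist(coords_s, coords_s)
        np.fill_diagonal(self.D, 0.0)
        off = self.D[np.triu_indices(self.n, 1)]
        self.dist_scale = float(np.median(off)) if off.size else 1.0
        self.max_dist = float(np.max(off)) if off.size else 1.0

    def sigma(self, nugget: float, psill: float, rng: float) -> np.ndarray:
        S = psill * np.exp(-self.D / rng)
        idx = np.diag_indices(self.n)
        S[idx] = psill + nugget
        return S

    def _core(self, S: np.ndarray):
        sill = float(S[0, 0])
        L = _chol_with_jitter(S, sill if sill > 0 else 1.0)
        c = (L, True)
        SiX = cho_solve(c, self.X)
        XtSiX = self.X.T @ SiX
        beta = np.linalg.solve(XtSiX, SiX.T @ self.z)
        r = self.z - self.X @ beta
        q = float(r @ cho_solve(c, r))
        logdet_sigma = 2.0 * float(np.sum(np.log(np.diag(L))))
        sign, logdet_xsx = np.linalg.slogdet(XtSiX)
        if sign <= 0:
            return None
        return beta, q, logdet_sigma, logdet_xsx

    def objective(self, nugget: float, psill: float, rng: float) -> float:
        core = self._core(self.sigma(nugget, psill, rng))
        if core is None:
            return np.inf
        _, q, ld_s, ld_x = core
        return ld_s + ld_x + q

    def profiled(self, frac_psill: float, rng: float):
        """Objective with the total sill profiled out analytically.

        For Sigma = s * V(f, alpha) the optimum over s is closed form,
        s = q_V / (n - p); returns (objective, total sill at optimum).
        """
        V = self.sigma(1.0 - frac_psill, frac_psill, rng)
        core = self._core(V)
        if core is None:
            return np.inf, 1.0
        _, q, ld_v, ld_x = core
        df = self.n - self.p
        s = q / df
        if s <= 0:
            return np.inf, 1.0
        val = df * np.log(s) + ld_v + ld_x + df
        return val, s


def reml_objective(params: AutocovParams, coords_s, X_s, z_s) -> float:
    """The restricted-likelihood objective at fixed covariance parameters."""
    prob = _RemlProblem(coords_s, X_s, z_s)
    return prob.objective(params.nugget, params.psill, params.range)


def fit_reml(
    coords_s,
    X_s,
    z_s,
    family: str = "exponential",
    n_frac: int = 5,
    n_range: int = 5,
    maxfev: int = 200,
) -> SlmFit:
    """REML fit of (nugget, psill, range) for the exponential model.

    A coarse grid over sill-fraction x range (with the total sill
    profiled out in closed form) chooses a starting point; a Nelder-Mead
    simplex on the log-parameters refines it.  The returned objective
    value is never above any grid start.
    """
    if family != "exponential":
        raise ValueError("only the exponential autocovariance is supported for fitting")
    prob = _RemlProblem(coords_s, X_s, z_s)
    var_z = float(np.var(prob.z, ddof=1))
    floor = max(_VAR_FLOOR * max(var_z, 1.0), 1e-300)

    fracs = np.linspace(0.05, 0.95, n_frac)
    ranges = np.geomspace(prob.dist_scale / 4.0, max(prob.max_dist, prob.dist_scale), n_range)
    best = None
    for f in fracs:
        for a in ranges:
            val, s = prob.profiled(f, a)
            if np.isfinite(val) and (best is None or val < best[0]):
                best = (val, f, a, s)
    if best is None:
        raise SlmFitError("all REML grid starts failed")
    grid_val, f0, a0, s0 = best

    x0 = np.log([max(s0 * (1.0 - f0), floor), max(s0 * f0, floor), a0])

    def neg(x):
        nugget, psill, rng = np.exp(x)
        if not np.all(np.isfinite([nugget, psill, rng])) or rng <= 0:
            return np.inf
        return prob.objective(nugget, psill, rng)

    res = minimize(
        neg, x0, method="Nelder-Mead",
        options={"fatol": _REML_FATOL, "xatol": 1e-6, "maxfev": maxfev},
    )
    candidates = [(grid_val, x0, False)]
    if np.isfinite(res.fun):
        candidates.append((float(res.fun), res.x, bool(res.success)))
    val, x, converged = min(candidates, key=lambda t: t[0])
    nugget, psill, rng = np.exp(x)
    params = AutocovParams(nugget=float(nugget), psill=float(psill),
                           range=float(rng), family="exponential")
    core = prob._core(prob.sigma(nugget, psill, rng))
    if core is None:
        raise SlmFitError("REML optimum not evaluable", best_params=params)
    beta = core[0]
    return SlmFit(
        params=params, beta_gls=beta, reml_value=float(val),
        converged=converged, coords_s=np.asarray(coords_s, dtype=float),
        X_s=prob.X, z_s=prob.z,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _fit_factors(fit: SlmFit):
    S = fit.sigma_ss()
    L = _chol_with_jitter(S, fit.params.sill if fit.params.sill > 0 else 1.0)
    c = (L, True)
    SiX = cho_solve(c, fit.X_s)
    XtSiX = fit.X_s.T @ SiX
    r = fit.z_s - fit.X_s @ fit.beta_gls
    Sir = cho_solve(c, r)
    return c, SiX, XtSiX, Sir


def eblup_point(
    fit: SlmFit,
    X_u: np.ndarray,
    coords_u: np.ndarray,
    return_weights: bool = False,
) -> PredictorOutput:
    """Universal-kriging predictions and standard errors at new sites.

    The weights satisfy the unbiasedness constraints lambda' X_s = x_u'
    row-wise; the prediction variance is the kriging variance including
    the nugget of the predicted datum.
    """
    X_u = np.atleast_2d(np.asarray(X_u, dtype=float))
    coords_u = np.atleast_2d(np.asarray(coords_u, dtype=float))
    c, SiX, XtSiX, Sir = _fit_factors(fit)
    C_su = fit.sigma_su(coords_u)           # n x m
    SiC = cho_solve(c, C_su)                # Sigma^-1 sigma_su
    d = X_u - SiC.T @ fit.X_s               # m x p trend mismatch
    Ad = np.linalg.solve(XtSiX, d.T)        # p x m
    pred = X_u @ fit.beta_gls + C_su.T @ Sir
    sill = fit.params.sill
    var = sill - np.sum(C_su * SiC, axis=0) + np.sum(d * Ad.T, axis=1)
    var = np.clip(var, 0.0, None)
    lam = None
    if return_weights:
        lam = (SiC + SiX @ Ad).T            # m x n rows of kriging weights
    return PredictorOutput(pred=pred, se=np.sqrt(var), lam=lam)


def eblup_block(
    fit: SlmFit,
    population: SurveyPopulation,
    b: np.ndarray,
    X_u: np.ndarray | None = None,
) -> BlockPrediction:
    """Finite-population block BLUP of b'z with its standard error.

    The observed part of the block sum is taken as known; only the
    unobserved remainder is predicted, so the variance is exactly zero
    when every site is observed.
    """
    b = np.asarray(b, dtype=float)
    if b.shape[0] != population.n_total:
        raise ValueError("block weights must cover every site in the population")
    s = np.asarray(population.observed_idx)
    u = np.asarray(population.unobserved_idx)
    b_s, b_u = b[s], b[u]
    obs_part = float(b_s @ fit.z_s)
    if u.size == 0:
        return BlockPrediction(estimate=obs_part, se=0.0)
    coords_u = population.coords[u]
    if X_u is None:
        X_u = _match_design(fit, population, u)
    c, SiX, XtSiX, Sir = _fit_factors(fit)
    C_su = fit.sigma_su(coords_u)
    SiC = cho_solve(c, C_su)
    pred_u = X_u @ fit.beta_gls + C_su.T @ Sir
    est = obs_part + float(b_u @ pred_u)

    cb = C_su @ b_u                          # n-vector Sigma_su b_u
    Sicb = cho_solve(c, cb)
    S_uu = fit.sigma_uu(coords_u)
    var = float(b_u @ (S_uu @ b_u) - cb @ Sicb)
    db = X_u.T @ b_u - fit.X_s.T @ Sicb      # p-vector trend mismatch
    var += float(db @ np.linalg.solve(XtSiX, db))
    return BlockPrediction(estimate=est, se=float(np.sqrt(max(var, 0.0))))


def _match_design(fit: SlmFit, population: SurveyPopulation, u: np.ndarray) -> np.ndarray:
    """Design rows for unobserved sites matching the columns of fit.X_s.

    The fitted design may carry an intercept and a covariate subset; the
    caller is expected to have built fit.X_s from population columns via
    the same recipe.  We reconstruct by matching observed rows.
    """
    p = fit.X_s.shape[1]
    full = population.X
    s = np.asarray(population.observed_idx)
    # identify the design recipe: intercept column plus covariate columns
    cols = []
    intercept = []
    for j in range(p):
        col = fit.X_s[:, j]
        if np.allclose(col, 1.0):
            intercept.append(j)
            cols.append(None)
            continue
        match = None
        for jj in range(full.shape[1]):
            if np.allclose(col, full[s, jj]):
                match = jj
                break
        if match is None:
            raise ValueError(
                "could not match fitted design columns to population "
                "covariates; pass predictions explicitly via eblup_point"
            )
        cols.append(match)
    X_u = np.empty((u.size, p))
    for j, match in enumerate(cols):
        X_u[:, j] = 1.0 if match is None else full[u, match]
    return X_u


def lm_fit_predict(
    X_s: np.ndarray,
    z_s: np.ndarray,
    X_u: np.ndarray,
    coords_s: np.ndarray | None = None,
    coords_u: np.ndarray | None = None,
    return_weights: bool = False,
):
    """Ordinary multiple regression as the independence special case.

    Fits Sigma = sigma^2 I with the unbiased (REML) variance estimate
    r'r/(n-p) and reuses the kriging prediction formulas, which then
    reduce to OLS prediction with variance sigma^2 (1 + x'(X'X)^-1 x).
    Returns (PredictorOutput, SlmFit).
    """
    X_s = np.asarray(X_s, dtype=float)
    z_s = np.asarray(z_s, dtype=float)
    X_u = np.atleast_2d(np.asarray(X_u, dtype=float))
    n, p = X_s.shape
    if n <= p:
        raise ValueError("need n > p for the independence model")
    beta, _, rank, _ = np.linalg.lstsq(X_s, z_s, rcond=None)
    if rank < p:
        raise SlmFitError("rank-deficient design in the independence model")
    r = z_s - X_s @ beta
    sigma2 = float(r @ r) / (n - p)
    sigma2 = max(sigma2, 1e-300)
    if coords_s is None:
        coords_s = np.zeros((n, 2))
        coords_s[:, 0] = np.arange(n)  # distinct dummy locations
    if coords_u is None:
        coords_u = np.full((X_u.shape[0], 2), -1.0)
        coords_u[:, 0] = -1.0 - np.arange(X_u.shape[0])
    params = AutocovParams(nugget=sigma2, psill=0.0, range=1.0)
    fit = SlmFit(params=params, beta_gls=beta, reml_value=np.nan, converged=True,
                 coords_s=np.asarray(coords_s, dtype=float), X_s=X_s, z_s=z_s)
    out = eblup_point(fit, X_u, coords_u, return_weights=return_weights)
    return out, fit


def slm_interval(pred, var, level: float = 0.90):
    """Normal-theory interval pred +/- z * sqrt(var); tiny negative var clipped."""
    var = np.asarray(var, dtype=float)
    if np.any(var < -1e-10):
        raise ValueError("negative prediction variance")
    sd = np.sqrt(np.clip(var, 0.0, None))
    zq = norm.ppf(0.5 + level / 2.0)
    pred = np.asarray(pred, dtype=float)
    return pred - zq * sd, pred + zq * sd
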