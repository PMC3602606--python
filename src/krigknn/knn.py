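"""k-nearest-neighbor imputation in covariate ("variable") space.

Distances between sites are quadratic forms d(a, b) = sqrt((a-b)' W (a-b))
with the weight matrix W defining the metric: identity (raw), inverse
empirical variances (normalized), inverse empirical covariance
(Mahalanobis), or the canonical-correlation construction W = G L^2 G'
known as most-similar-neighbor (MSN) distance.  Predictions copy or
average the responses of the k nearest observed sites; uncertainty comes
from a leave-one-out cross-validation standard error that is constant
across sites, with a finite-population scaling for block totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "DistanceSpec",
    "KnnModel",
    "variable_space_distance",
    "build_weight_matrix",
    "knn_predict",
    "cv_predictions",
    "knn_se_cv",
    "knn_interval",
    "knn_total",
    "knn_total_se",
    "select_bstNN",
    "BlockPrediction",
]

METRICS = ("raw", "normalized", "mahalanobis", "msn")
SCHEMES = ("mean", "inverse_distance", "single")

# distances this close to zero count as exact covariate matches
_ZERO_DIST = 1e-12


@dataclass(frozen=True)
class BlockPrediction:
    """A block (total or mean) estimate with its standard error."""

    estimate: float
    se: float


@dataclass(frozen=True)
class DistanceSpec:
    """A variable-space metric: name plus its p x p weight matrix."""

    metric: str
    W: np.ndarray

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric: {self.metric!r}")
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(W, W.T, atol=1e-8):
            raise ValueError("W must be symmetric")


@dataclass
class KnnModel:
    """A fitted k-NN predictor: metric, k, and averaging scheme."""

    spec: DistanceSpec
    k: int
    scheme: str = "mean"
    X_s: np.ndarray | None = None
    z_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme: {self.scheme!r}")


def variable_space_distance(A: np.ndarray, B: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Pairwise distances sqrt((a_i - b_j)' W (a_i - b_j)), shape (len(A), len(B))."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    W = np.asarray(W, dtype=float)
    if A.shape[1] != B.shape[1] or A.shape[1] != W.shape[0]:
        raise ValueError(
            f"dimension mismatch: A has {A.shape[1]} columns, B {B.shape[1]}, "
            f"W is {W.shape[0]}x{W.shape[1]}"
        )
    AW = A @ W
    BW = B @ W
    sq = (
        np.sum(AW * A, axis=1)[:, None]
        - A @ BW.T
        - AW @ B.T
        + np.sum(BW * B, axis=1)[None, :]
    )
    return np.sqrt(np.clip(sq, 0.0, None))


def build_weight_matrix(metric: str, X_s: np.ndarray, z_s: np.ndarray | None = None) -> DistanceSpec:
    """Estimate the weight matrix for a metric from the observed data.

    ``normalized`` and ``mahalanobis`` need only the covariates; ``msn``
    additionally needs the (non-constant) response, since its weight
    matrix is built from the canonical correlation between the two.
    """
    X_s = np.asarray(X_s, dtype=float)
    n, p = X_s.shape
    if metric == "raw":
        return DistanceSpec("raw", np.eye(p))
    if metric == "normalized":
        var = np.var(X_s, axis=0, ddof=1)
        if np.any(var <= 0):
            raise ValueError("normalized distance needs non-constant covariates")
        return DistanceSpec("normalized", np.diag(1.0 / var))
    if metric == "mahalanobis":
        if n <= p:
            raise ValueError("Mahalanobis distance needs n > p observed sites")
        S = np.atleast_2d(np.cov(X_s, rowvar=False, ddof=1))
        cond = np.linalg.cond(S)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                "sample covariance is singular; consider the normalized metric"
            )
        return DistanceSpec("mahalanobis", np.linalg.inv(S))
    if metric == "msn":
        if z_s is None:
            raise ValueError("msn metric requires the observed responses")
        z_s = np.asarray(z_s, dtype=float)
        if np.var(z_s) <= 0:
            raise ValueError("msn metric requires a non-constant response")
        return DistanceSpec("msn", _msn_weight_matrix(X_s, z_s))
    raise ValueError(f"unknown metric: {metric!r}")


def _msn_weight_matrix(X_s: np.ndarray, z_s: np.ndarray) -> np.ndarray:
    """W = g lam^2 g' from canonical correlation of X with a scalar response.

    With one response the canonical analysis has rank one: the canonical
    vector is g ∝ Sxx^{-1} s_xz normalized so var(g'x) = 1, and lam is
    the canonical (equivalently multiple) correlation.
    """
    Sxx = np.atleast_2d(np.cov(X_s, rowvar=False, ddof=1))
    sxz = np.atleast_1d(np.cov(np.column_stack([X_s, z_s]), rowvar=False, ddof=1)[:-1, -1])
    szz = np.var(z_s, ddof=1)
    a = np.linalg.solve(Sxx, sxz)
    quad = float(a @ Sxx @ a)
    if quad <= 0:
        raise np.linalg.LinAlgError("degenerate canonical analysis for msn metric")
    g = a / np.sqrt(quad)
    lam_sq = float(sxz @ np.linalg.solve(Sxx, sxz)) / szz
    lam_sq = min(max(lam_sq, 0.0), 1.0)
    return lam_sq * np.outer(g, g)


def _neighbor_weights(d_row: np.ndarray, k: int, scheme: str):
    """Ordered neighbor indices and convex weights for one prediction site.

    Ties in distance are broken by lowest observed-site index (argsort is
    stable).  Under inverse-distance weighting an exact covariate match
    short-circuits to weight one on that neighbor.
    """
    order = np.argsort(d_row, kind="stable")[:k]
    d = d_row[order]
    if scheme == "inverse_distance":
        if d[0] <= _ZERO_DIST:
            w = np.zeros(k)
            w[0] = 1.0
        else:
            w = 1.0 / d
            w = w / w.sum()
    else:  # mean / single (single is k=1 mean)
        w = np.full(k, 1.0 / k)
    return order, w


def knn_predict(
    model: KnnModel,
    z_s: np.ndarray,
    X_u: np.ndarray,
    X_s: np.ndarray | None = None,
    return_weights: bool = False,
):
    """Point predictions at the rows of X_u; optionally the full lambda matrix.

    The lambda matrix has one row per prediction site, k nonzero entries,
    each row nonnegative and summing to one.
    """
    X_s = model.X_s if X_s is None else np.asarray(X_s, dtype=float)
    z_s = np.asarray(z_s, dtype=float)
    n = X_s.shape[0]
    if model.k > n:
        raise ValueError(f"k={model.k} exceeds the {n} observed sites")
    D = variable_space_distance(X_u, X_s, model.spec.W)
    m = D.shape[0]
    preds = np.empty(m)
    lam = np.zeros((m, n)) if return_weights else None
    neighbors = []
    for i in range(m):
        order, w = _neighbor_weights(D[i], model.k, model.scheme)
        neighbors.append(order)
        preds[i] = float(w @ z_s[order])
        if lam is not None:
            lam[i, order] = w
    if return_weights:
        return preds, lam, neighbors
    return preds


def cv_predictions(
    spec: DistanceSpec,
    k: int,
    scheme: str,
    X_s: np.ndarray,
    z_s: np.ndarray,
    return_neighbors: bool = False,
):
    """Leave-one-out predictions of each observed site from the others.

    The weight matrix is held fixed (estimated once from all n sites);
    only the deleted site is removed from the candidate neighbors.
    """
    X_s = np.asarray(X_s, dtype=float)
    z_s = np.asarray(z_s, dtype=float)
    n = X_s.shape[0]
    if k > n - 1:
        raise ValueError(f"k={k} exceeds n-1={n - 1} for leave-one-out")
    D = variable_space_distance(X_s, X_s, spec.W)
    np.fill_diagonal(D, np.inf)
    preds = np.empty(n)
    neighbors = []
    for i in range(n):
        order, w = _neighbor_weights(D[i], k, scheme)
        neighbors.append(order)
        preds[i] = float(w @ z_s[order])
    if return_neighbors:
        return preds, neighbors
    return preds


def knn_se_cv(z_s: np.ndarray, cv_preds: np.ndarray) -> float:
    """Constant prediction SE: root mean squared leave-one-out error."""
    z_s = np.asarray(z_s, dtype=float)
    if z_s.size < 2:
        raise ValueError("need at least two observed sites")
    return float(np.sqrt(np.mean((z_s - np.asarray(cv_preds)) ** 2)))


def knn_interval(pred, se, level: float = 0.90):
    """Normal-theory prediction interval pred +/- z * se."""
    zq = norm.ppf(0.5 + level / 2.0)
    pred = np.asarray(pred, dtype=float)
    return pred - zq * se, pred + zq * se


def knn_total(
    z_s: np.ndarray,
    preds_u: np.ndarray,
    b_s: np.ndarray | float = 1.0,
    b_u: np.ndarray | float = 1.0,
) -> float:
    """Block estimate: observed part summed exactly, unobserved part imputed."""
    return float(np.sum(np.asarray(b_s) * np.asarray(z_s))
                 + np.sum(np.asarray(b_u) * np.asarray(preds_u)))


def knn_total_se(se_cv: float, N: int, n: int, b_sum: float | None = None) -> float:
    """Finite-population SE for a block estimate from the CV standard error.

    Classical sampling-theory scaling with the CV SE in place of the
    sample standard deviation: SE = |sum(b)| * sqrt((1 - n/N) / n) * se_cv,
    which is N * sqrt((1-f)/n) * se for a total and sqrt((1-f)/n) * se for
    a mean, and exactly zero at a census.
    """
    if n > N:
        raise ValueError("sample size cannot exceed population size")
    if b_sum is None:
        b_sum = float(N)
    f = n / N
    return float(abs(b_sum) * np.sqrt((1.0 - f) / n) * se_cv)


def select_bstNN(
    X_s: np.ndarray,
    z_s: np.ndarray,
    metric_grid=("mahalanobis", "msn"),
    k_grid=(1, 2, 3, 4, 5),
    scheme: str = "mean",
    return_table: bool = False,
):
    """Pick (metric, k) minimizing the leave-one-out RMSPE.

    Ties go to the smaller k, then to the earlier metric in
    ``metric_grid`` (Mahalanobis before MSN by default).
    """
    if not len(metric_grid) or not len(k_grid):
        raise ValueError("metric_grid and k_grid must be nonempty")
    z_s = np.asarray(z_s, dtype=float)
    table = []
    for rank, metric in enumerate(metric_grid):
        spec = build_weight_matrix(metric, X_s, z_s)
        for k in k_grid:
            cv = cv_predictions(spec, k, scheme, X_s, z_s)
            rmspe = float(np.sqrt(np.mean((z_s - cv) ** 2)))
            table.append((rmspe, k, rank, metric, spec))
    best = min(table, key=lambda row: (row[0], row[1], row[2]))
    if return_table:
        cv_table = [(metric, k, rmspe) for rmspe, k, _, metric, _ in table]
        return best[4], best[1], cv_table
    return best[4], best[1]
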