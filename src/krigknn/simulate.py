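"""Simulation of finite spatial populations for prediction experiments.

Generates populations on a regular grid with eight cross-correlated,
spatially autocorrelated covariates and a response that is Gaussian,
zero-inflated Poisson (log link), or binary (thresholded latent field).
The construction mirrors the design used throughout this package's
simulation experiments:

* covariates ``x1..x4`` and ``x5..x8`` form two groups; within a group an
  autoregressive-like recursion ``x_j = rho * x_{j-1} + w_j + delta_j``
  creates cross-correlation, while ``x5`` restarts the recursion so the
  two groups are mutually independent;
* each ``w_j`` is a zero-mean Gaussian random field with a spherical
  autocovariance (per-group partial sill and range) and each ``delta_j``
  is i.i.d. noise;
* the response is ``X beta + w0 + delta0`` on the latent scale, with
  ``w0`` a spherical random field.

Sampling designs cover simple random sampling and a spatially unbalanced
design that oversamples one quadrant of the domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import cdist

__all__ = [
    "GridSpec",
    "AutocovParams",
    "SimulationScenario",
    "SurveyPopulation",
    "SampleDesign",
    "make_grid",
    "autocov",
    "cov_matrix",
    "GaussianFieldSampler",
    "simulate_gaussian_field",
    "simulate_covariates",
    "simulate_response",
    "draw_sample",
    "simulate_population",
    "scenario_s1",
    "scenario_s2",
    "scenario_s3",
    "scenario_unbalanced",
    "population_to_csv",
    "population_from_csv",
    "scenario_to_yaml",
    "scenario_from_yaml",
]

# Diagonal jitter added on factorization failure, as a fraction of the
# total sill, escalating by 10x at most JITTER_MAX_TRIES times.
JITTER_FRACTION = 1e-10
JITTER_MAX_TRIES = 3


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """A regular n_side x n_side grid, evenly spaced within a rectangle.

    The default is the 20x20 grid on [-1, 1] x [-1, 1] used by every
    built-in scenario.  Site ordering is row-major (x varies fastest)
    and stable across calls.
    """

    n_side: int = 20
    extent: tuple[tuple[float, float], tuple[float, float]] = ((-1.0, 1.0), (-1.0, 1.0))

    def __post_init__(self) -> None:
        if self.n_side < 2:
            raise ValueError("n_side must be >= 2 for a spatial grid")
        for lo, hi in self.extent:
            if not hi > lo:
                raise ValueError("extent intervals must have positive length")

    @property
    def n_sites(self) -> int:
        return self.n_side ** 2


@dataclass(frozen=True)
class AutocovParams:
    """Isotropic autocovariance: nugget + partial sill + range.

    ``family`` selects the correlation model: ``exponential`` decays as
    exp(-d/range); ``spherical`` is exactly zero beyond ``range``.  The
    nugget contributes only at distance zero (measurement-error
    convention), so the value at d=0 is ``nugget + psill``.
    """

    nugget: float
    psill: float
    range: float
    family: str = "exponential"

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.psill < 0:
            raise ValueError("variance components must be nonnegative")
        if self.range <= 0:
            raise ValueError("range parameter must be positive")
        if self.family not in ("exponential", "spherical"):
            raise ValueError(f"unknown autocovariance family: {self.family!r}")

    @property
    def sill(self) -> float:
        return self.nugget + self.psill


@dataclass(frozen=True)
class SampleDesign:
    """Sampling design: simple random, or spatially unbalanced.

    The unbalanced design oversamples the quadrant below ``split`` on
    both axes: ``n_quadrant`` sites are drawn there and the remainder
    from the complement, emulating preferential geographic sampling.
    """

    kind: str = "srs"
    split: tuple[float, float] = (0.0, 0.0)
    quadrant_fraction: float = 52.0 / 100.0

    def __post_init__(self) -> None:
        if self.kind not in ("srs", "unbalanced"):
            raise ValueError(f"unknown sampling design: {self.kind!r}")
        if not 0.0 <= self.quadrant_fraction <= 1.0:
            raise ValueError("quadrant_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationScenario:
    """Full parameterization of one simulated-population recipe.

    ``mu`` and ``beta`` are the 8-vectors of covariate mean offsets and
    regression coefficients; ``rho_x`` drives the within-group
    cross-correlation recursion.  Group 1 covers w1..w4 and group 2
    covers w5..w8 (the latter with smaller sill and range).
    """

    scenario_id: str
    mu: tuple[float, ...]
    beta: tuple[float, ...]
    rho_x: float
    covariate_field_params: tuple[AutocovParams, AutocovParams]
    covariate_nugget_var: float
    response_field_params: AutocovParams
    response_family: str = "gaussian"
    binary_threshold: float = 0.0
    n_sample: int = 100
    design: SampleDesign = field(default_factory=SampleDesign)
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.mu) != 8 or len(self.beta) != 8:
            raise ValueError("mu and beta must have length 8")
        if self.covariate_nugget_var < 0:
            raise ValueError("covariate_nugget_var must be nonnegative")
        if self.response_family not in ("gaussian", "poisson_log", "binary_threshold"):
            raise ValueError(f"unknown response family: {self.response_family!r}")
        if self.n_sample < 1:
            raise ValueError("n_sample must be positive")


@dataclass(frozen=True)
class SurveyPopulation:
    """A finite population of N sites with an observed/unobserved split."""

    coords: np.ndarray
    X: np.ndarray
    z: np.ndarray
    observed_idx: np.ndarray
    unobserved_idx: np.ndarray

    def __post_init__(self) -> None:
        n_total = self.coords.shape[0]
        if self.X.shape[0] != n_total or self.z.shape[0] != n_total:
            raise ValueError("coords, X and z must have aligned rows")
        s = np.asarray(self.observed_idx)
        u = np.asarray(self.unobserved_idx)
        if np.intersect1d(s, u).size:
            raise ValueError("observed and unobserved index sets overlap")
        if s.size + u.size != n_total:
            raise ValueError("observed and unobserved sets must partition the population")

    @property
    def n_total(self) -> int:
        return self.coords.shape[0]

    @property
    def n_observed(self) -> int:
        return int(np.asarray(self.observed_idx).size)


# ---------------------------------------------------------------------------
# grid and autocovariance
# ---------------------------------------------------------------------------

def make_grid(spec: GridSpec) -> np.ndarray:
    """Coordinates of the regular grid, shape (n_side**2, 2), row-major."""
    (x_lo, x_hi), (y_lo, y_hi) = spec.extent
    xs = np.linspace(x_lo, x_hi, spec.n_side)
    ys = np.linspace(y_lo, y_hi, spec.n_side)
    xx, yy = np.meshgrid(xs, ys)  # x varies fastest within a row of sites
    return np.column_stack([xx.ravel(), yy.ravel()])


def autocov(dist, params: AutocovParams):
    """Autocovariance C(d) for scalar or array distances.

    C(0) = nugget + psill; for d > 0 the nugget does not contribute.
    """
    d = np.asarray(dist, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if params.family == "exponential":
        corr = np.exp(-d / params.range)
    else:  # spherical: compact support beyond the range
        u = np.minimum(d / params.range, 1.0)
        corr = 1.0 - 1.5 * u + 0.5 * u ** 3
    out = params.psill * corr + params.nugget * (d == 0)
    return out if out.ndim else float(out)


def cov_matrix(coords_a: np.ndarray, coords_b: np.ndarray | None, params: AutocovParams) -> np.ndarray:
    """Model covariance matrix between two coordinate sets.

    With ``coords_b is None`` the symmetric within-set matrix is built
    (nugget on the diagonal).  For cross-matrices the nugget appears
    only where sites coincide exactly.
    """
    if coords_b is None:
        d = cdist(coords_a, coords_a)
        np.fill_diagonal(d, 0.0)
        return autocov(d, params)
    return autocov(cdist(coords_a, coords_b), params)


class GaussianFieldSampler:
    """Draws zero-mean Gaussian fields with a fixed covariance.

    Caches the Cholesky factor of the model covariance so repeated
    draws on the same site set (the common case in replicated
    experiments) cost one matrix-vector product each.
    """

    def __init__(self, coords: np.ndarray, params: AutocovParams):
        self.coords = np.asarray(coords, dtype=float)
        self.params = params
        if params.sill == 0:
            self._chol = np.zeros((self.coords.shape[0], self.coords.shape[0]))
        else:
            sigma = cov_matrix(self.coords, None, params)
            self._chol = _chol_with_jitter(sigma, params.sill)

    def draw(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        n = self.coords.shape[0]
        if size is None:
            return self._chol @ rng.standard_normal(n)
        return rng.standard_normal((size, n)) @ self._chol.T


def _chol_with_jitter(sigma: np.ndarray, sill: float) -> np.ndarray:
    """Lower Cholesky factor with escalating diagonal jitter on failure."""
    scale = sill if sill > 0 else max(float(np.max(np.abs(sigma))), 1.0)
    jitter = 0.0
    for attempt in range(JITTER_MAX_TRIES + 1):
        try:
            return np.linalg.cholesky(sigma + jitter * np.eye(sigma.shape[0]))
        except np.linalg.LinAlgError:
            jitter = JITTER_FRACTION * scale * 10 ** attempt
    raise np.linalg.LinAlgError(
        "covariance matrix not positive definite after "
        f"{JITTER_MAX_TRIES} jitter escalations (sill={sill:g}, "
        f"final jitter={jitter:g})"
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_gaussian_field(coords: np.ndarray, params: AutocovParams, seed=None) -> np.ndarray:
    """One zero-mean Gaussian field realization with covariance from ``params``."""
    return GaussianFieldSampler(coords, params).draw(_as_rng(seed))


# ---------------------------------------------------------------------------
# covariates and response
# ---------------------------------------------------------------------------

def simulate_covariates(
    scenario: SimulationScenario,
    coords: np.ndarray,
    seed=None,
    samplers: tuple[GaussianFieldSampler, GaussianFieldSampler] | None = None,
) -> np.ndarray:
    """The N x 8 covariate matrix for one population.

    ``x1 = w1 + d1``; within each group ``x_j = rho_x * x_{j-1} + w_j + d_j``;
    ``x5`` restarts, breaking cross-correlation between the groups.  The
    constant offsets ``mu`` are added last.  Pass ``samplers`` (one per
    group, built on ``coords``) to reuse cached Cholesky factors.
    """
    rng = _as_rng(seed)
    n = coords.shape[0]
    if samplers is None:
        samplers = (
            GaussianFieldSampler(coords, scenario.covariate_field_params[0]),
            GaussianFieldSampler(coords, scenario.covariate_field_params[1]),
        )
    sd_delta = np.sqrt(scenario.covariate_nugget_var)
    X = np.empty((n, 8))
    for j in range(8):
        group = 0 if j < 4 else 1
        w = samplers[group].draw(rng)
        delta = sd_delta * rng.standard_normal(n) if sd_delta > 0 else 0.0
        if j in (0, 4):  # fresh start of each group's recursion
            X[:, j] = w + delta
        else:
            X[:, j] = scenario.rho_x * X[:, j - 1] + w + delta
    return X + np.asarray(scenario.mu)


# Latent values above this make exp() useless for Poisson sampling.
_POISSON_LATENT_CAP = 30.0


def simulate_response(
    X: np.ndarray,
    scenario: SimulationScenario,
    coords: np.ndarray,
    seed=None,
    sampler: GaussianFieldSampler | None = None,
) -> np.ndarray:
    """Response vector: latent = X beta + w0 (+ nugget noise), then transformed.

    gaussian: the latent itself.  poisson_log: Poisson(exp(latent)) —
    raises if the latent is large enough to overflow, pointing at the
    smaller-coefficient count parameterization.  binary_threshold:
    1{latent > threshold}.
    """
    rng = _as_rng(seed)
    if X.shape[1] != 8:
        raise ValueError("X must have 8 columns")
    if sampler is None:
        sampler = GaussianFieldSampler(coords, scenario.response_field_params)
    latent = X @ np.asarray(scenario.beta) + sampler.draw(rng)
    if scenario.response_family == "gaussian":
        return latent
    if scenario.response_family == "poisson_log":
        if np.max(latent) > _POISSON_LATENT_CAP:
            raise FloatingPointError(
                "latent field too large for Poisson(exp(latent)); use the "
                "count scenario's smaller regression coefficients and "
                "response variances"
            )
        return rng.poisson(np.exp(latent)).astype(float)
    return (latent > scenario.binary_threshold).astype(float)


# ---------------------------------------------------------------------------
# sampling designs
# ---------------------------------------------------------------------------

def draw_sample(
    coords: np.ndarray,
    design: SampleDesign,
    n: int,
    seed=None,
) -> np.ndarray:
    """Indices of the observed sites under the requested design, sorted."""
    rng = _as_rng(seed)
    n_total = coords.shape[0]
    if n > n_total:
        raise ValueError(f"cannot sample {n} of {n_total} sites")
    if design.kind == "srs":
        return np.sort(rng.choice(n_total, size=n, replace=False))
    x0, y0 = design.split
    in_quad = (coords[:, 0] < x0) & (coords[:, 1] < y0)
    quad = np.flatnonzero(in_quad)
    rest = np.flatnonzero(~in_quad)
    n_quad = int(round(design.quadrant_fraction * n))
    n_rest = n - n_quad
    if n_quad > quad.size or n_rest > rest.size:
        raise ValueError(
            f"unbalanced design needs {n_quad} of {quad.size} quadrant sites "
            f"and {n_rest} of {rest.size} others"
        )
    picked = np.concatenate([
        rng.choice(quad, size=n_quad, replace=False) if n_quad else np.empty(0, int),
        rng.choice(rest, size=n_rest, replace=False) if n_rest else np.empty(0, int),
    ])
    return np.sort(picked)


def simulate_population(
    scenario: SimulationScenario,
    grid: GridSpec = GridSpec(),
    seed=None,
    samplers=None,
) -> SurveyPopulation:
    """One full population draw plus its observed/unobserved partition.

    ``samplers`` may carry a triple of :class:`GaussianFieldSampler`
    (group 1, group 2, response) to amortize Cholesky factorizations
    across replicates.
    """
    rng = _as_rng(seed if seed is not None else scenario.seed)
    coords = make_grid(grid)
    if samplers is None:
        samplers = build_samplers(scenario, coords)
    g1, g2, resp = samplers
    X = simulate_covariates(scenario, coords, rng, samplers=(g1, g2))
    z = simulate_response(X, scenario, coords, rng, sampler=resp)
    s = draw_sample(coords, scenario.design, scenario.n_sample, rng)
    u = np.setdiff1d(np.arange(coords.shape[0]), s)
    return SurveyPopulation(coords=coords, X=X, z=z, observed_idx=s, unobserved_idx=u)


def build_samplers(scenario: SimulationScenario, coords: np.ndarray):
    """The (group1, group2, response) field samplers for a scenario."""
    return (
        GaussianFieldSampler(coords, scenario.covariate_field_params[0]),
        GaussianFieldSampler(coords, scenario.covariate_field_params[1]),
        GaussianFieldSampler(coords, scenario.response_field_params),
    )


# ---------------------------------------------------------------------------
# built-in scenarios
# ---------------------------------------------------------------------------
#
# The covariate structure is shared by all scenarios: two groups of four
# spherical fields, the second group with half the sill and range of the
# first, weak independent noise, and a strong within-group recursion.
# S1 is the Gaussian response with a large, strongly autocorrelated error
# field; S2 shrinks the coefficients and response variances so that
# exp(latent) stays in a realistic count range while the latent still
# drops below zero over patches (zero inflation); S3 thresholds the S2
# latent at zero.

_COV_GROUP1 = AutocovParams(nugget=0.0, psill=1.0, range=1.5, family="spherical")
_COV_GROUP2 = AutocovParams(nugget=0.0, psill=0.5, range=0.75, family="spherical")
_COV_NUGGET_VAR = 0.1
_RHO_X = 0.9

_MU_S1 = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0)
_MU_S2 = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
_BETA_S1 = (0.0, 0.5, 0.5, 0.5, 0.0, 0.5, 0.5, 0.5)
_BETA_S2 = (0.0, 0.05, 0.05, 0.05, 0.0, 0.05, 0.05, 0.05)

_RESPONSE_S1 = AutocovParams(nugget=2.0, psill=12.0, range=2.0, family="spherical")
_RESPONSE_S2 = AutocovParams(nugget=0.1, psill=0.8, range=2.0, family="spherical")

#: Covariate columns used by every predictor (0-based): x1,x2,x3,x5,x6,x7.
#: This deliberately includes the two null covariates and excludes x4 and
#: x8, whose coefficients are real.
FITTED_COVARIATES = (0, 1, 2, 4, 5, 6)


def _base(scenario_id, mu, beta, response, family, design=None, seed=None):
    return SimulationScenario(
        scenario_id=scenario_id,
        mu=mu,
        beta=beta,
        rho_x=_RHO_X,
        covariate_field_params=(_COV_GROUP1, _COV_GROUP2),
        covariate_nugget_var=_COV_NUGGET_VAR,
        response_field_params=response,
        response_family=family,
        n_sample=100,
        design=design or SampleDesign(),
        seed=seed,
    )


def scenario_s1(seed: int | None = None) -> SimulationScenario:
    """Gaussian response with strong spatial autocorrelation."""
    return _base("S1", _MU_S1, _BETA_S1, _RESPONSE_S1, "gaussian", seed=seed)


def scenario_s2(seed: int | None = None) -> SimulationScenario:
    """Zero-inflated counts: Poisson of the exponentiated latent field."""
    return _base("S2", _MU_S2, _BETA_S2, _RESPONSE_S2, "poisson_log", seed=seed)


def scenario_s3(seed: int | None = None) -> SimulationScenario:
    """Binary response: indicator of the S2 latent field above zero."""
    return _base("S3", _MU_S2, _BETA_S2, _RESPONSE_S2, "binary_threshold", seed=seed)


def scenario_unbalanced(seed: int | None = None) -> SimulationScenario:
    """S1 surfaces sampled preferentially from the lower-left quadrant."""
    design = SampleDesign(kind="unbalanced")
    return _base("UN", _MU_S1, _BETA_S1, _RESPONSE_S1, "gaussian", design=design, seed=seed)


SCENARIOS = {
    "S1": scenario_s1,
    "S2": scenario_s2,
    "S3": scenario_s3,
    "UN": scenario_unbalanced,
}


# ---------------------------------------------------------------------------
# external interfaces: CSV populations, YAML scenarios
# ---------------------------------------------------------------------------

def population_to_frame(pop: SurveyPopulation) -> pd.DataFrame:
    observed = np.zeros(pop.n_total, dtype=int)
    observed[np.asarray(pop.observed_idx)] = 1
    data = {"x_coord": pop.coords[:, 0], "y_coord": pop.coords[:, 1]}
    for j in range(pop.X.shape[1]):
        data[f"x{j + 1}"] = pop.X[:, j]
    data["z"] = pop.z
    data["observed"] = observed
    return pd.DataFrame(data)


def population_to_csv(pop: SurveyPopulation, path) -> None:
    population_to_frame(pop).to_csv(path, index=False)


def population_from_csv(path) -> SurveyPopulation:
    df = pd.read_csv(path)
    xcols = sorted(
        (c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    observed = df["observed"].to_numpy().astype(bool)
    return SurveyPopulation(
        coords=df[["x_coord", "y_coord"]].to_numpy(float),
        X=df[xcols].to_numpy(float),
        z=df["z"].to_numpy(float),
        observed_idx=np.flatnonzero(observed),
        unobserved_idx=np.flatnonzero(~observed),
    )


_FAMILY_TO_YAML = {"gaussian": "gaussian", "poisson_log": "poisson_log",
                   "binary_threshold": "binary_threshold"}


def scenario_to_yaml(scenario: SimulationScenario, path) -> None:
    g1, g2 = scenario.covariate_field_params
    resp = scenario.response_field_params
    doc = {
        "scenario_id": scenario.scenario_id,
        "mu": list(scenario.mu),
        "beta": list(scenario.beta),
        "rho_x": scenario.rho_x,
        "covariate_sill": [g1.psill, g2.psill],
        "covariate_range": [g1.range, g2.range],
        "covariate_nugget": scenario.covariate_nugget_var,
        "response_sill": resp.psill,
        "response_range": resp.range,
        "response_nugget": resp.nugget,
        "family": _FAMILY_TO_YAML[scenario.response_family],
        "n_sample": scenario.n_sample,
        "seed": scenario.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def scenario_from_yaml(path) -> SimulationScenario:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    sills = doc["covariate_sill"]
    ranges = doc["covariate_range"]
    return SimulationScenario(
        scenario_id=doc.get("scenario_id", "custom"),
        mu=tuple(doc["mu"]),
        beta=tuple(doc["beta"]),
        rho_x=float(doc["rho_x"]),
        covariate_field_params=(
            AutocovParams(0.0, float(sills[0]), float(ranges[0]), "spherical"),
            AutocovParams(0.0, float(sills[1]), float(ranges[1]), "spherical"),
        ),
        covariate_nugget_var=float(doc["covariate_nugget"]),
        response_field_params=AutocovParams(
            float(doc["response_nugget"]), float(doc["response_sill"]),
            float(doc["response_range"]), "spherical",
        ),
        response_family=doc["family"],
        n_sample=int(doc["n_sample"]),
        seed=doc.get("seed"),
    )
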