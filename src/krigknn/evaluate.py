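"""Simulation experiments and performance summaries.

Runs replicated prediction experiments on simulated populations and
summarizes them in the measure x scenario x (point/total) x method grid
used throughout this package: RMSPE, signed relative bias (SRB), 90/95%
prediction-interval coverage (PIC), percent correctly classified (PCC)
for binary targets, and a Kendall-tau calibration experiment relating
estimated standard errors to realized absolute errors.

Every predictor sees the same deliberately mis-specified design: six of
the eight covariates (two null covariates included, two covariates with
real effects excluded) and, for the spatial linear model, an exponential
autocovariance fit to data generated from a spherical one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, norm

from . import knn as _knn
from . import knn_uncertainty as _uq
from . import slm as _slm
from .simulate import (
    FITTED_COVARIATES,
    GridSpec,
    SimulationScenario,
    SurveyPopulation,
    build_samplers,
    make_grid,
    simulate_covariates,
    simulate_response,
    draw_sample,
)

__all__ = [
    "ExperimentConfig",
    "rmspe",
    "srb",
    "pic",
    "pcc",
    "kendall_calibration",
    "run_experiment",
    "run_calibration",
    "CalibrationResult",
    "ALL_METHODS",
]

logger = logging.getLogger("krigknn")

ALL_METHODS = ("MAH1", "MAH5", "MSN1", "MSN5", "bstNN", "LM", "SLM")

_KNN_METHODS = {
    "MAH1": ("mahalanobis", 1),
    "MAH5": ("mahalanobis", 5),
    "MSN1": ("msn", 1),
    "MSN5": ("msn", 5),
}


# ---------------------------------------------------------------------------
# performance measures
# ---------------------------------------------------------------------------

def rmspe(truth, pred) -> float:
    """Root-mean-squared prediction error over all entries."""
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction shapes must match")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def srb(truth, pred) -> float:
    """Signed relative bias: sign(bias) * bias^2 / error variance.

    Bias squared plus the error variance equals the mean squared
    prediction error exactly, so SRB expresses the bias component as a
    signed fraction of the variability.  Positive values indicate
    over-prediction.
    """
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction shapes must match")
    err = pred - truth
    bias = float(np.mean(err))
    var = float(np.mean(err ** 2)) - bias ** 2
    if var <= 0:
        if bias == 0:
            return 0.0
        import warnings

        warnings.warn("zero error variance with nonzero bias; SRB is infinite")
        return float(np.sign(bias) * np.inf)
    return float(np.sign(bias) * bias ** 2 / var)


def pic(truth, pred, se, level: float = 0.90) -> float:
    """Empirical prediction-interval coverage at a nominal level."""
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    se = np.broadcast_to(np.asarray(se, dtype=float), truth.shape)
    if np.any(se < 0):
        raise ValueError("standard errors must be nonnegative")
    zq = norm.ppf(0.5 + level / 2.0)
    return float(np.mean(np.abs(truth - pred) <= zq * se))


def pcc(truth, pred) -> float:
    """Percent correctly classified; non-binary predictions round at 0.5."""
    truth = np.asarray(truth, dtype=float)
    if not np.all(np.isin(truth, (0.0, 1.0))):
        raise ValueError("truth must be binary (0/1)")
    rounded = (np.asarray(pred, dtype=float) >= 0.5).astype(float)
    return float(np.mean(rounded == truth))


def kendall_calibration(abs_errors, ses):
    """Kendall tau-b between absolute errors and estimated SEs.

    Returns ``(tau, degenerate)``; a constant input (e.g. the constant
    cross-validation SE) makes tau undefined and yields (0.0, True).
    """
    abs_errors = np.asarray(abs_errors, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if abs_errors.size != ses.size or abs_errors.size < 2:
        raise ValueError("need two equal-length vectors")
    if np.ptp(ses) == 0 or np.ptp(abs_errors) == 0:
        return 0.0, True
    tau = kendalltau(abs_errors, ses, variant="b").statistic
    return float(tau), False


# ---------------------------------------------------------------------------
# experiment harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """One replicated simulation experiment.

    The block target defaults by scenario: the population mean
    (estimated proportion) for binary responses, the total otherwise.
    """

    scenario: SimulationScenario
    n_reps: int
    methods: tuple[str, ...] = ALL_METHODS
    seed: int = 0
    grid: GridSpec = field(default_factory=GridSpec)
    block_target: str | None = None

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        if not self.methods:
            raise ValueError("at least one method is required")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @property
    def resolved_block_target(self) -> str:
        if self.block_target is not None:
            return self.block_target
        return "mean" if self.scenario.response_family == "binary_threshold" else "total"


def _design(X: np.ndarray, idx, with_intercept: bool) -> np.ndarray:
    """The fitted six-covariate design, optionally with an intercept."""
    sub = X[np.ix_(np.asarray(idx), np.array(FITTED_COVARIATES))]
    if with_intercept:
        return np.column_stack([np.ones(sub.shape[0]), sub])
    return sub


def _predict_knn(method, X_s, z_s, X_u, N, n, b_sum, b_s, b_u):
    if method == "bstNN":
        spec, k = _knn.select_bstNN(X_s, z_s)
    else:
        metric, k = _KNN_METHODS[method]
        spec = _knn.build_weight_matrix(metric, X_s, z_s)
    model = _knn.KnnModel(spec=spec, k=k, scheme="mean", X_s=X_s, z_s=z_s)
    preds = _knn.knn_predict(model, z_s, X_u)
    cv = _knn.cv_predictions(spec, k, "mean", X_s, z_s)
    se_cv = _knn.knn_se_cv(z_s, cv)
    point_se = np.full(preds.shape, se_cv)
    block_est = _knn.knn_total(z_s, preds, b_s=b_s, b_u=b_u)
    block_se = _knn.knn_total_se(se_cv, N, n, b_sum=b_sum)
    return preds, point_se, block_est, block_se


def _predict_lm(pop, ds, du, b):
    s, u = np.asarray(pop.observed_idx), np.asarray(pop.unobserved_idx)
    out, fit = _slm.lm_fit_predict(
        ds, pop.z[s], du, coords_s=pop.coords[s], coords_u=pop.coords[u]
    )
    block = _slm.eblup_block(fit, pop, b, X_u=du)
    return out.pred, out.se, block.estimate, block.se


def _predict_slm(pop, ds, du, b):
    s, u = np.asarray(pop.observed_idx), np.asarray(pop.unobserved_idx)
    fit = _slm.fit_reml(pop.coords[s], ds, pop.z[s])
    out = _slm.eblup_point(fit, du, pop.coords[u])
    block = _slm.eblup_block(fit, pop, b, X_u=du)
    return out.pred, out.se, block.estimate, block.se


def _replicate_population(scenario, coords, samplers, rng) -> SurveyPopulation:
    X = simulate_covariates(scenario, coords, rng, samplers=samplers[:2])
    z = simulate_response(X, scenario, coords, rng, sampler=samplers[2])
    s = draw_sample(coords, scenario.design, scenario.n_sample, rng)
    u = np.setdiff1d(np.arange(coords.shape[0]), s)
    return SurveyPopulation(coords=coords, X=X, z=z, observed_idx=s, unobserved_idx=u)


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Replicate the scenario and summarize every requested method.

    Returns the long-format performance table with one row per
    (measure, scenario, point/total, method) cell, each carrying a
    Monte-Carlo standard error.  Replicates use independent seeded
    streams spawned from the root seed, so results do not depend on
    execution order.
    """
    scenario = config.scenario
    coords = make_grid(config.grid)
    samplers = build_samplers(scenario, coords)
    N = coords.shape[0]
    block_target = config.resolved_block_target
    binary = scenario.response_family == "binary_threshold"
    zq90 = norm.ppf(0.95)

    acc = {
        m: {"mspe": [], "bias": [], "cov90": [], "pcc": [],
            "terr": [], "tse": []}
        for m in config.methods
    }
    failures = {m: 0 for m in config.methods}

    streams = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pop = _replicate_population(scenario, coords, samplers, rng)
        s, u = np.asarray(pop.observed_idx), np.asarray(pop.unobserved_idx)
        z_s, z_u = pop.z[s], pop.z[u]
        n = s.size
        X_s6 = _design(pop.X, s, with_intercept=False)
        X_u6 = _design(pop.X, u, with_intercept=False)
        ds = _design(pop.X, s, with_intercept=True)
        du = _design(pop.X, u, with_intercept=True)
        if block_target == "total":
            b = np.ones(N)
        else:
            b = np.full(N, 1.0 / N)
        b_sum = float(b.sum())
        true_block = float(b @ pop.z)

        for method in config.methods:
            try:
                if method in _KNN_METHODS or method == "bstNN":
                    preds, pse, best, bse = _predict_knn(
                        method, X_s6, z_s, X_u6, N, n, b_sum, b[s], b[u]
                    )
                elif method == "LM":
                    preds, pse, best, bse = _predict_lm(pop, ds, du, b)
                elif method == "SLM":
                    preds, pse, best, bse = _predict_slm(pop, ds, du, b)
                else:  # pragma: no cover - guarded by config validation
                    raise ValueError(method)
            except Exception:
                failures[method] += 1
                logger.exception("method %s failed on replicate %d", method, rep)
                continue
            err = preds - z_u
            a = acc[method]
            if err.size:  # a census leaves nothing to point-predict
                a["mspe"].append(float(np.mean(err ** 2)))
                a["bias"].append(float(np.mean(err)))
                a["cov90"].append(float(np.mean(np.abs(err) <= zq90 * pse)))
                if binary:
                    a["pcc"].append(pcc(z_u, preds))
            a["terr"].append(best - true_block)
            a["tse"].append(float(bse))

    return _summarize(acc, failures, scenario.scenario_id, binary, config.n_reps)


def _mc(vals):
    vals = np.asarray(vals, dtype=float)
    if vals.size < 2:
        return 0.0
    return float(np.std(vals, ddof=1) / np.sqrt(vals.size))


def _summarize(acc, failures, scenario_id, binary, n_reps) -> pd.DataFrame:
    rows = []

    def add(measure, pt, method, value, mc_se, n_used):
        rows.append({
            "measure": measure, "scenario": scenario_id, "point_or_total": pt,
            "method": method, "value": value, "mc_se": mc_se,
            "n_reps_used": n_used, "n_reps_requested": n_reps,
        })

    zq90 = norm.ppf(0.95)
    for method, a in acc.items():
        m_used = len(a["terr"])
        if m_used == 0:
            continue
        if a["mspe"]:  # point rows (absent under census sampling)
            mspe = np.asarray(a["mspe"])
            bias = np.asarray(a["bias"])
            if binary:
                add("PCC", "P", method, float(np.mean(a["pcc"])), _mc(a["pcc"]), m_used)
            else:
                val = float(np.sqrt(np.mean(mspe)))
                add("RMSPE", "P", method, val,
                    _mc(mspe) / (2.0 * val) if val > 0 else 0.0, m_used)
            b = float(np.mean(bias))
            var = float(np.mean(mspe)) - b ** 2
            srb_val = float(np.sign(b) * b ** 2 / var) if var > 0 else 0.0
            per_rep_srb = np.sign(bias) * bias ** 2 / np.maximum(mspe - bias ** 2, 1e-300)
            add("SRB", "P", method, srb_val, _mc(per_rep_srb), m_used)
            add("PIC90", "P", method, float(np.mean(a["cov90"])), _mc(a["cov90"]), m_used)
        # total rows
        terr = np.asarray(a["terr"])
        tse = np.asarray(a["tse"])
        tot_mspe = terr ** 2
        val = float(np.sqrt(np.mean(tot_mspe)))
        add("RMSPE", "T", method, val, _mc(tot_mspe) / (2.0 * val) if val > 0 else 0.0, m_used)
        tb = float(np.mean(terr))
        tvar = float(np.mean(tot_mspe)) - tb ** 2
        add("SRB", "T", method, float(np.sign(tb) * tb ** 2 / tvar) if tvar > 0 else 0.0,
            np.nan, m_used)
        cov_t = (np.abs(terr) <= zq90 * tse).astype(float)
        add("PIC90", "T", method, float(np.mean(cov_t)), _mc(cov_t), m_used)
        if failures[method]:
            logger.warning("%s failed on %d/%d replicates", method,
                           failures[method], n_reps)
    df = pd.DataFrame(rows)
    _assert_table_invariants(df)
    return df


def _assert_table_invariants(df: pd.DataFrame) -> None:
    pic_rows = df[df["measure"].str.startswith("PIC") | (df["measure"] == "PCC")]
    if not ((pic_rows["value"] >= 0) & (pic_rows["value"] <= 1)).all():
        raise AssertionError("coverage/classification cells must lie in [0, 1]")
    rmspe_rows = df[df["measure"] == "RMSPE"]
    if not (rmspe_rows["value"] >= 0).all():
        raise AssertionError("RMSPE cells must be nonnegative")


def pivot_table1(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long table into the (measure, scenario, P/T) x method grid."""
    return df.pivot_table(
        index=["measure", "scenario", "point_or_total"],
        columns="method", values="value",
    )


# ---------------------------------------------------------------------------
# calibration experiment (SE vs realized absolute error)
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Kendall-tau distributions and global coverages for three SE estimators."""

    taus: dict[str, np.ndarray]
    coverage: dict[str, float]
    coverage_mc_se: dict[str, float]
    itervar_convergence_rate: float
    itervar_divergence_rate: float
    n_reps: int


def run_calibration(
    scenario: SimulationScenario,
    n_reps: int,
    seed: int = 0,
    metric: str = "msn",
    k: int = 5,
    grid: GridSpec = GridSpec(),
) -> CalibrationResult:
    """Compare EBLUP, IterVar and kNNGeo standard errors to actual errors.

    Per replicate: fit the SLM (for EBLUP SEs and for the kNNGeo
    covariance/trend), run the mean-of-k k-NN predictor, estimate its
    per-site SEs by the iterated variogram and by the model-based
    RMSPE, then record the Kendall rank correlation between each SE
    vector and the realized absolute errors, plus 90% interval coverage
    for the two k-NN estimators.
    """
    coords = make_grid(grid)
    samplers = build_samplers(scenario, coords)
    zq90 = norm.ppf(0.95)
    taus = {"EBLUP": [], "IterVar": [], "kNNGeo": []}
    cover = {"IterVar": [], "kNNGeo": []}
    converged, diverged = [], []

    streams = np.random.SeedSequence(seed).spawn(n_reps)
    for ss in streams:
        rng = np.random.default_rng(ss)
        pop = _replicate_population(scenario, coords, samplers, rng)
        s, u = np.asarray(pop.observed_idx), np.asarray(pop.unobserved_idx)
        z_s, z_u = pop.z[s], pop.z[u]
        X_s6 = _design(pop.X, s, with_intercept=False)
        X_u6 = _design(pop.X, u, with_intercept=False)
        ds = _design(pop.X, s, with_intercept=True)
        du = _design(pop.X, u, with_intercept=True)
        coords_s, coords_u = pop.coords[s], pop.coords[u]

        fit = _slm.fit_reml(coords_s, ds, z_s)
        eblup = _slm.eblup_point(fit, du, coords_u)

        spec = _knn.build_weight_matrix(metric, X_s6, z_s)
        model = _knn.KnnModel(spec=spec, k=k, scheme="mean", X_s=X_s6, z_s=z_s)
        preds, lam, _ = _knn.knn_predict(model, z_s, X_u6, return_weights=True)
        knn_abs_err = np.abs(preds - z_u)

        state, var_u = _uq.itervar(coords_s, X_s6, z_s, spec, k,
                                   coords_u=coords_u, X_u=X_u6)
        itervar_se = np.sqrt(var_u)
        knngeo_se = _uq.knngeo_rmspe(lam, fit, ds, du, coords_u)

        taus["EBLUP"].append(kendall_calibration(np.abs(eblup.pred - z_u), eblup.se)[0])
        taus["IterVar"].append(kendall_calibration(knn_abs_err, itervar_se)[0])
        taus["kNNGeo"].append(kendall_calibration(knn_abs_err, knngeo_se)[0])
        cover["IterVar"].append(float(np.mean(knn_abs_err <= zq90 * itervar_se)))
        cover["kNNGeo"].append(float(np.mean(knn_abs_err <= zq90 * knngeo_se)))
        converged.append(state.converged)
        diverged.append(state.diverged)

    return CalibrationResult(
        taus={k_: np.asarray(v) for k_, v in taus.items()},
        coverage={k_: float(np.mean(v)) for k_, v in cover.items()},
        coverage_mc_se={k_: _mc(v) for k_, v in cover.items()},
        itervar_convergence_rate=float(np.mean(converged)),
        itervar_divergence_rate=float(np.mean(diverged)),
        n_reps=n_reps,
    )
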