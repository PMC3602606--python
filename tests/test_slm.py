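"""Tests for REML estimation and (E)BLUP point/block prediction."""

import numpy as np
import pytest

from krigknn import (
    AutocovParams,
    GridSpec,
    SurveyPopulation,
    cov_matrix,
    eblup_block,
    eblup_point,
    fit_reml,
    lm_fit_predict,
    make_grid,
    reml_objective,
    slm_interval,
)
from krigknn.slm import SlmFit, _RemlProblem


def make_fit(params, coords_s, X_s, z_s, beta=None):
    """An SlmFit with known covariance parameters plugged in directly."""
    if beta is None:
        # GLS coefficients at the given covariance
        S = cov_matrix(coords_s, None, params)
        Si = np.linalg.inv(S)
        beta = np.linalg.solve(X_s.T @ Si @ X_s, X_s.T @ Si @ z_s)
    return SlmFit(params=params, beta_gls=np.asarray(beta, float), reml_value=np.nan,
                  converged=True, coords_s=coords_s, X_s=X_s, z_s=z_s)


def explicit_blup(params, coords_s, X_s, z_s, x_u, coord_u):
    """Direct matrix-algebra universal-kriging weights (independent path)."""
    S = cov_matrix(coords_s, None, params)
    c = cov_matrix(coords_s, np.atleast_2d(coord_u), params)[:, 0]
    Si = np.linalg.inv(S)
    A = X_s.T @ Si @ X_s
    d = x_u - X_s.T @ Si @ c
    lam = Si @ (c + X_s @ np.linalg.solve(A, d))
    var = params.sill - c @ Si @ c + d @ np.linalg.solve(A, d)
    return lam, var


class TestRemlObjective:
    def test_independence_profile_matches_closed_form(self, toy_observed):
        """With psill ~ 0 the REML variance optimum is r'r/(n-p)."""
        coords, X, z = toy_observed
        X1 = np.column_stack([np.ones(len(z)), X])
        beta = np.linalg.lstsq(X1, z, rcond=None)[0]
        r = z - X1 @ beta
        s2_hat = r @ r / (len(z) - X1.shape[1])
        grid = s2_hat * np.linspace(0.3, 3.0, 61)
        vals = [
            reml_objective(AutocovParams(s2, 1e-12, 1.0), coords, X1, z, )
            for s2 in grid
        ]
        assert grid[int(np.argmin(vals))] == pytest.approx(s2_hat, rel=0.05)

    def test_permutation_invariance_and_determinism(self, toy_observed):
        coords, X, z = toy_observed
        X1 = np.column_stack([np.ones(len(z)), X])
        params = AutocovParams(0.3, 1.0, 0.7)
        v1 = reml_objective(params, coords, X1, z)
        assert v1 == reml_objective(params, coords, X1, z)
        perm = np.random.default_rng(0).permutation(len(z))
        v2 = reml_objective(params, coords[perm], X1[perm], z[perm])
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_matches_naive_linear_algebra(self, toy_observed):
        """The factorized objective equals an explicit-inverse evaluation."""
        coords, X, z = toy_observed
        X1 = np.column_stack([np.ones(len(z)), X])
        params = AutocovParams(0.4, 1.3, 0.6)
        S = cov_matrix(coords, None, params)
        Si = np.linalg.inv(S)
        A = X1.T @ Si @ X1
        beta = np.linalg.solve(A, X1.T @ Si @ z)
        r = z - X1 @ beta
        naive = (np.linalg.slogdet(S)[1] + np.linalg.slogdet(A)[1] + r @ Si @ r)
        assert reml_objective(params, coords, X1, z) == pytest.approx(naive, rel=1e-8)


class TestFitReml:
    def test_optimum_not_above_any_grid_start(self, rng):
        coords = make_grid(GridSpec(7))
        n = coords.shape[0]
        params = AutocovParams(0.5, 2.0, 0.8)
        L = np.linalg.cholesky(cov_matrix(coords, None, params))
        z = 1.0 + L @ rng.standard_normal(n)
        X = np.ones((n, 1))
        fit = fit_reml(coords, X, z)
        prob = _RemlProblem(coords, X, z)
        for f in np.linspace(0.05, 0.95, 5):
            for a in np.geomspace(0.1, 2.0, 5):
                val, _ = prob.profiled(f, a)
                assert fit.reml_value <= val + 1e-6

    def test_pure_nugget_data(self, rng):
        coords = rng.uniform(-1, 1, size=(80, 2))
        z = rng.normal(scale=1.5, size=80)
        X = np.ones((80, 1))
        fit = fit_reml(coords, X, z)
        resid_var = np.var(z, ddof=1)
        assert fit.params.sill == pytest.approx(resid_var, rel=0.35)
        # spatial structure should be negligible: either tiny psill or tiny range
        spatial_at_median = fit.params.psill * np.exp(-1.0)
        assert spatial_at_median < 0.5 * resid_var

    def test_rank_deficient_design_rejected(self, rng):
        coords = rng.uniform(size=(10, 2))
        X = np.ones((10, 2))  # duplicated intercept
        with pytest.raises(ValueError):
            fit_reml(coords, X, rng.normal(size=10))


class TestEblupPoint:
    def test_exact_interpolation_without_nugget(self, rng):
        coords = rng.uniform(-1, 1, size=(15, 2))
        params = AutocovParams(0.0, 2.0, 1.0)
        L = np.linalg.cholesky(cov_matrix(coords, None, params) + 1e-10 * np.eye(15))
        z = L @ rng.standard_normal(15)
        X = np.ones((15, 1))
        fit = make_fit(params, coords, X, z)
        out = eblup_point(fit, np.ones((1, 1)), coords[[4]])
        assert out.pred[0] == pytest.approx(z[4], abs=1e-6)
        assert out.se[0] == pytest.approx(0.0, abs=1e-4)

    def test_iid_intercept_reduces_to_sample_mean(self, rng):
        """Sigma = s^2 I with an intercept: OLS prediction of a new datum."""
        n = 25
        coords = rng.uniform(size=(n, 2))
        z = rng.normal(loc=3.0, size=n)
        params = AutocovParams(1.0, 0.0, 1.0)
        fit = make_fit(params, coords, np.ones((n, 1)), z)
        out = eblup_point(fit, np.ones((1, 1)), np.array([[5.0, 5.0]]))
        assert out.pred[0] == pytest.approx(z.mean(), rel=1e-10)
        assert out.se[0] ** 2 == pytest.approx(1.0 * (1 + 1 / n), rel=1e-10)

    def test_four_point_toy_matches_explicit_algebra(self, rng):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        X = np.column_stack([np.ones(4), [0.0, 1.0, 2.0, 3.0]])
        z = np.array([1.0, 2.0, 0.5, 3.0])
        params = AutocovParams(0.2, 1.0, 0.9)
        fit = make_fit(params, coords, X, z)
        x_u = np.array([1.0, 1.5])
        coord_u = np.array([0.4, 0.6])
        out = eblup_point(fit, x_u[None, :], coord_u[None, :], return_weights=True)
        lam, var = explicit_blup(params, coords, X, z, x_u, coord_u)
        assert np.allclose(out.lam[0], lam, atol=1e-9)
        assert out.se[0] ** 2 == pytest.approx(var, rel=1e-9)
        assert out.pred[0] == pytest.approx(lam @ z, rel=1e-9)
        # unbiasedness constraints lambda' X_s = x_u'
        assert np.allclose(out.lam[0] @ X, x_u, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_blup_weights_beat_feasible_alternatives(self, seed):
        """Eq-8 weights minimize the error variance over the constraint set.

        Independent oracle: parameterize the feasible set via a null-space
        basis and minimize the quadratic exactly with dense linear algebra.
        """
        rng = np.random.default_rng(seed)
        n = 7
        coords = rng.uniform(size=(n, 2))
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        z = rng.normal(size=n)
        params = AutocovParams(0.3, 1.0, 0.5)
        fit = make_fit(params, coords, X, z)
        x_u = np.array([1.0, rng.normal()])
        coord_u = rng.uniform(size=2)
        out = eblup_point(fit, x_u[None, :], coord_u[None, :], return_weights=True)
        lam = out.lam[0]

        S = cov_matrix(coords, None, params)
        c = cov_matrix(coords, coord_u[None, :], params)[:, 0]

        def objective(l):
            return l @ S @ l - 2 * l @ c + params.sill

        # particular solution + null-space parameterization of lam' X = x_u'
        lam0 = np.linalg.lstsq(X.T, x_u, rcond=None)[0]
        _, _, Vt = np.linalg.svd(X.T)
        Z = Vt[X.shape[1]:].T  # basis of the null space of X'
        H = Z.T @ S @ Z
        g = Z.T @ (S @ lam0 - c)
        t_star = np.linalg.solve(H, -g)
        lam_opt = lam0 + Z @ t_star
        assert objective(lam) == pytest.approx(objective(lam_opt), rel=1e-9)
        assert np.allclose(lam, lam_opt, atol=1e-7)
        # random feasible perturbations never do better
        for _ in range(25):
            pert = lam + Z @ rng.normal(scale=0.3, size=Z.shape[1])
            assert objective(pert) >= objective(lam) - 1e-10


class TestEblupBlock:
    @staticmethod
    def _population(rng, n_total=6, n_obs=3):
        coords = rng.uniform(size=(n_total, 2))
        X = np.column_stack([np.ones(n_total), rng.normal(size=n_total)])
        z = rng.normal(size=n_total)
        s = np.arange(n_obs)
        u = np.arange(n_obs, n_total)
        pop = SurveyPopulation(coords=coords, X=X[:, 1:], z=z,
                               observed_idx=s, unobserved_idx=u)
        return pop, coords, X, z, s, u

    def test_census_variance_is_zero(self, rng):
        coords = rng.uniform(size=(5, 2))
        X = np.ones((5, 1))
        z = rng.normal(size=5)
        pop = SurveyPopulation(coords=coords, X=np.zeros((5, 0)), z=z,
                               observed_idx=np.arange(5), unobserved_idx=np.arange(0))
        fit = make_fit(AutocovParams(0.5, 1.0, 0.4), coords, X, z)
        bp = eblup_block(fit, pop, np.ones(5), X_u=np.empty((0, 1)))
        assert bp.se == 0.0
        assert bp.estimate == pytest.approx(z.sum())

    def test_iid_total_matches_srs_closed_form(self, rng):
        """Sigma = s^2 I, intercept only: N^2 (1-f) s^2 / n variance."""
        N, n = 9, 4
        pop, coords, X, z, s, u = self._population(rng, N, n)
        sigma2 = 1.7
        fit = make_fit(AutocovParams(sigma2, 0.0, 1.0), coords[s],
                       np.ones((n, 1)), z[s])
        bp = eblup_block(fit, pop, np.ones(N), X_u=np.ones((N - n, 1)))
        f = n / N
        expected_var = N**2 * sigma2 * (1 - f) / n
        assert bp.se**2 == pytest.approx(expected_var, rel=1e-9)
        assert bp.estimate == pytest.approx(z[s].sum() + (N - n) * z[s].mean(), rel=1e-9)

    def test_toy_matches_brute_force_matrix_algebra(self, rng):
        pop, coords, X, z, s, u = self._population(rng)
        params = AutocovParams(0.2, 1.1, 0.6)
        fit = make_fit(params, coords[s], X[s], z[s])
        b = np.ones(6)
        bp = eblup_block(fit, pop, b, X_u=X[u])

        # explicit evaluation of the block BLUP and its variance
        S = cov_matrix(coords, None, params)
        Sss, Ssu, Suu = S[np.ix_(s, s)], S[np.ix_(s, u)], S[np.ix_(u, u)]
        Si = np.linalg.inv(Sss)
        A = X[s].T @ Si @ X[s]
        beta = np.linalg.solve(A, X[s].T @ Si @ z[s])
        r = z[s] - X[s] @ beta
        pred_u = X[u] @ beta + Ssu.T @ Si @ r
        b_s, b_u = b[s], b[u]
        est = b_s @ z[s] + b_u @ pred_u
        cb = Ssu @ b_u
        d = X[u].T @ b_u - X[s].T @ Si @ cb
        var = b_u @ Suu @ b_u - cb @ Si @ cb + d @ np.linalg.solve(A, d)
        assert bp.estimate == pytest.approx(est, rel=1e-9)
        assert bp.se**2 == pytest.approx(var, rel=1e-9)

    def test_block_variance_shrinks_with_nested_samples(self, rng):
        """Along nested samples on one population the variance never grows."""
        N = 30
        coords = rng.uniform(size=(N, 2))
        X = np.column_stack([np.ones(N), rng.normal(size=N)])
        z = rng.normal(size=N)
        params = AutocovParams(0.3, 1.0, 0.5)
        order = rng.permutation(N)
        prev = np.inf
        for n in (5, 10, 20, 30):
            s = np.sort(order[:n])
            u = np.setdiff1d(np.arange(N), s)
            pop = SurveyPopulation(coords=coords, X=X[:, 1:], z=z,
                                   observed_idx=s, unobserved_idx=u)
            fit = make_fit(params, coords[s], X[s], z[s])
            bp = eblup_block(fit, pop, np.ones(N), X_u=X[u])
            assert bp.se <= prev + 1e-9
            prev = bp.se


class TestLmAndIntervals:
    def test_orthogonal_design_matches_per_column_ols(self, rng):
        n = 16
        X = np.zeros((n, 2))
        X[: n // 2, 0] = 1.0
        X[n // 2:, 1] = 1.0
        z = rng.normal(size=n)
        out, fit = lm_fit_predict(X, z, X[:2])
        assert fit.beta_gls[0] == pytest.approx(z[: n // 2].mean())
        assert fit.beta_gls[1] == pytest.approx(z[n // 2:].mean())

    def test_consistent_with_eblup_under_independence(self, toy_observed):
        coords, X, z = toy_observed
        X1 = np.column_stack([np.ones(len(z)), X])
        out, fit = lm_fit_predict(X1, z, X1, coords_s=coords, coords_u=coords + 10.0)
        ref = eblup_point(fit, X1, coords + 10.0)
        assert np.allclose(out.pred, ref.pred)
        assert np.allclose(out.se, ref.se)

    def test_interval_quantiles_and_degenerate(self):
        lo, hi = slm_interval(0.0, 1.0, level=0.90)
        assert lo == pytest.approx(-1.6449, abs=1e-3)
        lo, hi = slm_interval(2.0, 0.0, level=0.95)
        assert lo == hi == 2.0
        lo, hi = slm_interval(0.0, 4.0, level=0.95)
        assert hi == pytest.approx(2 * 1.95996, abs=1e-3)
        with pytest.raises(ValueError):
            slm_interval(0.0, -1e-6)
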