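"""Ridge/OLS estimators: closed forms, optimality, cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from sklearn.linear_model import Ridge as SkRidge

from tunadrivers.errors import SingularMatrixError, ValidationError
from tunadrivers.ridge import (
    cv_select,
    default_lambda_grid,
    fit_and_test,
    lambda_path,
    ols_fit,
    ols_min_norm,
    penalized_rss,
    ridge_fit,
    standardize,
)


class TestOls:
    def test_noiseless_recovery(self, rng):
        x = rng.normal(size=(30, 3))
        beta = np.array([2.0, -1.0, 0.5])
        y = 1.0 + x @ beta
        fit = ols_fit(x, y)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(fit.coef_vector(), beta, atol=1e-10)

    def test_orthonormal_design_simplification(self, rng):
        """With centered orthonormal columns, slopes reduce to X'y."""
        a = rng.normal(size=(50, 3))
        q, _ = np.linalg.qr(a - a.mean(axis=0))
        y = rng.normal(size=50)
        fit = ols_fit(q, y)
        assert np.allclose(fit.coef_vector(), q.T @ y, atol=1e-10)

    def test_hand_solved_normal_equations(self):
        # X = [[1,0],[0,1],[1,1],[1,-1]], y = [1,2,4,0], no intercept:
        # X'X = [[3,0],[0,3]], X'y = [5,6] -> beta = (5/3, 2)
        x = np.array([[1.0, 0], [0, 1], [1, 1], [1, -1]])
        y = np.array([1.0, 2.0, 4.0, 0.0])
        fit = ols_fit(x, y, intercept=False)
        assert np.allclose(fit.coef_vector(), [5 / 3, 2.0], atol=1e-12)

    def test_residual_orthogonality(self, toy_design):
        x, y, _ = toy_design
        fit = ols_fit(x, y)
        resid = y - fit.predict(x)
        assert np.abs(x.to_numpy().T @ resid).max() < 1e-8

    def test_singular_design_raises(self):
        x = np.ones((10, 2))  # duplicated constant columns
        with pytest.raises(SingularMatrixError, match="lambda"):
            ols_fit(x, np.arange(10.0))

    def test_min_norm_matches_ols_on_full_rank(self, toy_design):
        x, y, _ = toy_design
        a, b = ols_fit(x, y), ols_min_norm(x, y)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-8)
        assert np.allclose(a.coef_vector(), b.coef_vector(), atol=1e-8)


class TestRidge:
    def test_lambda_zero_equals_ols(self, toy_design):
        x, y, _ = toy_design
        a, b = ols_fit(x, y), ridge_fit(x, y, 0.0)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-10)
        assert np.allclose(a.coef_vector(), b.coef_vector(), atol=1e-10)

    def test_uncorrelated_design_closed_form_shrinkage(self, rng):
        """Exactly uncorrelated columns: ridge = OLS * n / (n + lambda).

        After internal standardization the Gram matrix of an exactly
        orthogonal, centered design is n*I, so the ridge solve shrinks
        every standardized OLS coefficient by the same known factor.
        """
        n, lam = 60, 25.0
        a = rng.normal(size=(n, 4))
        q, _ = np.linalg.qr(a - a.mean(axis=0))  # centered orthonormal columns
        y = rng.normal(size=n)
        ols = ridge_fit(q, y, 0.0)
        shrunk = ridge_fit(q, y, lam)
        expected = ols.coef_vector(standardized=True) * n / (n + lam)
        assert np.allclose(shrunk.coef_vector(standardized=True), expected, atol=1e-10)

    def test_total_shrinkage_limit(self, toy_design):
        x, y, _ = toy_design
        fit = ridge_fit(x, y, 1e9)
        assert np.abs(fit.coef_vector()).max() < 1e-6
        assert fit.intercept == pytest.approx(y.mean(), abs=1e-5)

    def test_negative_lambda_rejected(self, toy_design):
        x, y, _ = toy_design
        with pytest.raises(ValidationError):
            ridge_fit(x, y, -0.1)

    def test_constant_column_at_lambda_zero_raises(self, rng):
        x = np.column_stack([rng.normal(size=20), np.full(20, 3.0)])
        with pytest.raises(SingularMatrixError):
            ridge_fit(x, rng.normal(size=20), 0.0)

    def test_mean_scale_equals_sum_scale_at_n_lambda(self, toy_design):
        x, y, _ = toy_design
        a = ridge_fit(x, y, 0.5, lambda_scale="mean")
        b = ridge_fit(x, y, 0.5 * len(y), lambda_scale="sum")
        assert np.allclose(a.coef_vector(), b.coef_vector(), atol=1e-12)

    def test_agreement_with_sklearn(self, rng):
        """Independent route: sklearn Ridge on the pre-standardized design."""
        x = rng.normal(size=(80, 6)) * rng.uniform(0.5, 4, 6)
        y = rng.normal(size=80)
        z, _, _ = standardize(x)
        for lam in (0.01, 1.0, 50.0):
            ours = ridge_fit(x, y, lam)
            sk = SkRidge(alpha=lam, fit_intercept=True).fit(z, y)
            assert np.allclose(ours.coef_vector(standardized=True), sk.coef_, atol=1e-8)


class TestPenalizedObjective:
    def test_zero_beta_gives_centered_tss(self, rng):
        y = rng.normal(size=25)
        z = rng.normal(size=(25, 3))
        yc = y - y.mean()
        assert penalized_rss(z, yc, np.zeros(3), 4.0) == pytest.approx((yc**2).sum())

    def test_lambda_zero_at_ols_equals_rss(self, toy_design):
        x, y, _ = toy_design
        fit = ols_fit(x, y)
        z, _, _ = standardize(x.to_numpy())
        beta = fit.coef_vector(standardized=True)
        obj = penalized_rss(z, y - y.mean(), beta, 0.0)
        rss = float(((y - fit.predict(x)) ** 2).sum())
        assert obj == pytest.approx(rss, rel=1e-10)

    def test_solution_beats_random_perturbations(self, rng):
        x = rng.normal(size=(40, 4))
        y = rng.normal(size=40)
        lam = 3.0
        fit = ridge_fit(x, y, lam)
        z, _, _ = standardize(x)
        beta = fit.coef_vector(standardized=True)
        best = penalized_rss(z, y - y.mean(), beta, lam)
        for _ in range(1000):
            trial = beta + rng.normal(0, 0.1, 4)
            assert penalized_rss(z, y - y.mean(), trial, lam) >= best - 1e-9


class TestLambdaPath:
    def test_norm_monotone_and_deviance_nonincreasing(self, rng):
        x = rng.normal(size=(60, 5))
        y = x @ rng.normal(size=5) + rng.normal(0, 0.5, 60)
        grid = default_lambda_grid(x, y)
        path = lambda_path(x, y, grid)
        norms = np.linalg.norm(path.coefs, axis=1)
        order = np.argsort(path.lambdas)  # ascending lambda
        assert (np.diff(norms[order]) <= 1e-9).all()
        assert (np.diff(path.deviance_explained[order]) <= 1e-9).all()

    def test_single_lambda_matches_direct_fit(self, toy_design):
        x, y, _ = toy_design
        path = lambda_path(x, y, [2.0])
        fit = ridge_fit(x, y, 2.0)
        assert np.allclose(path.coefs_original[0], fit.coef_vector(), atol=1e-12)

    def test_duplicate_grid_rejected(self, toy_design):
        x, y, _ = toy_design
        with pytest.raises(ValidationError):
            lambda_path(x, y, [1.0, 1.0])


class TestCrossValidation:
    def test_fixed_seed_reproducible(self, rng):
        x = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        a = cv_select(x, y, k=5, seed=3)
        b = cv_select(x, y, k=5, seed=3)
        assert a.lambda_min == b.lambda_min
        assert np.array_equal(a.mean_mse, b.mean_mse)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)

    def test_folds_partition_rows(self, rng):
        x = rng.normal(size=(53, 3))
        y = rng.normal(size=53)
        res = cv_select(x, y, k=10, seed=1)
        counts = np.bincount(res.fold_assignment, minlength=10)
        assert counts.sum() == 53
        assert counts.min() >= 5 and counts.max() <= 6

    def test_lambda_1se_definition(self, rng):
        x = rng.normal(size=(80, 5))
        y = x @ np.array([1.0, -1, 0.5, 0, 0]) + rng.normal(0, 1, 80)
        res = cv_select(x, y, k=10, seed=2)
        assert res.lambda_1se >= res.lambda_min
        thresh = res.mean_mse.min() + res.se_mse[np.argmin(res.mean_mse)]
        chosen = res.lambda_grid[res.lambda_grid >= res.lambda_1se]
        # every lambda above lambda_1se must exceed the 1-SE threshold
        above = res.mean_mse[np.isin(res.lambda_grid, chosen[:-1])]
        assert (above > thresh).all()

    def test_strong_signal_prefers_small_lambda(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.normal(size=(100, 4))
            y = x @ np.array([3.0, -2.0, 1.5, 1.0]) + r.normal(0, 0.1, 100)
            res = cv_select(x, y, k=10, seed=seed)
            decile = np.quantile(res.lambda_grid, 0.1)
            hits += res.lambda_min <= decile
        assert hits >= 18

    def test_pure_noise_curve_flat_within_two_se(self):
        flat = 0
        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            x = r.normal(size=(100, 4))
            y = r.normal(size=100)
            res = cv_select(x, y, k=10, seed=seed)
            spread = res.mean_mse.max() - res.mean_mse.min()
            flat += spread <= 2.0 * res.se_mse.mean()
        assert flat >= 18

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValidationError):
            cv_select(rng.normal(size=(5, 2)), rng.normal(size=5), k=10)


class TestFitAndTest:
    def test_noiseless_table_perfect_test_r2(self, small_config):
        from tunadrivers.synthetic import generate_bundle

        cfg = type(small_config)(**{**small_config.__dict__, "noise_sd": 0.0, "seed": 9})
        bundle = generate_bundle(cfg)
        report = fit_and_test(bundle.feature_table, seed=4, k=5)
        assert report.test_r2 == pytest.approx(1.0, abs=1e-6)

    def test_shuffled_response_has_no_skill(self, small_bundle):
        table = small_bundle.feature_table.copy()
        misses = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            table["f_over_fmsy"] = r.permutation(table["f_over_fmsy"].to_numpy())
            report = fit_and_test(table, seed=seed, k=5)
            misses += report.test_r2 <= 0.1
        assert misses >= 18

    def test_split_sizes(self, small_bundle):
        report = fit_and_test(small_bundle.feature_table, seed=0, k=5)
        n = len(small_bundle.feature_table)
        assert report.n_train == round(2 * n / 3)
        assert report.n_train + report.n_test == n
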