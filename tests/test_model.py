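"""Prognostic-model tests: standardization, elastic net, LOOCV, imputation."""

import numpy as np
import pandas as pd
import pytest

from falff_prognosis.model import (
    CohortTable,
    HyperGrid,
    clamp_prediction,
    elastic_net_fit,
    ensemble_run,
    impute_missing,
    loocv_predict,
    tune_hyperparameters,
    zscore_fit_apply,
)

SMALL_GRID = HyperGrid(alphas=(0.5, 1.0), n_lambdas=8)


def toy_table(n=8, p=3, seed=0, missing=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.array([0.3, -0.2, 0.1])[:p]
    pre = rng.uniform(0.2, 0.8, n)
    post = np.clip(0.5 * pre + X @ beta * 0.1 + 0.5, 0, 1)
    preds = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
    preds["pre_tsm"] = pre
    if missing:
        ii = rng.integers(0, n, missing)
        jj = rng.integers(0, p, missing)
        for i, j in zip(ii, jj):
            preds.iat[i, j] = np.nan
    return CohortTable([f"s{i}" for i in range(n)], preds, pre, post)


class TestZscore:
    def test_simple_column(self):
        train_std, test_std, params = zscore_fit_apply(
            np.array([[1.0], [2.0], [3.0]]), np.array([[2.0]])
        )
        np.testing.assert_allclose(train_std.ravel(), [-1, 0, 1])
        assert test_std[0, 0] == pytest.approx(0.0)

    def test_constant_column_dropped_and_logged(self, caplog):
        train = np.column_stack([np.ones(4), np.arange(4.0)])
        with caplog.at_level("WARNING"):
            train_std, _, params = zscore_fit_apply(train, None, names=["c", "x"])
        assert train_std.shape[1] == 1
        assert params["dropped_names"] == ["c"]
        assert "c" in caplog.text


class TestElasticNet:
    def test_lambda_zero_matches_ols(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((6, 2))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = rng.standard_normal(6)
        fit = elastic_net_fit(X, y, mixing_alpha=0.5, penalty_lambda=0.0)
        Xi = np.column_stack([np.ones(6), X])
        beta = np.linalg.lstsq(Xi, y, rcond=None)[0]
        np.testing.assert_allclose(fit.intercept, beta[0], atol=1e-6)
        np.testing.assert_allclose(fit.coefficients, beta[1:], atol=1e-6)

    def test_full_shrinkage(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 3))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = rng.standard_normal(10)
        fit = elastic_net_fit(X, y, mixing_alpha=1.0, penalty_lambda=1e6)
        np.testing.assert_allclose(fit.coefficients, 0.0, atol=1e-12)
        assert fit.intercept == pytest.approx(y.mean())

    def test_pure_ridge_matches_closed_form(self):
        rng = np.random.default_rng(3)
        n, lam = 3, 0.7
        X = rng.standard_normal((n, 2))
        X = X - X.mean(0)  # centered, as the objective's closed form assumes
        y = rng.standard_normal(n)
        fit = elastic_net_fit(X, y, mixing_alpha=0.0, penalty_lambda=lam)
        beta = np.linalg.solve(X.T @ X / n + lam * np.eye(2), X.T @ (y - y.mean()) / n)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-6)

    def test_coefficient_norm_nonincreasing_in_lambda(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((20, 5))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = X @ np.array([1.0, -0.5, 0.3, 0.0, 0.2]) + 0.1 * rng.standard_normal(20)
        for alpha in (0.1, 0.55, 1.0):
            norms = [
                np.linalg.norm(elastic_net_fit(X, y, alpha, lam).coefficients)
                for lam in np.logspace(-4, 1, 12)
            ]
            assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))


class TestTuning:
    def test_single_point_grid(self):
        t = toy_table(n=8)
        grid = HyperGrid(alphas=(0.55,), lambdas=(0.1,))
        assert tune_hyperparameters(t.predictors.to_numpy(), t.post_tsm, grid) == (0.55, 0.1)

    def test_chosen_point_minimizes_cv_error(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((12, 3))
        y = rng.standard_normal(12)
        grid = HyperGrid(alphas=(0.5, 1.0), n_lambdas=6)
        a, lam = tune_hyperparameters(X, y, grid)
        # recompute CV error for the chosen point and for a few others
        def cv_err(alpha, lam):
            errs = []
            for i in range(12):
                idx = np.arange(12) != i
                Xtr, Xte, _ = zscore_fit_apply(X[idx], X[i : i + 1])
                fit = elastic_net_fit(Xtr, y[idx], alpha, lam)
                errs.append((fit.intercept + Xte[0] @ fit.coefficients - y[i]) ** 2)
            return np.mean(errs)

        chosen = cv_err(a, lam)
        Xs, _, _ = zscore_fit_apply(X, None)
        for alpha in grid.alphas:
            for other in grid.lambda_path(Xs, y, alpha):
                assert chosen <= cv_err(alpha, other) + 1e-10

    def test_pure_signal_selects_unpenalized(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((15, 2))
        y = X @ np.array([1.0, -2.0])  # exact linear signal, no noise
        grid = HyperGrid(alphas=(1.0,), lambdas=(0.0, 10.0))
        a, lam = tune_hyperparameters(X, y, grid)
        assert lam == 0.0


class TestClamp:
    @pytest.mark.parametrize("value,expected", [(1.05, 1.0), (-0.02, 0.0), (0.5, 0.5)])
    def test_examples(self, value, expected):
        assert clamp_prediction(value) == expected
        assert clamp_prediction(clamp_prediction(value)) == clamp_prediction(value)


class TestLoocv:
    def test_constant_outcome_predicts_constant(self):
        t = toy_table(n=8)
        t.post_tsm[:] = 0.6
        res = loocv_predict(t, grid=SMALL_GRID)
        np.testing.assert_allclose(res.predictions, 0.6, atol=1e-8)

    def test_permutation_invariance(self):
        t = toy_table(n=10, seed=7)
        res = loocv_predict(t, grid=SMALL_GRID)
        perm = np.random.default_rng(0).permutation(10)
        tp = CohortTable(
            [t.subject_ids[i] for i in perm],
            t.predictors.iloc[perm].reset_index(drop=True),
            t.pre_tsm[perm],
            t.post_tsm[perm],
        )
        res_p = loocv_predict(tp, grid=SMALL_GRID)
        by_id = dict(zip(res.subject_ids, res.predictions))
        for sid, p in zip(res_p.subject_ids, res_p.predictions):
            assert p == pytest.approx(by_id[sid], abs=1e-10)

    def test_held_out_outcome_never_leaks(self):
        t = toy_table(n=8, seed=8)
        res = loocv_predict(t, grid=SMALL_GRID)
        corrupted = CohortTable(
            list(t.subject_ids), t.predictors.copy(), t.pre_tsm.copy(), t.post_tsm.copy()
        )
        corrupted.post_tsm[3] = 0.987  # corrupt one held-out outcome
        res_c = loocv_predict(corrupted, grid=SMALL_GRID)
        assert res_c.predictions[3] == pytest.approx(res.predictions[3], abs=1e-12)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            loocv_predict(toy_table(n=3), grid=SMALL_GRID)

    def test_predictions_clamped(self):
        t = toy_table(n=10, seed=9)
        res = loocv_predict(t, grid=SMALL_GRID)
        assert ((res.predictions >= 0) & (res.predictions <= 1)).all()


class TestImputation:
    def test_complete_table_returned_unchanged(self):
        t = toy_table(n=8)
        assert impute_missing(t, seed=1) is t

    def test_deterministic(self):
        t = toy_table(n=12, missing=4, seed=10)
        a = impute_missing(t, seed=3)
        b = impute_missing(t, seed=3)
        pd.testing.assert_frame_equal(a.predictors, b.predictors)

    def test_observed_cells_untouched(self):
        t = toy_table(n=12, missing=4, seed=10)
        completed = impute_missing(t, seed=3)
        obs = t.predictors.notna()
        np.testing.assert_array_equal(
            completed.predictors.to_numpy()[obs.to_numpy()],
            t.predictors.to_numpy()[obs.to_numpy()],
        )

    def test_recovers_linear_structure(self):
        rng = np.random.default_rng(11)
        n = 24
        a = rng.uniform(1, 3, n)
        preds = pd.DataFrame({"A": a, "B": 2 * a, "C": rng.standard_normal(n)})
        preds.iloc[5, preds.columns.get_loc("B")] = np.nan
        t = CohortTable([f"s{i}" for i in range(n)], preds,
                        rng.uniform(0, 1, n), rng.uniform(0, 1, n))
        completed = impute_missing(t, seed=4, n_trees=200)
        imputed = completed.predictors.iloc[5]["B"]
        assert imputed == pytest.approx(2 * a[5], rel=0.10)

    def test_sparse_column_raises(self):
        preds = pd.DataFrame({"A": [1.0, np.nan, np.nan, np.nan], "B": [1.0, 2, 3, 4]})
        t = CohortTable(["a", "b", "c", "d"], preds, np.zeros(4), np.zeros(4))
        with pytest.raises(ValueError, match="A"):
            impute_missing(t, seed=0)


class TestEnsemble:
    def test_complete_data_equals_single_run(self):
        t = toy_table(n=8, seed=12)
        single = loocv_predict(t, grid=SMALL_GRID)
        ens = ensemble_run(t, n_imputations=10, base_seed=0, grid=SMALL_GRID)
        assert ens.n_imputations == 1
        np.testing.assert_array_equal(ens.predictions_median, single.predictions)
        np.testing.assert_array_equal(
            ens.coefficients_median.to_numpy(), single.coefficient_series().to_numpy()
        )

    def test_coefficient_order_statistics(self):
        t = toy_table(n=12, missing=5, seed=13)
        ens = ensemble_run(t, n_imputations=3, base_seed=2, grid=SMALL_GRID, n_trees=20)
        assert ens.n_imputations == 3
        assert (ens.coefficients_min <= ens.coefficients_median + 1e-12).all()
        assert (ens.coefficients_median <= ens.coefficients_max + 1e-12).all()
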