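"""Tests of random grid search, stacking, and hyperparameter diagnostics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Ridge

from hybfact.features import FeatureTable
from hybfact.learners import HYPERPARAMETER_SPACES, ModelSpec
from hybfact.tuning import (
    GridSearchResult,
    StackedEnsemble,
    build_stacked_ensemble,
    hyperparameter_mse_correlations,
    make_folds,
    predict_ensemble,
    run_grid_search,
    sample_hyperparameters,
)


def toy_table(n: int, seed: int = 0) -> tuple[FeatureTable, np.ndarray]:
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    keys = [(f"A{r}", f"B{r}") for r in range(n)]
    table = FeatureTable(keys, pd.DataFrame(X, columns=["f0", "f1", "f2"]), "markers")
    y = X @ np.array([2.0, -1.0, 0.5]) + rng.normal(0, 0.3, n)
    return table, y


def rigged_fit_predict(spec, X_train, y_train, X_test):
    """Fake learner whose behavior is encoded in spec.params['bias']."""
    bias = spec.params.get("bias", 0.0)
    return np.full(len(X_test.row_keys), float(np.mean(y_train)) + bias)


def make_rigged_spec(bias: float, seed: int = 0) -> ModelSpec:
    spec = ModelSpec("gb", seed=seed)
    spec.params = {"bias": bias}
    return spec


class TestSampleHyperparameters:
    def test_small_space_returned_whole(self, monkeypatch):
        monkeypatch.setitem(
            HYPERPARAMETER_SPACES, "svm",
            {"C": [0.1, 1, 10], "epsilon": [0.01, 0.1], "kernel": ["linear", "radial"]},
        )
        specs = sample_hyperparameters("svm", n=50, seed=1)
        assert len(specs) == 12
        assert len({s.key() for s in specs}) == 12

    def test_large_space_sampling_is_deterministic(self):
        a = sample_hyperparameters("gb", n=50, seed=9)
        b = sample_hyperparameters("gb", n=50, seed=9)
        assert [s.params for s in a] == [s.params for s in b]

    def test_samples_are_distinct_across_many_seeds(self):
        for seed in range(100):
            specs = sample_hyperparameters("gb", n=50, seed=seed)
            assert len({s.key() for s in specs}) == 50

    def test_values_lie_in_declared_space(self):
        for spec in sample_hyperparameters("rf", n=50, seed=2):
            for name, value in spec.params.items():
                assert value in HYPERPARAMETER_SPACES["rf"][name]


class TestRunGridSearch:
    def test_oracle_spec_wins_with_zero_mse(self):
        table, y = toy_table(40)

        def oracle_or_mean(spec, Xtr, ytr, Xte):
            if spec.params.get("bias") == -1.0:  # tagged oracle
                idx = [table.row_keys.index(k) for k in Xte.row_keys]
                return y[idx]
            return rigged_fit_predict(spec, Xtr, ytr, Xte)

        specs = [make_rigged_spec(5.0), make_rigged_spec(-1.0), make_rigged_spec(2.0)]
        grid = run_grid_search(specs, table, y, seed=3, fit_predict_fn=oracle_or_mean)
        assert grid.best_index == 1
        assert grid.cv_mse[1] == pytest.approx(0.0, abs=1e-18)

    def test_cv_mse_is_definitional_identity(self):
        table, y = toy_table(30)
        specs = [make_rigged_spec(b) for b in (0.0, 1.0)]
        grid = run_grid_search(specs, table, y, seed=4, fit_predict_fn=rigged_fit_predict)
        for s in range(2):
            assert grid.cv_mse[s] == pytest.approx(np.mean((y - grid.oof_predictions[s]) ** 2))

    def test_ranking_matches_hand_rolled_cv(self):
        table, y = toy_table(20, seed=5)
        specs = [make_rigged_spec(0.5, seed=11), make_rigged_spec(0.1, seed=11)]
        grid = run_grid_search(specs, table, y, folds=10, seed=11, fit_predict_fn=rigged_fit_predict)
        # independent manual 10-fold loop with the same assignment
        assignment = make_folds(20, 10, 11)
        manual_mse = []
        for spec in specs:
            oof = np.empty(20)
            for f in range(10):
                te = assignment == f
                oof[te] = np.mean(y[~te]) + spec.params["bias"]
            manual_mse.append(np.mean((y - oof) ** 2))
        assert grid.cv_mse == pytest.approx(manual_mse)
        assert grid.best_index == int(np.argmin(manual_mse))

    def test_failing_spec_flagged_not_fatal(self):
        table, y = toy_table(25)

        def flaky(spec, Xtr, ytr, Xte):
            if spec.params.get("bias") == 9.0:
                raise RuntimeError("synthetic failure")
            return rigged_fit_predict(spec, Xtr, ytr, Xte)

        specs = [make_rigged_spec(9.0), make_rigged_spec(0.0)]
        grid = run_grid_search(specs, table, y, seed=6, fit_predict_fn=flaky)
        assert grid.failed == [0]
        assert not np.isfinite(grid.cv_mse[0])
        assert grid.best_index == 1

    def test_shared_fold_assignment(self):
        table, y = toy_table(23)
        specs = [make_rigged_spec(0.0), make_rigged_spec(1.0)]
        grid = run_grid_search(specs, table, y, seed=7, fit_predict_fn=rigged_fit_predict)
        assert len(grid.fold_assignment) == 23
        assert set(grid.fold_assignment) == set(range(10))


def synthetic_grid(n=60, n_specs=12, seed=8, noise=1.0):
    """A grid whose base models are mean + per-spec Gaussian distortions."""
    rng = np.random.default_rng(seed)
    table, y = toy_table(n, seed=seed)
    specs = []
    for s in range(n_specs):
        spec = make_rigged_spec(0.0, seed=s)
        spec.params = {"bias": 0.0, "noise": (s + 1) * noise / n_specs}
        specs.append(spec)

    def noisy(spec, Xtr, ytr, Xte):
        r = np.random.default_rng(spec.seed + 1000)
        idx = [table.row_keys.index(k) for k in Xte.row_keys]
        return y[idx] + r.normal(0, spec.params["noise"], len(idx))

    grid = run_grid_search(specs, table, y, seed=seed, fit_predict_fn=noisy)
    return grid, table, y, noisy


class TestStackedEnsemble:
    def test_perfect_member_dominates(self):
        table, y = toy_table(50, seed=9)

        def perfect_first(spec, Xtr, ytr, Xte):
            idx = [table.row_keys.index(k) for k in Xte.row_keys]
            if spec.params.get("bias") == 0.0:
                return y[idx]
            return np.full(len(idx), np.mean(ytr))

        specs = [make_rigged_spec(b) for b in (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)]
        grid = run_grid_search(specs, table, y, seed=10, fit_predict_fn=perfect_first)
        se = build_stacked_ensemble(grid, y, ks=(5,))
        assert se.k == 5
        assert se.cv_r_by_k[5] >= 0.999

    def test_selected_k_matches_exhaustive_oracle(self):
        grid, table, y, _ = synthetic_grid(n_specs=20)
        ks = (5, 10, 15, 20)
        se = build_stacked_ensemble(grid, y, ks=ks)
        # exhaustive re-evaluation of every feasible k
        best = max(ks, key=lambda k: (build_stacked_ensemble(grid, y, ks=(k,)).cv_r_by_k[k], -k))
        assert se.k == best
        assert all(se.cv_r_by_k[se.k] >= r for r in se.cv_r_by_k.values())

    def test_pure_noise_ensemble_has_low_cv_r(self):
        table, y = toy_table(200, seed=12)

        def noise_learner(spec, Xtr, ytr, Xte):
            r = np.random.default_rng(spec.seed + 33)
            return r.normal(0, 1, len(Xte.row_keys))

        specs = [make_rigged_spec(float(b), seed=b) for b in range(10)]
        grid = run_grid_search(specs, table, y, seed=13, fit_predict_fn=noise_learner)
        se = build_stacked_ensemble(grid, y, ks=(5, 10))
        assert max(se.cv_r_by_k.values()) <= 0.3

    def test_super_learner_only_sees_out_of_fold_predictions(self):
        # with a mean-predicting learner, every OOF value must equal the
        # training mean computed WITHOUT that row's fold
        table, y = toy_table(30, seed=14)
        specs = [make_rigged_spec(0.0)]
        grid = run_grid_search(specs, table, y, seed=14, fit_predict_fn=rigged_fit_predict)
        for f in range(10):
            te = grid.fold_assignment == f
            expected = np.mean(y[~te])
            assert np.allclose(grid.oof_predictions[0, te], expected)

    def test_large_ridge_penalty_shrinks_toward_intercept(self):
        grid, table, y, _ = synthetic_grid(n_specs=10, noise=3.0)
        Z = grid.oof_predictions[grid.ranked_indices()[:5]].T
        spread = {}
        for lam in (1e2, 1e6):
            model = Ridge(alpha=lam).fit(Z, y)
            se = StackedEnsemble(
                base_specs=[grid.specs[i] for i in grid.ranked_indices()[:5]],
                k=5, super_intercept=float(model.intercept_),
                super_coefs=model.coef_, ridge_lambda=lam, cv_r_by_k={5: 0.0},
                base_indices=grid.ranked_indices()[:5],
            )
            spread[lam] = np.std(se.combine(Z))
        assert spread[1e6] < spread[1e2]
        assert spread[1e6] < 0.05 * np.std(y)

    def test_constant_oof_predictions_scored_zero(self):
        table, y = toy_table(30, seed=15)

        def constant(spec, Xtr, ytr, Xte):
            return np.zeros(len(Xte.row_keys))

        specs = [make_rigged_spec(0.0)]
        grid = run_grid_search(specs, table, y, seed=15, fit_predict_fn=constant)
        with pytest.warns(UserWarning, match="constant"):
            se = build_stacked_ensemble(grid, y, ks=(1,))
        assert se.cv_r_by_k[se.k] == 0.0


class TestPredictEnsemble:
    def test_single_model_identity(self):
        table, y = toy_table(20, seed=16)
        spec = make_rigged_spec(1.5)
        se = StackedEnsemble(
            base_specs=[spec], k=1, super_intercept=0.0,
            super_coefs=np.array([1.0]), ridge_lambda=1.0,
            cv_r_by_k={1: 1.0}, base_indices=[0],
        )
        preds = predict_ensemble(se, table, y, table, fit_predict_fn=rigged_fit_predict)
        assert np.allclose(preds, rigged_fit_predict(spec, table, y, table))

    def test_zero_coefficients_give_intercept(self):
        table, y = toy_table(15, seed=17)
        se = StackedEnsemble(
            base_specs=[make_rigged_spec(0.0), make_rigged_spec(1.0)],
            k=2, super_intercept=4.2, super_coefs=np.zeros(2),
            ridge_lambda=1.0, cv_r_by_k={2: 0.0}, base_indices=[0, 1],
        )
        preds = predict_ensemble(se, table, y, table, fit_predict_fn=rigged_fit_predict)
        assert np.allclose(preds, 4.2)

    def test_hand_set_linear_combination(self):
        table, y = toy_table(3, seed=18)
        se = StackedEnsemble(
            base_specs=[make_rigged_spec(1.0), make_rigged_spec(-1.0)],
            k=2, super_intercept=0.5, super_coefs=np.array([2.0, 3.0]),
            ridge_lambda=1.0, cv_r_by_k={2: 0.0}, base_indices=[0, 1],
        )
        m = float(np.mean(y))
        expected = 0.5 + 2.0 * (m + 1.0) + 3.0 * (m - 1.0)
        preds = predict_ensemble(se, table, y, table, fit_predict_fn=rigged_fit_predict)
        assert np.allclose(preds, expected)

    def test_wrong_column_count_raises(self):
        se = StackedEnsemble(
            base_specs=[make_rigged_spec(0.0)], k=1, super_intercept=0.0,
            super_coefs=np.array([1.0]), ridge_lambda=1.0,
            cv_r_by_k={1: 0.0}, base_indices=[0],
        )
        with pytest.raises(ValueError, match="base prediction columns"):
            se.combine(np.zeros((4, 2)))


class TestHyperparameterCorrelations:
    def _grid_from(self, params_mse: list[tuple[dict, float]]) -> GridSearchResult:
        specs = []
        for params, _ in params_mse:
            s = ModelSpec("gb")
            s.params = params
            specs.append(s)
        n = len(specs)
        return GridSearchResult(
            specs=specs,
            cv_mse=np.array([m for _, m in params_mse]),
            oof_predictions=np.zeros((n, 5)),
            fold_assignment=np.zeros(5, dtype=int),
        )

    def test_monotone_hyperparameter_detected(self):
        grid = self._grid_from([({"depth": d}, 1.0 + 0.5 * d) for d in range(8)])
        assert hyperparameter_mse_correlations(grid)["depth"] >= 0.99

    def test_constant_column_not_available(self):
        grid = self._grid_from([({"depth": 3, "x": i}, float(i)) for i in range(5)])
        assert hyperparameter_mse_correlations(grid)["depth"] is None

    def test_five_point_fixture_matches_closed_form(self):
        pairs = [(1.0, 2.0), (2.0, 2.5), (3.0, 2.1), (4.0, 3.9), (5.0, 3.5)]
        grid = self._grid_from([({"v": v}, m) for v, m in pairs])
        v = np.array([p[0] for p in pairs])
        m = np.array([p[1] for p in pairs])
        vc, mc = v - v.mean(), m - m.mean()
        expected = float((vc * mc).sum() / np.sqrt((vc**2).sum() * (mc**2).sum()))
        assert hyperparameter_mse_correlations(grid)["v"] == pytest.approx(expected, abs=1e-12)

    def test_needs_three_entries(self):
        grid = self._grid_from([({"v": 1.0}, 1.0), ({"v": 2.0}, 2.0)])
        with pytest.raises(ValueError, match="at least 3"):
            hyperparameter_mse_correlations(grid)
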