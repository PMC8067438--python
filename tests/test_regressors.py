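import numpy as np
import pytest
from sklearn.tree import DecisionTreeRegressor

from intervalreg.regressors import (
    DEFAULT_HYPERPARAMETERS,
    LeastSquaresRegressor,
    PenalizedLinearCV,
    RegressorSpec,
    RPropNetRegressor,
    TriangularKNNRegressor,
    fit_lm,
    make_regressor,
)


class TestSpec:
    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown regressor family"):
            RegressorSpec("gp")

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="unknown hyperparameters"):
            RegressorSpec("tree", {"min_leaf": 3})

    def test_dict_round_trip(self):
        spec = RegressorSpec("knn", {"max_k": 5}, seed=7)
        assert RegressorSpec.from_dict(spec.to_dict()) == spec

    def test_defaults_are_benchmark_settings(self):
        assert DEFAULT_HYPERPARAMETERS["rf"]["n_trees"] == 500
        assert DEFAULT_HYPERPARAMETERS["boost"]["learning_rate"] == 0.1
        assert DEFAULT_HYPERPARAMETERS["boost"]["interaction_depth"] == 1
        assert DEFAULT_HYPERPARAMETERS["knn"]["max_k"] == 20
        assert DEFAULT_HYPERPARAMETERS["nnet"] == {
            "hidden": 10, "threshold": 0.05, "max_steps": 100_000,
        }
        assert DEFAULT_HYPERPARAMETERS["tree"] == {"min_split": 20, "max_depth": 10}


class TestLeastSquares:
    def test_exact_line(self):
        x = np.arange(5.0)[:, None]
        model = fit_lm(x, 2 * x.ravel() + 1)
        assert model.intercept_ == pytest.approx(1.0, abs=1e-10)
        assert model.coef_[0] == pytest.approx(2.0, abs=1e-10)
        assert model.predict(np.array([[3.0]]))[0] == pytest.approx(7.0)

    def test_matches_pseudo_inverse_oracle(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        model = fit_lm(X, y)
        A = np.column_stack([np.ones(30), X])
        beta = np.linalg.pinv(A) @ y
        np.testing.assert_allclose(
            np.concatenate([[model.intercept_], model.coef_]), beta, atol=1e-8
        )

    def test_duplicated_column_raises(self, rng):
        x = rng.normal(size=(20, 1))
        X = np.column_stack([x, x])
        with pytest.raises(np.linalg.LinAlgError, match="rank-deficient"):
            fit_lm(X, rng.normal(size=20))

    def test_feature_count_mismatch(self, rng):
        model = fit_lm(rng.normal(size=(10, 2)), rng.normal(size=10))
        with pytest.raises(ValueError, match="features"):
            model.predict(rng.normal(size=(3, 4)))


class TestPenalized:
    def test_ridge_small_lambda_matches_ols(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(0, 0.1, 40)
        ridge = PenalizedLinearCV("ridge", lambdas=[1e-10]).fit(X, y)
        ols = fit_lm(X, y)
        np.testing.assert_allclose(ridge.coef_, ols.coef_, atol=1e-6)
        np.testing.assert_allclose(ridge.intercept_, ols.intercept_, atol=1e-6)

    def test_huge_lambda_zeroes_slopes(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        for penalty in ("ridge", "lasso"):
            model = PenalizedLinearCV(penalty, lambdas=[1e8]).fit(X, y)
            np.testing.assert_allclose(model.coef_, 0.0, atol=1e-4)

    def test_lasso_soft_threshold_on_orthogonal_design(self, rng):
        # columns with zero mean, population sd 1, X^T X = n I
        n, p = 32, 3
        raw = rng.normal(size=(n, p))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)
        X = q * np.sqrt(n)
        y = rng.normal(size=n)
        alpha = 0.15
        model = PenalizedLinearCV("lasso", lambdas=[alpha]).fit(X, y)
        z = X.T @ (y - y.mean()) / n
        expected = np.sign(z) * np.clip(np.abs(z) - alpha, 0.0, None)
        np.testing.assert_allclose(model.coef_, expected, atol=1e-6)

    def test_ridge_norm_monotone_in_lambda(self, rng):
        X = rng.normal(size=(50, 4))
        y = X @ [3.0, -1.0, 2.0, 0.0] + rng.normal(0, 0.5, 50)
        norms = [
            np.linalg.norm(PenalizedLinearCV("ridge", lambdas=[lam]).fit(X, y).coef_)
            for lam in np.logspace(-4, 4, 15)
        ]
        assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))

    def test_small_n_falls_back_to_loo(self, rng):
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        with pytest.warns(UserWarning, match="leave-one-out"):
            PenalizedLinearCV("lasso", cv_folds=10).fit(X, y)


class TestTree:
    def test_constant_response_single_leaf(self, rng):
        tree = make_regressor("tree").fit(rng.normal(size=(30, 2)), np.full(30, 4.2))
        assert tree.get_n_leaves() == 1
        np.testing.assert_allclose(tree.predict(rng.normal(size=(5, 2))), 4.2)

    def test_step_function_single_split_at_midpoint(self):
        x = np.concatenate([np.linspace(-2, -0.1, 20), np.linspace(0.1, 2, 20)])[:, None]
        y = (x.ravel() > 0).astype(float)
        tree = make_regressor("tree").fit(x, y)
        assert tree.get_n_leaves() == 2
        threshold = tree.tree_.threshold[0]
        assert -0.1 < threshold < 0.1
        np.testing.assert_allclose(sorted(tree.predict([[-1.0], [1.0]])), [0.0, 1.0])

    def test_training_prediction_equals_leaf_mean(self, rng):
        X = rng.normal(size=(80, 2))
        y = rng.normal(size=80)
        tree = make_regressor("tree").fit(X, y)
        leaves = tree.apply(X)
        pred = tree.predict(X)
        for leaf in np.unique(leaves):
            np.testing.assert_allclose(pred[leaves == leaf], y[leaves == leaf].mean())


class TestEnsembles:
    def test_single_tree_forest_equals_cart(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.normal(size=60)
        rf = make_regressor(
            RegressorSpec("rf", {"n_trees": 1, "bootstrap": False, "max_features": 1.0}),
            seed=0,
        ).fit(X, y)
        cart = DecisionTreeRegressor(random_state=0).fit(X, y)
        np.testing.assert_allclose(rf.predict(X), cart.predict(X))

    def test_single_stump_boost_equals_depth1_tree(self, rng):
        X = rng.normal(size=(60, 2))
        y = rng.normal(size=60)
        boost = make_regressor(
            RegressorSpec("boost", {"n_trees": 1, "learning_rate": 1.0})
        ).fit(X, y)
        stump = DecisionTreeRegressor(max_depth=1).fit(X, y)
        np.testing.assert_allclose(boost.predict(X), stump.predict(X), atol=1e-10)

    def test_forest_beats_single_tree_on_linear_signal(self):
        # variance-reduction property, averaged over seeds
        wins = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.uniform(-2, 2, size=(120, 3))
            y = X @ [1.0, 2.0, -1.0] + r.normal(0, 0.5, 120)
            Xte = r.uniform(-2, 2, size=(60, 3))
            yte = Xte @ [1.0, 2.0, -1.0] + r.normal(0, 0.5, 60)
            rf = make_regressor(RegressorSpec("rf", {"n_trees": 100}), seed=seed).fit(X, y)
            tree = make_regressor("tree").fit(X, y)
            rmse = lambda m: np.sqrt(np.mean((m.predict(Xte) - yte) ** 2))
            wins.append(rmse(rf) - rmse(tree))
        assert np.mean(wins) < 0

    @pytest.mark.parametrize("family", ["rf", "boost", "nnet"])
    def test_stochastic_families_reproducible_under_seed(self, rng, family):
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        hp = {"n_trees": 20} if family in ("rf", "boost") else {"max_steps": 500}
        a = make_regressor(RegressorSpec(family, hp, seed=11)).fit(X, y)
        b = make_regressor(RegressorSpec(family, hp, seed=11)).fit(X, y)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))


class TestTriangularKNN:
    def test_k1_memorizes_training_points(self, rng):
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        knn = TriangularKNNRegressor(k=1).fit(X, y)
        np.testing.assert_allclose(knn.predict(X), y)

    def test_constant_response(self, rng):
        X = rng.normal(size=(20, 2))
        knn = TriangularKNNRegressor().fit(X, np.full(20, 3.0))
        np.testing.assert_allclose(knn.predict(rng.normal(size=(6, 2))), 3.0)

    def test_matches_hand_rolled_weighted_mean(self, rng):
        x = np.linspace(0, 9, 10)[:, None]
        y = rng.normal(size=10)
        knn = TriangularKNNRegressor(k=3).fit(x, y)
        x0 = np.array([[4.3]])
        # brute-force oracle on standardized distances
        xs = (x - x.mean()) / x.std()
        x0s = (x0 - x.mean()) / x.std()
        d = np.abs(xs.ravel() - x0s.ravel()[0])
        order = np.argsort(d, kind="stable")
        dk, bandwidth = d[order[:3]], d[order[3]]
        w = 1 - dk / bandwidth
        expected = np.sum(w * y[order[:3]]) / np.sum(w)
        assert knn.predict(x0)[0] == pytest.approx(expected)

    def test_predictions_within_response_range(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        knn = TriangularKNNRegressor().fit(X, y)
        pred = knn.predict(rng.normal(size=(30, 3)) * 2)
        assert np.all(pred >= y.min() - 1e-12) and np.all(pred <= y.max() + 1e-12)

    def test_duplicate_points_get_maximal_weight(self):
        X = np.array([[0.0], [0.0], [5.0], [9.0]])
        y = np.array([1.0, 3.0, 10.0, 20.0])
        knn = TriangularKNNRegressor(k=2).fit(X, y)
        # both duplicates at distance 0 share weight 1: prediction is their mean
        assert knn.predict(np.array([[0.0]]))[0] == pytest.approx(2.0)


class TestRPropNet:
    def test_fits_line_to_small_error(self):
        x = np.linspace(0, 1, 50)[:, None]
        net = RPropNetRegressor(random_state=3).fit(x, x.ravel())
        rmse = np.sqrt(np.mean((net.predict(x) - x.ravel()) ** 2))
        assert rmse < 0.05

    def test_bit_identical_under_seed(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        a = RPropNetRegressor(max_steps=2000, random_state=5).fit(X, y)
        b = RPropNetRegressor(max_steps=2000, random_state=5).fit(X, y)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_warns_when_budget_exhausted(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        with pytest.warns(UserWarning, match="rprop"):
            net = RPropNetRegressor(max_steps=5, random_state=0).fit(X, y)
        assert not net.converged_
        assert np.all(np.isfinite(net.predict(X)))


class TestSVR:
    def test_constant_response_within_epsilon(self, rng):
        X = rng.normal(size=(25, 2))
        svr = make_regressor("svm").fit(X, np.full(25, 7.0))
        assert np.all(np.abs(svr.predict(X) - 7.0) <= 0.1 + 1e-9)

    def test_translation_equivariance(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        base = make_regressor("svm").fit(X, y).predict(X)
        shifted = make_regressor("svm").fit(X, y + 100.0).predict(X)
        np.testing.assert_allclose(shifted - 100.0, base, atol=1e-3)
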