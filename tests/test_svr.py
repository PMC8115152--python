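"""Epsilon-SVR dual solver, KKT structure, and the GA tuner."""

import numpy as np
import pytest

from conftest import svr_qp_oracle
from skinperm import GaConfig, ga_optimize, predict_svr, rbf_kernel, train_svr
from skinperm.svr import cv_mse, dual_objective, kernel_matrix, _fold_indices


def random_instance(seed, n_max=25):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, n_max + 1))
    d = int(rng.integers(1, 4))
    X = rng.normal(size=(n, d))
    y = np.sin(X[:, 0]) + 0.3 * rng.normal(size=n)
    C = float(rng.uniform(0.5, 20.0))
    gamma = float(rng.uniform(0.1, 2.0))
    eps = float(rng.uniform(0.01, 0.2))
    return X, y, C, gamma, eps


class TestRbfKernel:
    def test_identical_points_give_one(self):
        assert rbf_kernel([1.0, 2.0], [1.0, 2.0], 3.0) == 1.0

    def test_zero_gamma_gives_one(self):
        assert rbf_kernel([0.0, 0.0], [5.0, -1.0], 0.0) == 1.0

    def test_printed_value(self):
        assert rbf_kernel([1.0, 0.0], [0.0, 0.0], 1.72) == pytest.approx(
            np.exp(-1.72), abs=1e-5
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel([1.0], [1.0, 2.0], 1.0)


class TestTrainSvr:
    def test_constant_target_all_coefficients_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 2))
        model = train_svr(X, np.full(15, 3.7), C=5.0, gamma=0.5, epsilon=0.1)
        assert np.abs(model.beta).max() == 0.0
        assert model.b == pytest.approx(3.7, abs=0.1)
        assert predict_svr(model, X) == pytest.approx(np.full(15, 3.7), abs=0.1)

    @pytest.mark.parametrize("seed", range(25))
    def test_dual_matches_qp_oracle(self, seed):
        X, y, C, gamma, eps = random_instance(seed)
        model = train_svr(X, y, C=C, gamma=gamma, epsilon=eps, tol=1e-8)
        beta_o, b_o, W_o, (Xs, K, _, _) = svr_qp_oracle(X, y, C, gamma, eps)
        W = dual_objective(K, y, model.beta, eps)
        assert W == pytest.approx(W_o, abs=1e-6)
        grid = np.linspace(X.min(axis=0), X.max(axis=0), 15)
        mine = predict_svr(model, grid)
        theirs = kernel_matrix((grid - model.mean) / model.scale, Xs, gamma) @ beta_o + b_o
        assert np.allclose(mine, theirs, atol=1e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_kkt_structure(self, seed):
        X, y, C, gamma, eps = random_instance(seed)
        model = train_svr(X, y, C=C, gamma=gamma, epsilon=eps, tol=1e-6)
        # box constraint holds exactly
        assert np.all(np.abs(model.beta) <= C + 1e-12)
        # stated KKT gap honoured
        assert model.kkt_gap < 1e-3
        # points strictly inside the tube carry zero coefficient
        resid = np.abs(y - predict_svr(model, X))
        inside = resid < eps - 1e-6
        assert np.all(np.abs(model.beta[inside]) < 1e-6)

    def test_six_point_toy_against_oracle(self):
        X = np.array([[-2.0], [-1.0], [0.0], [1.0], [2.0], [3.0]])
        y = np.array([0.1, 0.4, 1.0, 1.5, 1.4, 0.9])
        model = train_svr(X, y, C=10.0, gamma=0.8, epsilon=0.05, tol=1e-9)
        beta_o, _, W_o, (_, K, _, _) = svr_qp_oracle(X, y, 10.0, 0.8, 0.05)
        assert dual_objective(K, y, model.beta, 0.05) == pytest.approx(W_o, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_predictions_agree_with_libsvm_reference(self, seed):
        sklearn_svm = pytest.importorskip("sklearn.svm")
        X, y, C, gamma, eps = random_instance(seed + 500)
        model = train_svr(X, y, C=C, gamma=gamma, epsilon=eps, tol=1e-8)
        Xs = (X - model.mean) / model.scale
        ref = sklearn_svm.SVR(C=C, gamma=gamma, epsilon=eps, tol=1e-8)
        ref.fit(Xs, y)
        probe = np.random.default_rng(seed).normal(size=(12, X.shape[1]))
        assert np.allclose(
            predict_svr(model, probe),
            ref.predict((probe - model.mean) / model.scale),
            atol=1e-3,
        )

    def test_epsilon_monotonicity_of_support_count(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 2))
        y = np.sin(X[:, 0]) + 0.2 * rng.normal(size=25)
        counts = [
            train_svr(X, y, C=5.0, gamma=0.7, epsilon=e, tol=1e-6).n_support
            for e in (0.01, 0.05, 0.1, 0.3, 0.8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_training_prediction_reproduces_training_fit(self):
        X, y, C, gamma, eps = random_instance(99)
        model = train_svr(X, y, C=C, gamma=gamma, epsilon=eps)
        first = predict_svr(model, X)
        assert np.allclose(model.predict(X), first)

    def test_json_round_trip(self):
        from skinperm import SvrModel

        X, y, C, gamma, eps = random_instance(1)
        model = train_svr(X, y, C=C, gamma=gamma, epsilon=eps)
        clone = SvrModel.from_json(model.to_json())
        assert np.allclose(predict_svr(clone, X), predict_svr(model, X), atol=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            train_svr([[np.nan]], [1.0, 2.0], C=1, gamma=1, epsilon=0.1)
        with pytest.raises(ValueError):
            train_svr([[1.0], [2.0]], [1.0, 2.0], C=0.0, gamma=1, epsilon=0.1)

    def test_prediction_dimension_mismatch(self):
        X, y, C, gamma, eps = random_instance(3)
        model = train_svr(X, y, C=C, gamma=gamma, epsilon=eps)
        with pytest.raises(ValueError, match="feature count"):
            predict_svr(model, np.zeros((2, X.shape[1] + 1)))


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(10)
    X = rng.uniform(-2, 2, size=(30, 1))
    y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=30)
    return X, y


class TestGaOptimize:
    def small_cfg(self, seed=0):
        return GaConfig(generations=4, population=6, folds=3, seed=seed)

    def test_fitness_is_heldout_mse_with_same_folds(self, toy):
        X, y = toy
        cfg = self.small_cfg()
        rng = np.random.default_rng(cfg.seed)
        folds = _fold_indices(len(y), cfg.folds, rng)
        # recompute the cross-validated error by hand over the same folds
        by_hand = []
        for held in folds:
            mask = np.ones(len(y), dtype=bool)
            mask[held] = False
            model = train_svr(X[mask], y[mask], C=5.0, gamma=0.5,
                              epsilon=cfg.epsilon)
            by_hand.append(np.mean((predict_svr(model, X[held]) - y[held]) ** 2))
        assert cv_mse(X, y, 5.0, 0.5, cfg.epsilon, folds) == pytest.approx(
            np.mean(by_hand), abs=1e-12
        )

    def test_same_seed_identical_result(self, toy):
        X, y = toy
        a = ga_optimize(X, y, self.small_cfg(seed=5))
        b = ga_optimize(X, y, self.small_cfg(seed=5))
        assert a[:2] == b[:2]
        assert a[2] == b[2]

    def test_best_fitness_non_increasing(self, toy):
        X, y = toy
        _, _, history = ga_optimize(X, y, self.small_cfg(seed=1))
        assert all(b <= a + 1e-15 for a, b in zip(history, history[1:]))

    def test_candidates_respect_box(self, toy):
        X, y = toy
        cfg = GaConfig(generations=3, population=6, folds=3, seed=2,
                       c_range=(0.0, 50.0), gamma_range=(0.0, 2.0))
        c_best, g_best, _ = ga_optimize(X, y, cfg)
        assert 0 < c_best <= 50.0
        assert 0.0 <= g_best <= 2.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GaConfig(population=7)
        with pytest.raises(ValueError):
            GaConfig(folds=1)
        with pytest.raises(ValueError):
            GaConfig(c_range=(5.0, 5.0))
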