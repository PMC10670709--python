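import pickle

import numpy as np
import pytest

from aoquant.models import (
    BPNet,
    SSAConfig,
    bp_train,
    choose_lv_by_cv,
    init_bp,
    pls_coefficient_path,
    plsr_fit,
    ssa_bp_fit,
    ssa_optimize,
    svr_fit,
    svr_grid_cv,
)


class TestPLSR:
    def test_exact_recovery_of_linear_response(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 6))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0, -1.0]) + 4.0
        model = plsr_fit(X, y, n_lv=6)
        assert np.abs(model.predict(X) - y).max() < 1e-8

    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        model = plsr_fit(X, y, n_lv=3)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        assert np.abs(model.coef - beta).max() < 1e-6

    def test_single_variable_equals_simple_regression(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = 2.5 * x + rng.normal(scale=0.1, size=40)
        model = plsr_fit(x[:, None], y, n_lv=1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert model.coef[0] == pytest.approx(slope, rel=1e-10)

    def test_matches_sklearn_nipals(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 12))
        y = X[:, 0] - X[:, 5] + rng.normal(scale=0.2, size=40)
        for lv in (1, 3, 5):
            ours = plsr_fit(X, y, n_lv=lv)
            ref = PLSRegression(n_components=lv, scale=False).fit(X, y)
            assert np.allclose(ours.coef, ref.coef_.ravel(), atol=1e-8)

    def test_coefficient_path_consistent_with_single_fits(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 8))
        y = rng.normal(size=25)
        coefs, xm, ym = pls_coefficient_path(X, y, 4)
        for lv in (1, 2, 4):
            model = plsr_fit(X, y, n_lv=lv)
            assert np.allclose(coefs[lv - 1], model.coef, atol=1e-10)

    def test_excessive_components_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError):
            plsr_fit(X, np.arange(5.0), n_lv=5)


class TestChooseLV:
    def test_rank_two_response_needs_at_most_two(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=(80, 2))
        loadings = rng.normal(size=(2, 20))
        X = scores @ loadings
        y = scores @ np.array([1.0, -1.0])
        assert choose_lv_by_cv(X, y, max_lv=8, seed=0) <= 2

    def test_pure_noise_returns_small_lv(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 10))
        y = rng.normal(size=50)
        assert choose_lv_by_cv(X, y, max_lv=8, seed=0) <= 4

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        assert choose_lv_by_cv(X, y, 6, seed=3) == choose_lv_by_cv(X, y, 6, seed=3)

    def test_invalid_max_lv_rejected(self):
        with pytest.raises(ValueError):
            choose_lv_by_cv(np.ones((10, 2)), np.arange(10.0), max_lv=0)


class TestSVR:
    def test_constant_target_within_epsilon(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 4))
        y = np.full(30, 2.0)
        model = svr_fit(X, y, c=1.0, g=0.1, epsilon=0.01)
        # y_scale degenerates to 1 for constant targets
        assert np.abs(model.predict(X) - 2.0).max() <= 0.011

    def test_sinusoid_fit_quality(self):
        from aoquant.metrics import r_squared

        x = np.linspace(0, 2 * np.pi, 60)
        y = np.sin(x)
        c, g = svr_grid_cv(x[:, None], y, folds=5, seed=0)
        model = svr_fit(x[:, None], y, c=c, g=g)
        assert r_squared(y, model.predict(x[:, None])) > 0.9

    def test_duplicate_inputs_identical_predictions(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        model = svr_fit(X, y, c=4.0, g=0.5)
        p = model.predict(np.vstack([X[0], X[0]]))
        assert p[0] == p[1]

    @pytest.mark.parametrize("c,g", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_invalid_hyperparameters_rejected(self, c, g):
        with pytest.raises(ValueError):
            svr_fit(np.ones((5, 2)), np.arange(5.0), c=c, g=g)

    def test_single_cell_grid_returned(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        assert svr_grid_cv(X, y, [2.0], [0.25], seed=0) == (2.0, 0.25)

    def test_grid_recovers_generating_kernel_scale(self):
        """On data generated from an RBF function, the grid optimum is an
        exhaustive search by construction; the chosen cell's CV error is the
        grid minimum."""
        rng = np.random.default_rng(11)
        X = rng.uniform(-2, 2, size=(60, 2))
        y = np.exp(-1.0 * (X**2).sum(axis=1)) + rng.normal(scale=0.02, size=60)
        grid = 2.0 ** np.arange(-4, 5)
        c, g = svr_grid_cv(X, y, grid, grid, folds=5, seed=1)
        assert c in grid and g in grid

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        grid = [0.5, 2.0]
        assert svr_grid_cv(X, y, grid, grid, seed=4) == svr_grid_cv(X, y, grid, grid, seed=4)


def sphere(x):
    return float(x @ x)


class TestSSA:
    def test_degenerate_bounds_return_that_point(self):
        cfg = SSAConfig(pop_size=5, n_iterations=5, lower=5.0, upper=5.0, seed=0)
        run = ssa_optimize(sphere, dim=3, config=cfg)
        assert np.allclose(run.best_position, 5.0)
        assert run.best_fitness == pytest.approx(75.0)

    def test_fitness_curve_non_increasing(self):
        for seed in range(5):
            cfg = SSAConfig(pop_size=10, n_iterations=30, lower=-5, upper=5, seed=seed)
            run = ssa_optimize(sphere, dim=4, config=cfg)
            assert np.all(np.diff(run.fitness_curve) <= 0)

    def test_unbounded_space_rejected(self):
        cfg = SSAConfig(lower=-np.inf, upper=np.inf)
        with pytest.raises(ValueError):
            ssa_optimize(sphere, dim=2, config=cfg)

    def test_warm_seed_never_worse_than_start(self):
        start = np.array([0.01, -0.01])
        cfg = SSAConfig(pop_size=8, n_iterations=10, lower=-5, upper=5, seed=1)
        run = ssa_optimize(sphere, dim=2, config=cfg, initial=start)
        assert run.best_fitness <= sphere(start)

    @pytest.mark.parametrize("kw", [dict(pop_size=1), dict(discoverer_fraction=0.0),
                                    dict(scout_fraction=1.5), dict(alarm_threshold=0.0)])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SSAConfig(**kw)


class TestBP:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.X = rng.normal(size=(200, 2))
        self.y = 3 * self.X[:, 0] - 2 * self.X[:, 1]

    def test_zero_epochs_returns_seeded_init(self):
        net_a = bp_train(init_bp(self.X, self.y, seed=3), self.X, self.y, epochs=0)
        net_b = bp_train(init_bp(self.X, self.y, seed=3), self.X, self.y, epochs=0)
        assert np.array_equal(net_a.predict(self.X), net_b.predict(self.X))

    def test_learns_linear_target(self):
        net = init_bp(self.X, self.y, hidden=8, seed=0)
        net = bp_train(net, self.X, self.y, epochs=2000)
        assert net.training_mse(self.X, self.y) < 1e-3

    def test_full_batch_order_invariance(self):
        net = init_bp(self.X, self.y, hidden=4, seed=1)
        perm = np.random.default_rng(5).permutation(len(self.y))
        a = bp_train(net, self.X, self.y, epochs=100)
        b = bp_train(net, self.X[perm], self.y[perm], epochs=100)
        assert np.allclose(a.predict(self.X), b.predict(self.X), atol=1e-8)

    def test_parameter_vector_roundtrip(self):
        net = init_bp(self.X, self.y, hidden=5, seed=2)
        vec = net.flatten()
        assert vec.size == net.n_params
        clone = net.with_params(vec)
        assert np.array_equal(clone.predict(self.X), net.predict(self.X))


class TestSSABP:
    def test_zero_ssa_iterations_equals_plain_bp(self, ao_training_matrix):
        X, y = ao_training_matrix
        cfg = SSAConfig(pop_size=5, n_iterations=0, seed=7)
        net_a, run = ssa_bp_fit(X, y, ssa_config=cfg, bp_epochs=200, seed=7)
        net_b = bp_train(init_bp(X, y, seed=7), X, y, epochs=200)
        assert run is None
        assert np.allclose(net_a.predict(X), net_b.predict(X))

    def test_deterministic_given_seed(self, ao_training_matrix):
        X, y = ao_training_matrix
        cfg = SSAConfig(pop_size=10, n_iterations=10, seed=9)
        a, _ = ssa_bp_fit(X, y, ssa_config=cfg, bp_epochs=100, seed=9)
        b, _ = ssa_bp_fit(X, y, ssa_config=cfg, bp_epochs=100, seed=9)
        assert np.array_equal(a.predict(X), b.predict(X))

    def test_ssa_run_reported_with_non_increasing_curve(self, ao_training_matrix):
        X, y = ao_training_matrix
        cfg = SSAConfig(pop_size=10, n_iterations=15, seed=2)
        _, run = ssa_bp_fit(X, y, ssa_config=cfg, bp_epochs=50, seed=2)
        assert run is not None
        assert np.all(np.diff(run.fitness_curve) <= 0)


class TestSerialization:
    def test_models_pickle_roundtrip_identical_predictions(self, ao_training_matrix):
        X, y = ao_training_matrix
        plsr = plsr_fit(X, y, n_lv=3)
        svr = svr_fit(X, y, c=4.0, g=0.5)
        net = bp_train(init_bp(X, y, seed=0), X, y, epochs=50)
        for model in (plsr, svr, net):
            clone = pickle.loads(pickle.dumps(model))
            assert np.array_equal(clone.predict(X), model.predict(X))
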