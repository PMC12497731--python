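import numpy as np
import pytest

from saltlax import (
    OptimizerConfig,
    SearchSpace,
    STRATEGIES,
    minimize,
    tune_lssvm,
)
from saltlax.lssvm import predict, train_lssvm
from saltlax.optimizers import default_hyper_space

UNIT_1D = SearchSpace((0.0,), (10.0,))


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class TestSearchSpace:
    def test_log_scale_round_trip(self):
        space = default_hyper_space()
        lo, hi = space.internal_bounds()
        assert lo == pytest.approx([-2.0, -2.0])
        assert hi == pytest.approx([4.0, 2.0])
        assert space.to_natural(np.array([0.0, 1.0])) == pytest.approx([1.0, 10.0])

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace((1.0,), (1.0,))
        with pytest.raises(ValueError):
            SearchSpace((-1.0,), (1.0,), ("log10",))


class TestMinimize:
    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_solves_1d_quadratic(self, strategy):
        config = OptimizerConfig(strategy=strategy, n_particles=20, max_iter=100, seed=5)
        result = minimize(lambda x: (x[0] - 3.0) ** 2, UNIT_1D, config)
        assert abs(result.best_position[0] - 3.0) < 1e-3

    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_constant_objective_is_harmless(self, strategy):
        config = OptimizerConfig(strategy=strategy, n_particles=5, max_iter=20, seed=0)
        result = minimize(lambda x: 1.0, UNIT_1D, config)
        assert result.best_fitness == 1.0
        assert 0.0 <= result.best_position[0] <= 10.0
        assert np.all(result.trace == 1.0)

    def test_rosenbrock_benchmark(self):
        space = SearchSpace((-2.0, -2.0), (2.0, 2.0))
        config = OptimizerConfig(strategy="nrbo", n_particles=40, max_iter=500, seed=1)
        rosen = lambda x: (1 - x[0]) ** 2 + 100.0 * (x[1] - x[0] ** 2) ** 2
        result = minimize(rosen, space, config)
        assert result.best_fitness < 1e-2  # true minimum is 0 at (1, 1)

    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_same_seed_bit_identical(self, strategy):
        config = OptimizerConfig(strategy=strategy, n_particles=10, max_iter=30, seed=9)
        a = minimize(sphere, UNIT_1D.__class__((-5.0,) * 3, (5.0,) * 3), config)
        b = minimize(sphere, SearchSpace((-5.0,) * 3, (5.0,) * 3), config)
        assert a.best_position.tobytes() == b.best_position.tobytes()
        assert a.trace.tobytes() == b.trace.tobytes()
        assert a.n_evaluations == b.n_evaluations

    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_all_evaluations_within_bounds(self, strategy):
        seen = []
        space = SearchSpace((-1.0, 2.0), (1.0, 5.0))

        def probe(x):
            seen.append(np.array(x))
            return sphere(x)

        config = OptimizerConfig(strategy=strategy, n_particles=8, max_iter=25, seed=2)
        minimize(probe, space, config)
        arr = np.array(seen)
        assert (arr[:, 0] >= -1.0).all() and (arr[:, 0] <= 1.0).all()
        assert (arr[:, 1] >= 2.0).all() and (arr[:, 1] <= 5.0).all()

    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_trace_monotone_non_increasing(self, strategy):
        config = OptimizerConfig(strategy=strategy, n_particles=10, max_iter=50, seed=4)
        result = minimize(
            lambda x: np.sin(5 * x[0]) + 0.1 * x[0] ** 2, SearchSpace((-10.0,), (10.0,)), config
        )
        assert (np.diff(result.trace) <= 0).all()

    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_sphere_5d_batch(self, strategy):
        space = SearchSpace((-5.0,) * 5, (5.0,) * 5)
        for seed in range(10):
            config = OptimizerConfig(strategy=strategy, n_particles=30, max_iter=300, seed=seed)
            assert minimize(sphere, space, config).best_fitness < 1e-4

    def test_non_finite_objective_treated_as_inf(self):
        def nasty(x):
            return float("nan") if x[0] > 5 else (x[0] - 3.0) ** 2

        result = minimize(nasty, UNIT_1D, OptimizerConfig(n_particles=15, max_iter=60, seed=3))
        assert abs(result.best_position[0] - 3.0) < 1e-2

    def test_canonical_nrbo_also_converges(self):
        config = OptimizerConfig(
            strategy="nrbo", canonical_nrbo=True, n_particles=20, max_iter=100, seed=6
        )
        result = minimize(lambda x: (x[0] - 3.0) ** 2, UNIT_1D, config)
        assert abs(result.best_position[0] - 3.0) < 1e-3

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            OptimizerConfig(n_particles=1)
        with pytest.raises(ValueError):
            OptimizerConfig(strategy="genetic")
        with pytest.raises(ValueError):
            OptimizerConfig(df=1.5)


class TestTuneLSSVM:
    def _surface(self, rng, gamma0=50.0, sigma0=0.3, n=40):
        X = rng.random((n, 2))
        anchors = rng.random((5, 2))
        coef = rng.normal(size=5)
        from saltlax.lssvm import rbf_kernel

        y = rbf_kernel(X, anchors, sigma0) @ coef + 0.001 * rng.normal(size=n)
        return X, y

    def test_recovers_generating_surface_quality(self):
        rng = np.random.default_rng(12)
        X, y = self._surface(rng)
        gen_model = train_lssvm(X, y, 50.0, 0.3)
        gen_mse = np.mean((predict(gen_model, X) - y) ** 2)
        gamma, sigma, _ = tune_lssvm(
            X[:30],
            y[:30],
            X[30:],
            y[30:],
            fitness_mode="paper_faithful",
            config=OptimizerConfig(n_particles=15, max_iter=60, seed=1),
        )
        tuned = train_lssvm(X[:30], y[:30], gamma, sigma)
        tuned_mse = np.mean((predict(tuned, X[:30]) - y[:30]) ** 2)
        assert tuned_mse <= 1.5 * max(gen_mse, 1e-12) + 1e-9

    def test_collapsed_space_returns_that_point(self):
        rng = np.random.default_rng(3)
        X, y = self._surface(rng, n=20)
        space = SearchSpace((9.999999, 0.49999999), (10.000001, 0.50000001))
        gamma, sigma, _ = tune_lssvm(
            X[:15], y[:15], X[15:], y[15:],
            space=space,
            config=OptimizerConfig(n_particles=5, max_iter=5, seed=0),
        )
        assert gamma == pytest.approx(10.0, rel=1e-6)
        assert sigma == pytest.approx(0.5, rel=1e-6)

    def test_nrbo_and_pso_agree_on_convex_fitness(self):
        # quadratic pseudo-fitness via minimize directly: both strategies
        # should reach the same basin on a convex target
        space = SearchSpace((-5.0, -5.0), (5.0, 5.0))
        results = [
            minimize(
                sphere, space, OptimizerConfig(strategy=s, n_particles=20, max_iter=150, seed=7)
            ).best_fitness
            for s in ("nrbo", "pso")
        ]
        assert abs(results[0] - results[1]) < 1e-6

    def test_cv_mode_never_needs_test_data(self):
        rng = np.random.default_rng(8)
        X, y = self._surface(rng, n=25)
        gamma, sigma, result = tune_lssvm(
            X, y, fitness_mode="cv",
            config=OptimizerConfig(n_particles=8, max_iter=20, seed=2),
        )
        assert gamma > 0 and sigma > 0 and np.isfinite(result.best_fitness)

    def test_excessive_fold_count_rejected(self):
        rng = np.random.default_rng(1)
        X, y = self._surface(rng, n=4)
        with pytest.raises(ValueError, match="fold"):
            tune_lssvm(X, y, fitness_mode="cv", n_folds=10)
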