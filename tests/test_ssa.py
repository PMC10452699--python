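import numpy as np
import pytest

from mtdnet import (SSAConfig, SSAState, random_search, ssa_optimize,
                    ssa_step_alerters, ssa_step_discoverers,
                    ssa_step_followers)

BOUNDS = np.array([[-5.0, 5.0], [-5.0, 5.0]])


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


def make_state(positions, fitness):
    positions = np.asarray(positions, dtype=float)
    fitness = np.asarray(fitness, dtype=float)
    b, w = int(np.argmin(fitness)), int(np.argmax(fitness))
    return SSAState(positions=positions, fitness=fitness,
                    best_position=positions[b].copy(), best_fitness=float(fitness[b]),
                    worst_position=positions[w].copy(), worst_fitness=float(fitness[w]))


class TestConfigValidation:
    def test_alerter_fraction_outside_band_rejected(self):
        with pytest.raises(ValueError, match="alerter"):
            SSAConfig(bounds=BOUNDS, alerter_fraction=0.3)

    def test_safety_threshold_band(self):
        with pytest.raises(ValueError, match="safety"):
            SSAConfig(bounds=BOUNDS, safety_threshold=0.3)

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            SSAConfig(bounds=[[1.0, -1.0]])


class TestDiscovererStep:
    def test_safe_branch_multiplicative_decay(self, rng):
        cfg = SSAConfig(bounds=np.array([[0.0, 5.0]]), n_sparrows=4,
                        max_iter=100, discoverer_fraction=0.25)
        state = make_state([[1.0], [2.0], [3.0], [4.0]], [0.1, 0.2, 0.3, 0.4])
        new = ssa_step_discoverers(state, cfg, r2=0.1, rng=rng, alphas=[0.5])
        # rank-1 discoverer at x=1.0: decay factor exp(-1 / (0.5 * 100))
        assert new[0, 0] == pytest.approx(np.exp(-1 / 50), abs=1e-12)
        assert np.array_equal(new[1:], state.positions[1:])

    def test_alarm_branch_with_zero_noise_is_identity(self, rng):
        cfg = SSAConfig(bounds=BOUNDS, n_sparrows=4, discoverer_fraction=0.25)
        state = make_state(np.ones((4, 2)), [0.1, 0.2, 0.3, 0.4])
        new = ssa_step_discoverers(state, cfg, r2=0.99, rng=rng,
                                   noise=[np.zeros(2)])
        assert np.array_equal(new, state.positions)

    def test_alpha_one_low_rank_limit(self, rng):
        # with alpha=1 and large T the decay factor approaches exp(0) = 1
        cfg = SSAConfig(bounds=np.array([[0.0, 5.0]]), n_sparrows=4,
                        max_iter=10000, discoverer_fraction=0.25)
        state = make_state([[2.0], [3.0], [4.0], [4.5]], [1, 2, 3, 4])
        new = ssa_step_discoverers(state, cfg, r2=0.1, rng=rng, alphas=[1.0])
        assert new[0, 0] == pytest.approx(2.0, rel=1e-3)


class TestFollowerStep:
    def test_follower_at_producer_position_stays(self, rng):
        cfg = SSAConfig(bounds=BOUNDS, n_sparrows=4, discoverer_fraction=0.25)
        pos = np.array([[1.0, 1.0], [1.0, 1.0], [0.5, 0.5], [2.0, 2.0]])
        state = make_state(pos, [0.1, 0.2, 0.3, 0.4])
        new = ssa_step_followers(state, cfg, rng, best_discoverer=pos[0])
        # rank-2 follower (index 1) sits exactly at x_p: |x - x_p| term vanishes
        assert np.array_equal(new[1], pos[0])

    def test_hungry_followers_resampled_near_worst_kernel(self):
        rng = np.random.default_rng(0)
        cfg = SSAConfig(bounds=BOUNDS, n_sparrows=4, discoverer_fraction=0.25)
        pos = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [4.0, 4.0]])
        state = make_state(pos, [0.1, 0.2, 0.3, 0.4])
        new = ssa_step_followers(state, cfg, rng)
        # ranks 3 and 4 exceed n/2: both take the Gamma * exp(x_w - x) form
        assert not np.array_equal(new[2], pos[2])
        assert not np.array_equal(new[3], pos[3])
        assert np.all(new >= BOUNDS[:, 0]) and np.all(new <= BOUNDS[:, 1])


class TestAlerterStep:
    def test_beta_zero_lands_on_best(self, rng):
        cfg = SSAConfig(bounds=BOUNDS, n_sparrows=4)
        pos = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        state = make_state(pos, [0.0, 1.0, 2.0, 3.0])
        new = ssa_step_alerters(state, cfg, rng, indices=[2], betas=[0.0])
        assert np.array_equal(new[2], state.best_position)

    def test_equal_fitness_displacement_finite(self, rng):
        cfg = SSAConfig(bounds=BOUNDS, n_sparrows=4)
        pos = np.zeros((4, 2))
        state = make_state(pos, [1.0, 1.0, 1.0, 1.0])  # f_i == f_w everywhere
        new = ssa_step_alerters(state, cfg, rng, indices=[0], ks=[0.7])
        assert np.all(np.isfinite(new))

    def test_zero_k_at_best_position_no_movement(self, rng):
        cfg = SSAConfig(bounds=BOUNDS, n_sparrows=4)
        pos = np.array([[0.5, 0.5], [1, 1], [2, 2], [3, 3.0]])
        state = make_state(pos, [0.0, 1.0, 2.0, 3.0])
        new = ssa_step_alerters(state, cfg, rng, indices=[0], ks=[0.0])
        assert np.array_equal(new[0], pos[0])


class TestOptimize:
    def test_sphere_convergence(self):
        cfg = SSAConfig(bounds=BOUNDS, n_sparrows=20, max_iter=100, seed=7)
        result = ssa_optimize(sphere, cfg)
        assert result.best_fitness < 1e-3
        assert np.all(np.diff(result.trace) <= 0)
        assert np.all(result.best_position >= BOUNDS[:, 0])
        assert np.all(result.best_position <= BOUNDS[:, 1])

    def test_constant_fitness_returns_in_bounds_point(self):
        cfg = SSAConfig(bounds=BOUNDS, n_sparrows=6, max_iter=5, seed=1)
        result = ssa_optimize(lambda x: 3.14, cfg)
        assert result.best_fitness == 3.14
        assert np.all(np.abs(result.best_position) <= 5)

    def test_single_iteration_bookkeeping(self):
        cfg = SSAConfig(bounds=BOUNDS, n_sparrows=10, max_iter=1, seed=2)
        result = ssa_optimize(sphere, cfg)
        assert len(result.trace) == 2
        assert result.trace[1] <= result.trace[0]
        assert result.n_evaluations == 20

    def test_deterministic_under_seed(self):
        cfg = SSAConfig(bounds=BOUNDS, n_sparrows=10, max_iter=20, seed=3)
        a, b = ssa_optimize(sphere, cfg), ssa_optimize(sphere, cfg)
        assert a.best_fitness == b.best_fitness
        assert np.array_equal(a.trace, b.trace)

    def test_nonfinite_fitness_rejected(self):
        cfg = SSAConfig(bounds=BOUNDS, n_sparrows=6, max_iter=3, seed=0)
        with pytest.raises(ValueError, match="finite"):
            ssa_optimize(lambda x: np.nan, cfg)

    def test_convex_fitness_trace_non_increasing_many_seeds(self):
        for seed in range(5):
            cfg = SSAConfig(bounds=BOUNDS, n_sparrows=10, max_iter=30, seed=seed)
            result = ssa_optimize(sphere, cfg)
            assert np.all(np.diff(result.trace) <= 0)

    def test_beats_random_search_at_matched_budget(self):
        ssa_best, rand_best = [], []
        for seed in range(10):
            cfg = SSAConfig(bounds=BOUNDS, n_sparrows=20, max_iter=50, seed=seed)
            res = ssa_optimize(sphere, cfg)
            ssa_best.append(res.best_fitness)
            rand_best.append(random_search(sphere, cfg, res.n_evaluations).best_fitness)
        assert np.median(ssa_best) <= np.median(rand_best)
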