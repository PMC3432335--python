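"""Unit and property tests for the PSO / hybrid island-PSO optimizers."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from swarmreg.benchmarks import F1, F3
from swarmreg.swarm import (
    OptimizerConfig,
    SearchSpace,
    SwarmState,
    Subpopulation,
    arithmetic_crossover,
    crossover_step,
    hpso_optimize,
    initialize_swarm,
    pso_optimize,
    pso_step,
    recombine_velocities,
    update_inertia,
)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class TestConfig:
    def test_even_partition(self):
        assert OptimizerConfig(n_particles=56, n_subpopulations=4).subpopulation_sizes() == [14] * 4

    def test_uneven_partition_differs_by_at_most_one(self):
        sizes = OptimizerConfig(n_particles=10, n_subpopulations=4).subpopulation_sizes()
        assert sizes == [3, 2, 2, 3][:4] or max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 10

    def test_island_below_two_members_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            OptimizerConfig(n_particles=5, n_subpopulations=4).subpopulation_sizes()

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            OptimizerConfig(iterations=0)
        with pytest.raises(ValueError):
            OptimizerConfig(w_min=0.9, w_max=0.5)


class TestInitialization:
    def test_positions_in_bounds_and_partitioned(self):
        space = SearchSpace([-5.12] * 3, [5.11] * 3)
        config = OptimizerConfig(n_particles=56, n_subpopulations=4, seed=1)
        state = initialize_swarm(space, config, sphere)
        assert [s.size for s in state.subpopulations] == [14] * 4
        for sub in state.subpopulations:
            assert np.all(sub.positions >= space.lower) and np.all(sub.positions <= space.upper)
        assert state.inertia == config.w_max

    def test_same_seed_bitwise_identical(self):
        space = SearchSpace([-1, -1], [1, 1])
        config = OptimizerConfig(n_particles=8, n_subpopulations=2, seed=42)
        a = initialize_swarm(space, config, sphere)
        b = initialize_swarm(space, config, sphere)
        for sa, sb in zip(a.subpopulations, b.subpopulations):
            assert np.array_equal(sa.positions, sb.positions)
            assert np.array_equal(sa.velocities, sb.velocities)
        assert a.global_best_score == b.global_best_score

    def test_initial_bests_match_objective(self):
        space = SearchSpace([-2, -2], [2, 2])
        state = initialize_swarm(space, OptimizerConfig(n_particles=6, n_subpopulations=2, seed=0), sphere)
        for sub in state.subpopulations:
            for particle in sub.particles():
                # internal sense is maximize, objective minimized -> negated
                assert particle.personal_best_score == pytest.approx(-sphere(particle.position))


class TestVelocityUpdate:
    def test_hand_computed_single_update(self, const_rng):
        """v' = w v + c1 r (p - x) + c2 r (g - x), x' = x + v' with r forced to 1."""
        objective = lambda x: -((x[0] - 2.0) ** 2)
        space = SearchSpace([-10.0], [10.0], sense="maximize")
        config = OptimizerConfig(n_particles=2, n_subpopulations=1, v_max_fraction=100.0)
        sub = Subpopulation(
            positions=np.array([[0.0]]),
            velocities=np.array([[1.0]]),
            pbest_positions=np.array([[2.0]]),
            pbest_scores=np.array([0.0]),
        )
        state = SwarmState(
            subpopulations=[sub],
            global_best_position=np.array([2.0]),
            global_best_score=0.0,
            inertia=0.5,
            iteration=0,
            rng=const_rng(1.0),
            sense="maximize",
        )
        pso_step(state, sub, objective, space, config)
        # v' = 0.5*1 + 2*(2-0) + 2*(2-0) = 8.5 ; x' = 0 + 8.5
        assert sub.velocities[0, 0] == pytest.approx(8.5)
        assert sub.positions[0, 0] == pytest.approx(8.5)

    def test_fixed_point_at_shared_best(self):
        """A particle sitting at its own and the group's best with zero velocity stays."""
        objective = lambda x: -float(x[0] ** 2)
        space = SearchSpace([-1.0], [1.0], sense="maximize")
        config = OptimizerConfig(n_particles=2, n_subpopulations=1)
        sub = Subpopulation(
            positions=np.array([[0.0]]),
            velocities=np.array([[0.0]]),
            pbest_positions=np.array([[0.0]]),
            pbest_scores=np.array([0.0]),
        )
        state = SwarmState(
            subpopulations=[sub],
            global_best_position=np.array([0.0]),
            global_best_score=0.0,
            inertia=0.7,
            iteration=0,
            rng=np.random.default_rng(0),
            sense="maximize",
        )
        pso_step(state, sub, objective, space, config)
        assert sub.positions[0, 0] == 0.0 and sub.velocities[0, 0] == 0.0

    def test_non_finite_objective_reported_with_position(self):
        space = SearchSpace([-1.0], [1.0])
        config = OptimizerConfig(n_particles=4, n_subpopulations=2, seed=0)
        with pytest.raises(FloatingPointError, match="non-finite"):
            initialize_swarm(space, config, lambda x: float("nan"))


class TestInertia:
    def test_linear_schedule_reaches_minimum(self):
        config = OptimizerConfig(iterations=100)
        state = SwarmState([], np.zeros(1), 0.0, config.w_max, 0, np.random.default_rng(0))
        dw = (config.w_min - config.w_max) / config.iterations
        assert dw == pytest.approx(-0.0058)
        for _ in range(100):
            update_inertia(state, config)
        assert state.inertia == pytest.approx(config.w_min)

    def test_weight_clamped_to_range(self):
        config = OptimizerConfig(iterations=50)
        state = SwarmState([], np.zeros(1), 0.0, config.w_max, 0, np.random.default_rng(0))
        for _ in range(120):  # run far past the schedule end
            update_inertia(state, config)
            assert config.w_min <= state.inertia <= config.w_max


class TestCrossover:
    def test_identical_parents_produce_identical_offspring(self):
        p = np.array([1.5, -2.0, 3.0])
        a, b = arithmetic_crossover(p, p, np.random.default_rng(3))
        assert np.allclose(a, p) and np.allclose(b, p)

    def test_r_equal_one_returns_parents(self, const_rng):
        xi, xj = np.array([0.0, 1.0]), np.array([2.0, 3.0])
        a, b = arithmetic_crossover(xi, xj, const_rng(1.0))
        assert np.allclose(a, xi) and np.allclose(b, xj)

    def test_quarter_blend_example(self, const_rng):
        a, b = arithmetic_crossover(np.array([0.0, 0.0]), np.array([2.0, 4.0]), const_rng(0.25))
        assert np.allclose(a, [1.5, 3.0])
        assert np.allclose(b, [0.5, 1.0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            arithmetic_crossover(np.zeros(2), np.zeros(3), np.random.default_rng(0))

    @given(st.integers(0, 2**31 - 1))
    def test_offspring_lie_in_parent_interval(self, seed):
        rng = np.random.default_rng(seed)
        xi, xj = rng.normal(size=4), rng.normal(size=4)
        a, b = arithmetic_crossover(xi, xj, rng)
        lo, hi = np.minimum(xi, xj), np.maximum(xi, xj)
        for off in (a, b):
            assert np.all(off >= lo - 1e-12) and np.all(off <= hi + 1e-12)


class TestVelocityRecombination:
    def test_equal_parents_unchanged(self):
        v = np.array([1.0, -2.0, 0.5])
        a, b = recombine_velocities(v, v)
        assert np.allclose(a, v) and np.allclose(b, v)

    def test_three_four_five_example(self):
        a, b = recombine_velocities(np.array([3.0, 0.0]), np.array([0.0, 4.0]))
        assert np.allclose(a, [1.8, 2.4])
        assert np.allclose(b, [2.4, 3.2])

    def test_cancelling_parents_fall_back_to_originals(self):
        vi = np.array([1.0, -1.0])
        a, b = recombine_velocities(vi, -vi)
        assert np.allclose(a, vi) and np.allclose(b, -vi)

    @given(st.integers(0, 2**31 - 1))
    def test_speed_preserved(self, seed):
        rng = np.random.default_rng(seed)
        vi, vj = rng.normal(size=3), rng.normal(size=3)
        a, b = recombine_velocities(vi, vj)
        assert np.linalg.norm(a) == pytest.approx(np.linalg.norm(vi), abs=1e-12)
        assert np.linalg.norm(b) == pytest.approx(np.linalg.norm(vj), abs=1e-12)


class TestCrossoverStep:
    def _state(self, seed=0):
        space = SearchSpace([-5.12] * 3, [5.11] * 3)
        config = OptimizerConfig(n_particles=12, n_subpopulations=3, seed=seed)
        return space, config, initialize_swarm(space, config, sphere)

    def test_island_sizes_conserved(self):
        space, config, state = self._state()
        sizes = [s.size for s in state.subpopulations]
        crossover_step(state, sphere, space, config)
        assert [s.size for s in state.subpopulations] == sizes

    def test_global_best_never_worsens(self):
        space, config, state = self._state()
        before = state.global_best_score
        crossover_step(state, sphere, space, config)
        assert state.global_best_score >= before

    def test_single_island_is_a_no_op(self):
        space = SearchSpace([-1.0, -1.0], [1.0, 1.0])
        config = OptimizerConfig(n_particles=4, n_subpopulations=1, seed=0)
        state = initialize_swarm(space, config, sphere)
        positions = [s.positions.copy() for s in state.subpopulations]
        crossover_step(state, sphere, space, config)
        assert all(np.array_equal(p, s.positions) for p, s in zip(positions, state.subpopulations))

    def test_identical_leaders_insert_their_common_position(self):
        space = SearchSpace([-1.0], [1.0], sense="maximize")
        config = OptimizerConfig(n_particles=4, n_subpopulations=2)
        p = np.array([0.5])
        subs = [
            Subpopulation(
                positions=np.array([[0.5], [-0.9]]),
                velocities=np.zeros((2, 1)),
                pbest_positions=np.array([[0.5], [-0.9]]),
                pbest_scores=np.array([1.0, -2.0]),
                index=k,
            )
            for k in range(2)
        ]
        state = SwarmState(subs, p.copy(), 1.0, 0.9, 0, np.random.default_rng(0), "maximize")
        crossover_step(state, lambda x: float(1 - (x[0] - 0.5) ** 2), space, config)
        for sub in subs:
            assert np.allclose(sub.positions[1], p)  # worst member replaced by leader blend


class TestOptimizers:
    def test_pso_converges_on_sphere(self):
        config = OptimizerConfig(n_particles=30, n_subpopulations=1, iterations=100, seed=0, crossover=False)
        result = pso_optimize(None, F1.space, config, objective_batch=F1.evaluate_many)
        assert result.best_score < 1e-6
        best = result.trace["global_best_score"].to_numpy()
        assert np.all(np.diff(best) <= 0)  # minimize: best-so-far non-increasing

    def test_hpso_trace_monotone_and_in_bounds(self):
        config = OptimizerConfig(n_particles=16, n_subpopulations=4, iterations=40, seed=2)
        result = hpso_optimize(None, F3.space, config, objective_batch=F3.evaluate_many)
        best = result.trace["global_best_score"].to_numpy()
        assert np.all(np.diff(best) <= 0)
        assert np.all(result.best_position >= F3.lower) and np.all(result.best_position <= F3.upper)

    def test_hpso_single_island_reduces_to_pso_exactly(self):
        """With one island and crossover off the hybrid replays plain PSO bit for bit."""
        config = OptimizerConfig(
            n_particles=20, n_subpopulations=1, iterations=30, seed=7, crossover=False
        )
        a = pso_optimize(None, F3.space, config, objective_batch=F3.evaluate_many)
        b = hpso_optimize(None, F3.space, config, objective_batch=F3.evaluate_many)
        assert np.array_equal(a.best_position, b.best_position)
        assert a.best_score == b.best_score
        assert np.array_equal(
            a.trace["global_best_score"].to_numpy(), b.trace["global_best_score"].to_numpy()
        )

    def test_seeded_runs_reproducible(self):
        config = OptimizerConfig(n_particles=12, n_subpopulations=3, iterations=20, seed=5)
        a = hpso_optimize(None, F3.space, config, objective_batch=F3.evaluate_many)
        b = hpso_optimize(None, F3.space, config, objective_batch=F3.evaluate_many)
        assert np.array_equal(a.best_position, b.best_position)

    def test_trace_layout(self):
        config = OptimizerConfig(n_particles=8, n_subpopulations=2, iterations=10, seed=0)
        result = hpso_optimize(None, F1.space, config, objective_batch=F1.evaluate_many)
        assert list(result.trace.columns) == ["iteration", "inertia", "global_best_score"]
        assert len(result.trace) == 10
        assert result.trace["inertia"].iloc[0] == pytest.approx(0.98)

    @given(st.integers(0, 1000))
    def test_positions_stay_in_bounds(self, seed):
        space = SearchSpace([-2.0, -3.0], [1.0, 4.0])
        config = OptimizerConfig(n_particles=6, n_subpopulations=2, iterations=8, seed=seed)
        result = hpso_optimize(lambda x: float(np.sum(x**2)), space, config)
        assert np.all(result.best_position >= space.lower)
        assert np.all(result.best_position <= space.upper)
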