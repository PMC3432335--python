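"""Particle swarm optimization with island subpopulations and crossover.

Two optimizers over box-bounded continuous domains:

``pso_optimize``
    Classic global-best PSO with a linearly decreasing inertia weight.

``hpso_optimize``
    Hybrid PSO borrowing two ingredients from genetic algorithms: the swarm
    is partitioned into subpopulations (islands), each evolving around its
    own best attractor, and once per iteration the leaders of the two best
    islands are recombined by arithmetic crossover, the offspring replacing
    the worst member of each parent island.

Both optimizers maximize internally; a ``SearchSpace`` with
``sense="minimize"`` negates the objective at the boundary, so traces and
returned scores are always on the caller's scale.

The velocity update for particle ``i`` at iteration ``t`` is

    v[t+1] = w[t] * v[t] + c1 * r1 * (p_best - x[t]) + c2 * r2 * (g - x[t])
    x[t+1] = x[t] + v[t+1]

with ``r1, r2 ~ U(0, 1)`` drawn fresh per particle per iteration (scalar by
default, per-dimension optionally), ``g`` the attractor (the subpopulation
best for HPSO islands, the swarm best for plain PSO), and the inertia weight
``w`` decreased linearly from ``w_max`` to ``w_min`` over the run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SearchSpace",
    "OptimizerConfig",
    "Particle",
    "Subpopulation",
    "SwarmState",
    "OptimizeResult",
    "initialize_swarm",
    "pso_step",
    "update_inertia",
    "arithmetic_crossover",
    "recombine_velocities",
    "crossover_step",
    "pso_optimize",
    "hpso_optimize",
]

ObjectiveFn = Callable[[np.ndarray], float]
BatchObjectiveFn = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class SearchSpace:
    """Box-bounded search domain.

    Parameters
    ----------
    lower, upper : array-like
        Per-dimension bounds, ``lower[i] < upper[i]``.
    sense : {"minimize", "maximize"}
        Direction of optimization of the objective.
    """

    lower: np.ndarray
    upper: np.ndarray
    sense: str = "minimize"

    def __post_init__(self) -> None:
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.ndim != 1 or lower.shape != upper.shape:
            raise ValueError("lower and upper must be 1-d arrays of equal length")
        if not np.all(lower < upper):
            raise ValueError("every lower bound must lie strictly below its upper bound")
        if self.sense not in ("minimize", "maximize"):
            raise ValueError("sense must be 'minimize' or 'maximize'")

    @property
    def dimension(self) -> int:
        return self.lower.size

    @property
    def range(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass(frozen=True)
class OptimizerConfig:
    """Swarm optimizer settings.

    Defaults follow the standard protocol used throughout the package:
    56 particles, 4 subpopulations, 100 iterations, c1 = c2 = 2 and an
    inertia weight decreasing linearly from 0.98 to 0.4.
    """

    n_particles: int = 56
    n_subpopulations: int = 4
    iterations: int = 100
    c1: float = 2.0
    c2: float = 2.0
    w_min: float = 0.4
    w_max: float = 0.98
    v_max_fraction: float = 0.5
    seed: int = 0
    crossover: bool = True
    rand_per_dimension: bool = False

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be at least 2")
        if self.n_subpopulations < 1:
            raise ValueError("n_subpopulations must be at least 1")
        if self.iterations < 1:
            raise ValueError("iterations must be at least 1")
        if not (0 < self.w_min <= self.w_max):
            raise ValueError("require 0 < w_min <= w_max")
        if self.v_max_fraction <= 0:
            raise ValueError("v_max_fraction must be positive")

    def subpopulation_sizes(self) -> list[int]:
        """Partition of the swarm across islands; sizes differ by at most 1.

        Raises if any island would have fewer than 2 members.
        """
        n, k = self.n_particles, self.n_subpopulations
        base, rem = divmod(n, k)
        sizes = [base + 1 if i < rem else base for i in range(k)]
        if min(sizes) < 2:
            raise ValueError(
                f"{n} particles over {k} subpopulations leaves an island with "
                f"fewer than 2 members (sizes {sizes})"
            )
        return sizes


class Particle(NamedTuple):
    """Read-only view of one swarm member."""

    position: np.ndarray
    velocity: np.ndarray
    personal_best_position: np.ndarray
    personal_best_score: float


@dataclass
class Subpopulation:
    """One island: member arrays plus its running best.

    Scores are stored in the optimizer's internal sense (larger is better);
    callers see the objective's own scale only through the optimize results.
    """

    positions: np.ndarray  # (m, d)
    velocities: np.ndarray  # (m, d)
    pbest_positions: np.ndarray  # (m, d)
    pbest_scores: np.ndarray  # (m,)
    index: int = 0

    @property
    def size(self) -> int:
        return self.positions.shape[0]

    @property
    def best_member(self) -> int:
        return int(np.argmax(self.pbest_scores))

    @property
    def sub_best_score(self) -> float:
        return float(self.pbest_scores[self.best_member])

    @property
    def sub_best_position(self) -> np.ndarray:
        return self.pbest_positions[self.best_member].copy()

    def particles(self) -> list[Particle]:
        return [
            Particle(
                self.positions[i].copy(),
                self.velocities[i].copy(),
                self.pbest_positions[i].copy(),
                float(self.pbest_scores[i]),
            )
            for i in range(self.size)
        ]


@dataclass
class SwarmState:
    """Full optimizer state between iterations."""

    subpopulations: list[Subpopulation]
    global_best_position: np.ndarray
    global_best_score: float
    inertia: float
    iteration: int
    rng: np.random.Generator
    sense: str = "maximize"


class OptimizeResult(NamedTuple):
    """(best_position, best_score, trace) in the caller's sense.

    ``trace`` has one row per iteration with columns
    ``iteration, inertia, global_best_score``.
    """

    best_position: np.ndarray
    best_score: float
    trace: pd.DataFrame

    def save_trace(self, path) -> None:
        self.trace.to_csv(path, index=False)


def _make_evaluate(
    objective: ObjectiveFn | None,
    objective_batch: BatchObjectiveFn | None,
    sense: str,
    n_jobs: int = 1,
) -> Callable[[np.ndarray], np.ndarray]:
    """Build a (m, d) -> (m,) evaluator in the internal maximize sense."""
    sign = 1.0 if sense == "maximize" else -1.0
    if objective_batch is not None:
        def raw(X: np.ndarray) -> np.ndarray:
            return np.asarray(objective_batch(np.asarray(X, dtype=float)), dtype=float)
    elif n_jobs != 1:
        from joblib import Parallel, delayed

        parallel = Parallel(n_jobs=n_jobs, backend="threading")

        def raw(X: np.ndarray) -> np.ndarray:
            X = np.asarray(X, dtype=float)
            return np.asarray(parallel(delayed(objective)(x) for x in X), dtype=float)
    else:
        def raw(X: np.ndarray) -> np.ndarray:
            X = np.asarray(X, dtype=float)
            return np.array([objective(x) for x in X], dtype=float)

    def evaluate(X: np.ndarray) -> np.ndarray:
        values = raw(X)
        if not np.all(np.isfinite(values)):
            bad = np.asarray(X, dtype=float)[~np.isfinite(values)][0]
            raise FloatingPointError(
                f"objective returned a non-finite value at position {bad}"
            )
        return sign * values

    return evaluate


def _initialize(
    space: SearchSpace,
    config: OptimizerConfig,
    evaluate: Callable[[np.ndarray], np.ndarray],
) -> SwarmState:
    sizes = config.subpopulation_sizes()
    rng = np.random.default_rng(config.seed)
    n, d = config.n_particles, space.dimension
    positions = rng.uniform(space.lower, space.upper, size=(n, d))
    v_max = config.v_max_fraction * space.range
    velocities = rng.uniform(-v_max, v_max, size=(n, d))
    scores = evaluate(positions)

    subpopulations: list[Subpopulation] = []
    start = 0
    for k, m in enumerate(sizes):
        sl = slice(start, start + m)
        start += m
        subpopulations.append(
            Subpopulation(
                positions=positions[sl].copy(),
                velocities=velocities[sl].copy(),
                pbest_positions=positions[sl].copy(),
                pbest_scores=scores[sl].copy(),
                index=k,
            )
        )
    best = int(np.argmax(scores))
    return SwarmState(
        subpopulations=subpopulations,
        global_best_position=positions[best].copy(),
        global_best_score=float(scores[best]),
        inertia=config.w_max,
        iteration=0,
        rng=rng,
        sense=space.sense,
    )


def initialize_swarm(
    space: SearchSpace,
    config: OptimizerConfig,
    objective: ObjectiveFn,
    *,
    objective_batch: BatchObjectiveFn | None = None,
) -> SwarmState:
    """Seeded uniform initialization of positions, velocities and all bests."""
    evaluate = _make_evaluate(objective, objective_batch, space.sense)
    return _initialize(space, config, evaluate)


def _pso_step(
    state: SwarmState,
    sub: Subpopulation,
    evaluate: Callable[[np.ndarray], np.ndarray],
    space: SearchSpace,
    config: OptimizerConfig,
) -> Subpopulation:
    m = sub.size
    shape = (m, space.dimension) if config.rand_per_dimension else (m, 1)
    r1 = state.rng.uniform(size=shape)
    r2 = state.rng.uniform(size=shape)
    v_max = config.v_max_fraction * space.range
    attractor = sub.pbest_positions[sub.best_member]
    velocities = (
        state.inertia * sub.velocities
        + config.c1 * r1 * (sub.pbest_positions - sub.positions)
        + config.c2 * r2 * (attractor - sub.positions)
    )
    np.clip(velocities, -v_max, v_max, out=velocities)
    sub.velocities = velocities
    sub.positions = space.clip(sub.positions + velocities)
    scores = evaluate(sub.positions)
    improved = scores > sub.pbest_scores
    sub.pbest_positions[improved] = sub.positions[improved]
    sub.pbest_scores[improved] = scores[improved]
    return sub


def pso_step(
    state: SwarmState,
    sub: Subpopulation,
    objective: ObjectiveFn,
    space: SearchSpace,
    config: OptimizerConfig,
    *,
    objective_batch: BatchObjectiveFn | None = None,
) -> Subpopulation:
    """One velocity/position update of every particle in one island.

    The attractor is the island's own best; velocities are clamped to
    ``±v_max_fraction * range`` and positions to the bounds.
    """
    evaluate = _make_evaluate(objective, objective_batch, state.sense)
    return _pso_step(state, sub, evaluate, space, config)


def update_inertia(state: SwarmState, config: OptimizerConfig) -> SwarmState:
    """Linear inertia decrease: w += (w_min - w_max)/T, clamped to [w_min, w_max]."""
    dw = (config.w_min - config.w_max) / config.iterations
    state.inertia = float(np.clip(state.inertia + dw, config.w_min, config.w_max))
    return state


def arithmetic_crossover(
    parent_i: np.ndarray, parent_j: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Complementary convex pair: one shared uniform draw r for both offspring.

    ``x_i' = r x_i + (1-r) x_j`` and ``x_j' = r x_j + (1-r) x_i``; each
    offspring coordinate lies in the interval spanned by the parents.
    """
    xi = np.asarray(parent_i, dtype=float)
    xj = np.asarray(parent_j, dtype=float)
    if xi.shape != xj.shape:
        raise ValueError("crossover parents must have the same dimension")
    r = float(rng.uniform())
    return r * xi + (1.0 - r) * xj, r * xj + (1.0 - r) * xi


def recombine_velocities(
    v_i: np.ndarray, v_j: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Offspring keep their parent's speed but point along the summed direction.

    V = (v_i + v_j)/||v_i + v_j||; v_i' = ||v_i|| V, v_j' = ||v_j|| V.
    If the parents cancel exactly (zero summed direction) the parent
    velocities are returned unchanged.
    """
    vi = np.asarray(v_i, dtype=float)
    vj = np.asarray(v_j, dtype=float)
    if vi.shape != vj.shape:
        raise ValueError("velocities must have the same dimension")
    summed = vi + vj
    norm = float(np.linalg.norm(summed))
    if norm == 0.0:
        return vi.copy(), vj.copy()
    direction = summed / norm
    return float(np.linalg.norm(vi)) * direction, float(np.linalg.norm(vj)) * direction


def _promote(state: SwarmState) -> None:
    for sub in state.subpopulations:
        if sub.sub_best_score > state.global_best_score:
            state.global_best_score = sub.sub_best_score
            state.global_best_position = sub.sub_best_position


def _crossover_step(
    state: SwarmState,
    evaluate: Callable[[np.ndarray], np.ndarray],
    space: SearchSpace,
    config: OptimizerConfig,
) -> SwarmState:
    subs = state.subpopulations
    if len(subs) < 2:
        return state
    order = sorted(range(len(subs)), key=lambda k: subs[k].sub_best_score, reverse=True)
    first, second = subs[order[0]], subs[order[1]]

    off_i, off_j = arithmetic_crossover(
        first.sub_best_position, second.sub_best_position, state.rng
    )
    # in-bounds parents give in-bounds offspring up to float round-off
    off_i, off_j = space.clip(off_i), space.clip(off_j)
    vel_i, vel_j = recombine_velocities(
        first.velocities[first.best_member], second.velocities[second.best_member]
    )
    scores = evaluate(np.stack([off_i, off_j]))
    for sub, pos, vel, score in (
        (first, off_i, vel_i, scores[0]),
        (second, off_j, vel_j, scores[1]),
    ):
        worst = int(np.argmin(sub.pbest_scores))  # ties -> lowest member index
        sub.positions[worst] = pos
        sub.velocities[worst] = vel
        sub.pbest_positions[worst] = pos
        sub.pbest_scores[worst] = score
    _promote(state)
    return state


def crossover_step(
    state: SwarmState,
    objective: ObjectiveFn,
    space: SearchSpace,
    config: OptimizerConfig,
    *,
    objective_batch: BatchObjectiveFn | None = None,
) -> SwarmState:
    """Recombine the two best island leaders; offspring replace each island's worst.

    Silently a no-op with fewer than two islands (degenerates to multi-start
    PSO). Replaced members have their personal bests re-initialized from the
    offspring's own evaluation.
    """
    evaluate = _make_evaluate(objective, objective_batch, state.sense)
    return _crossover_step(state, evaluate, space, config)


def hpso_optimize(
    objective: ObjectiveFn | None,
    space: SearchSpace,
    config: OptimizerConfig | None = None,
    *,
    objective_batch: BatchObjectiveFn | None = None,
    n_jobs: int = 1,
) -> OptimizeResult:
    """Run the hybrid island/crossover PSO for ``config.iterations`` iterations.

    Each iteration updates every island with its own attractor, promotes
    island bests to the global best, applies one crossover event, then
    decreases the inertia weight. With one island (or ``crossover=False``)
    this reduces exactly to plain PSO under the same seed.
    """
    config = config or OptimizerConfig()
    evaluate = _make_evaluate(objective, objective_batch, space.sense, n_jobs)
    state = _initialize(space, config, evaluate)
    sign = 1.0 if space.sense == "maximize" else -1.0

    rows = []
    for t in range(config.iterations):
        for sub in state.subpopulations:
            _pso_step(state, sub, evaluate, space, config)
        _promote(state)
        if config.crossover and len(state.subpopulations) >= 2:
            _crossover_step(state, evaluate, space, config)
        rows.append((t, state.inertia, sign * state.global_best_score))
        update_inertia(state, config)
        state.iteration = t + 1

    trace = pd.DataFrame(rows, columns=["iteration", "inertia", "global_best_score"])
    return OptimizeResult(
        state.global_best_position.copy(), sign * state.global_best_score, trace
    )


def pso_optimize(
    objective: ObjectiveFn | None,
    space: SearchSpace,
    config: OptimizerConfig | None = None,
    *,
    objective_batch: BatchObjectiveFn | None = None,
    n_jobs: int = 1,
) -> OptimizeResult:
    """Plain global-best PSO (single population, no crossover).

    Kept as an independent implementation of the single-swarm update so the
    island optimizer can be cross-checked against it step for step.
    """
    config = config or OptimizerConfig()
    evaluate = _make_evaluate(objective, objective_batch, space.sense, n_jobs)
    rng = np.random.default_rng(config.seed)
    n, d = config.n_particles, space.dimension

    positions = rng.uniform(space.lower, space.upper, size=(n, d))
    v_max = config.v_max_fraction * space.range
    velocities = rng.uniform(-v_max, v_max, size=(n, d))
    scores = evaluate(positions)
    pbest_positions = positions.copy()
    pbest_scores = scores.copy()
    best = int(np.argmax(pbest_scores))
    gbest_position = pbest_positions[best].copy()
    gbest_score = float(pbest_scores[best])

    sign = 1.0 if space.sense == "maximize" else -1.0
    w = config.w_max
    dw = (config.w_min - config.w_max) / config.iterations

    rows = []
    for t in range(config.iterations):
        shape = (n, d) if config.rand_per_dimension else (n, 1)
        r1 = rng.uniform(size=shape)
        r2 = rng.uniform(size=shape)
        attractor = pbest_positions[int(np.argmax(pbest_scores))]
        velocities = (
            w * velocities
            + config.c1 * r1 * (pbest_positions - positions)
            + config.c2 * r2 * (attractor - positions)
        )
        np.clip(velocities, -v_max, v_max, out=velocities)
        positions = space.clip(positions + velocities)
        scores = evaluate(positions)
        improved = scores > pbest_scores
        pbest_positions[improved] = positions[improved]
        pbest_scores[improved] = scores[improved]
        best = int(np.argmax(pbest_scores))
        if pbest_scores[best] > gbest_score:
            gbest_score = float(pbest_scores[best])
            gbest_position = pbest_positions[best].copy()
        rows.append((t, w, sign * gbest_score))
        w = float(np.clip(w + dw, config.w_min, config.w_max))

    trace = pd.DataFrame(rows, columns=["iteration", "inertia", "global_best_score"])
    return OptimizeResult(gbest_position.copy(), sign * gbest_score, trace)
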