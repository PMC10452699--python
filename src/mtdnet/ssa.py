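"""Sparrow search algorithm (SSA), a population metaheuristic.

The population of n candidate positions in a bounded d-dimensional box is
split each iteration into three roles, ranked by fitness (minimization):

- *discoverers* (best-ranked fraction): when the random alarm value R2 is
  below the safety threshold ST, position x of the rank-i discoverer decays
  multiplicatively by exp(-i / (alpha * T)) with alpha ~ U(0, 1]; otherwise
  it takes a standard-normal random step.
- *followers* (the rest): a follower whose overall rank i exceeds n/2 is
  resampled around the worst position as Gamma * exp(x_worst - x), applied
  per dimension; otherwise it moves to the best discoverer position x_p
  plus the correction |x - x_p| . A+ with A+ = A'(AA')^-1 for a random
  +/-1 row vector A.
- *alerters* (a random 10-20% each iteration): an alerter sitting at the
  global best moves by K (x - x_worst) / (|f - f_worst| + delta) with
  K ~ U[-1, 1]; any other alerter jumps toward the best via
  x_best + beta (x - x_best), beta ~ N(0, 1).

All positions are clamped to the bounds after every update, and the
best-so-far incumbent is retained across iterations (the reported trace is
therefore non-increasing).  Used here to tune the SVM hyperparameters
(C, Gamma) in log10 space, but the optimizer is generic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

_DELTA = 1e-50  # guards the alerter update against division by zero


@dataclass(frozen=True)
class SSAConfig:
    """Population layout and iteration budget for the sparrow search."""

    bounds: np.ndarray  # d x 2 array of [low, high] per dimension
    n_sparrows: int = 20
    max_iter: int = 50
    discoverer_fraction: float = 0.2
    alerter_fraction: float = 0.15
    safety_threshold: float = 0.8
    seed: int = 0

    def __post_init__(self):
        b = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if b.ndim != 2 or b.shape[1] != 2:
            raise ValueError("bounds must be a d x 2 array of [low, high] rows")
        if not np.all(np.isfinite(b)) or np.any(b[:, 0] >= b[:, 1]):
            raise ValueError("bounds must be finite with low < high")
        object.__setattr__(self, "bounds", b)
        if self.n_sparrows < 2:
            raise ValueError("population needs at least 2 sparrows")
        if not (0.0 < self.discoverer_fraction < 1.0):
            raise ValueError("discoverer_fraction must lie in (0, 1)")
        if not (0.10 <= self.alerter_fraction <= 0.20):
            raise ValueError("alerter_fraction must lie in [0.10, 0.20]")
        if not (0.5 <= self.safety_threshold <= 1.0):
            raise ValueError("safety_threshold must lie in [0.5, 1.0]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    @property
    def dimensions(self) -> int:
        return self.bounds.shape[0]

    @property
    def n_discoverers(self) -> int:
        return max(1, int(round(self.discoverer_fraction * self.n_sparrows)))

    @property
    def n_alerters(self) -> int:
        return max(1, int(round(self.alerter_fraction * self.n_sparrows)))


@dataclass
class SSAState:
    """Mutable population snapshot between update phases."""

    positions: np.ndarray  # n x d
    fitness: np.ndarray  # length n
    best_position: np.ndarray
    best_fitness: float
    worst_position: np.ndarray
    worst_fitness: float
    iteration: int = 0

    def ranks(self) -> np.ndarray:
        """Indices sorted by fitness, best first."""
        return np.argsort(self.fitness, kind="stable")


def _clamp(x: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    return np.clip(x, bounds[:, 0], bounds[:, 1])


def ssa_step_discoverers(state: SSAState, cfg: SSAConfig, r2: float,
                         rng: np.random.Generator,
                         alphas=None, noise=None) -> np.ndarray:
    """Update the discoverer (best-ranked) positions; returns the new n x d array.

    ``alphas`` and ``noise`` may be supplied to make the update deterministic.
    """
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"alarm value R2 must lie in [0, 1], got {r2}")
    pos = state.positions.copy()
    order = state.ranks()
    nd = cfg.n_discoverers
    for rank, idx in enumerate(order[:nd], start=1):
        if r2 < cfg.safety_threshold:
            alpha = float(alphas[rank - 1]) if alphas is not None else float(rng.uniform(0.0, 1.0)) or 1.0
            pos[idx] = pos[idx] * np.exp(-rank / (alpha * cfg.max_iter))
        else:
            gamma = noise[rank - 1] if noise is not None else rng.standard_normal(cfg.dimensions)
            pos[idx] = pos[idx] + gamma
    return _clamp(pos, cfg.bounds)


def ssa_step_followers(state: SSAState, cfg: SSAConfig, rng: np.random.Generator,
                       best_discoverer: np.ndarray | None = None) -> np.ndarray:
    """Update the follower (non-discoverer) positions; returns the new n x d array.

    ``best_discoverer`` is the producer position x_p the well-fed followers
    move toward; defaults to the current best position.
    """
    pos = state.positions.copy()
    order = state.ranks()
    n = cfg.n_sparrows
    xp = state.best_position if best_discoverer is None else np.asarray(best_discoverer)
    xw = state.worst_position
    for rank, idx in enumerate(order[cfg.n_discoverers:], start=cfg.n_discoverers + 1):
        if rank > n / 2:
            gamma = rng.standard_normal(cfg.dimensions)
            pos[idx] = gamma * np.exp(xw - pos[idx])
        else:
            signs = rng.choice((-1.0, 1.0), size=cfg.dimensions)
            pos[idx] = xp + np.abs(pos[idx] - xp) * signs / cfg.dimensions
    return _clamp(pos, cfg.bounds)


def ssa_step_alerters(state: SSAState, cfg: SSAConfig, rng: np.random.Generator,
                      indices=None, betas=None, ks=None) -> np.ndarray:
    """Update a randomly chosen alerter subset; returns the new n x d array."""
    pos = state.positions.copy()
    if indices is None:
        indices = rng.choice(cfg.n_sparrows, size=cfg.n_alerters, replace=False)
    for j, idx in enumerate(np.asarray(indices, dtype=int)):
        fi = state.fitness[idx]
        if fi != state.best_fitness:
            beta = float(betas[j]) if betas is not None else float(rng.standard_normal())
            pos[idx] = state.best_position + beta * (pos[idx] - state.best_position)
        else:
            k = float(ks[j]) if ks is not None else float(rng.uniform(-1.0, 1.0))
            denom = abs(fi - state.worst_fitness) + _DELTA
            pos[idx] = pos[idx] + k * (pos[idx] - state.worst_position) / denom
    return _clamp(pos, cfg.bounds)


@dataclass
class SSAResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness after initialization and each iteration
    n_evaluations: int


def _evaluate(fitness: Callable, positions: np.ndarray) -> np.ndarray:
    vals = np.array([float(fitness(p)) for p in positions])
    if not np.all(np.isfinite(vals)):
        bad = positions[int(np.flatnonzero(~np.isfinite(vals))[0])]
        raise ValueError(f"fitness is not finite at position {bad}")
    return vals


def ssa_optimize(fitness: Callable, cfg: SSAConfig) -> SSAResult:
    """Minimize ``fitness`` over the bounded box with the sparrow search.

    Fully reproducible for a fixed ``cfg.seed``.  The incumbent best is kept
    outside the population, so the reported trace never increases.
    """
    rng = np.random.default_rng(cfg.seed)
    span = cfg.bounds[:, 1] - cfg.bounds[:, 0]
    positions = cfg.bounds[:, 0] + rng.random((cfg.n_sparrows, cfg.dimensions)) * span
    fit = _evaluate(fitness, positions)
    n_eval = cfg.n_sparrows

    best_i, worst_i = int(np.argmin(fit)), int(np.argmax(fit))
    incumbent_x = positions[best_i].copy()
    incumbent_f = float(fit[best_i])
    state = SSAState(positions=positions, fitness=fit,
                     best_position=positions[best_i].copy(), best_fitness=float(fit[best_i]),
                     worst_position=positions[worst_i].copy(), worst_fitness=float(fit[worst_i]))
    trace = [incumbent_f]

    for t in range(1, cfg.max_iter + 1):
        r2 = float(rng.random())
        order = state.ranks()
        state.positions = ssa_step_discoverers(state, cfg, r2, rng)
        # producer position: the updated location of the previously best-ranked discoverer
        xp = state.positions[order[0]].copy()
        state.positions = ssa_step_followers(state, cfg, rng, best_discoverer=xp)
        state.positions = ssa_step_alerters(state, cfg, rng)

        state.fitness = _evaluate(fitness, state.positions)
        n_eval += cfg.n_sparrows
        best_i, worst_i = int(np.argmin(state.fitness)), int(np.argmax(state.fitness))
        state.best_position = state.positions[best_i].copy()
        state.best_fitness = float(state.fitness[best_i])
        state.worst_position = state.positions[worst_i].copy()
        state.worst_fitness = float(state.fitness[worst_i])
        state.iteration = t
        if state.best_fitness < incumbent_f:
            incumbent_f = state.best_fitness
            incumbent_x = state.best_position.copy()
        trace.append(incumbent_f)

    return SSAResult(best_position=incumbent_x, best_fitness=incumbent_f,
                     trace=np.asarray(trace), n_evaluations=n_eval)


def random_search(fitness: Callable, cfg: SSAConfig, n_evaluations: int) -> SSAResult:
    """Uniform random search baseline at a matched evaluation budget."""
    rng = np.random.default_rng(cfg.seed)
    span = cfg.bounds[:, 1] - cfg.bounds[:, 0]
    positions = cfg.bounds[:, 0] + rng.random((n_evaluations, cfg.dimensions)) * span
    vals = _evaluate(fitness, positions)
    trace = np.minimum.accumulate(vals)
    best = int(np.argmin(vals))
    return SSAResult(best_position=positions[best], best_fitness=float(vals[best]),
                     trace=trace, n_evaluations=n_evaluations)
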