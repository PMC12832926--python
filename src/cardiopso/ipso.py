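"""Improved particle swarm optimization (IPSO).

A maximizing PSO engine over the unit hypercube ``[0, 1]^D`` with two
anti-stagnation improvements over the textbook algorithm:

* **dynamic inertia** — the inertia weight decreases linearly from
  ``w_max`` to ``w_min`` over the run, trading early exploration for
  late exploitation;
* **Gaussian mutation** — after each position update, with probability
  ``p_mutation`` per particle per iteration, every coordinate receives
  an independent ``Normal(0, sigma)`` perturbation, letting particles
  escape local optima.

Setting ``p_mutation = 0`` and ``w_max = w_min`` degrades the engine to
standard PSO, which is exactly the ablation baseline
(:func:`SwarmConfig.standard_pso`).

The engine works in normalized coordinates: every dimension spans
``[0, 1]``, so a single ``sigma`` and velocity clamp apply uniformly to
heterogeneous search spaces.  Decoding to native parameter ranges is the
caller's job (see :mod:`cardiopso.search`).

Velocity update for particle *i* in dimension *d*::

    v <- w(t) * v + c1 * r1 * (pbest - x) + c2 * r2 * (gbest - x)
    x <- clip(x + v, 0, 1)

with ``r1, r2 ~ Uniform(0, 1)`` drawn independently per dimension.
Personal/global bests update asynchronously within a sweep: a particle
evaluated later in the iteration sees any gbest improvement made
earlier in the same iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .exceptions import DomainError, FitnessEvaluationError

__all__ = [
    "SwarmConfig",
    "Particle",
    "SwarmState",
    "inertia_at",
    "step_velocity",
    "step_position",
    "gaussian_mutation",
    "optimize",
]


@dataclass(frozen=True)
class SwarmConfig:
    """Control parameters of the swarm.

    Defaults are the settings used across all experiments: 50 particles,
    100 iterations, c1 = c2 = 2.0, inertia from 0.9 down to 0.4,
    mutation probability 0.1 with sigma 0.1.
    """

    n_particles: int = 50
    max_iterations: int = 100
    c1: float = 2.0
    c2: float = 2.0
    w_max: float = 0.9
    w_min: float = 0.4
    p_mutation: float = 0.1
    sigma: float = 0.1
    v_max_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise DomainError("n_particles must be >= 2")
        if self.max_iterations < 1:
            raise DomainError("max_iterations must be >= 1")
        if not (0 < self.w_min <= self.w_max):
            raise DomainError("need 0 < w_min <= w_max")
        if not (0 <= self.p_mutation <= 1):
            raise DomainError("p_mutation must be in [0, 1]")
        if self.sigma < 0:
            raise DomainError("sigma must be >= 0")
        if not (0 < self.v_max_fraction <= 1):
            raise DomainError("v_max_fraction must be in (0, 1]")

    @classmethod
    def standard_pso(cls, w: float = 0.9, **kwargs) -> "SwarmConfig":
        """Degenerate configuration: fixed inertia, no mutation — the
        textbook PSO used as the ablation's non-improved arm.

        The default fixed inertia is 0.9, the classic constant-inertia
        setting that linearly decreasing schedules were introduced to
        improve upon (the dynamic schedule replaces exactly this fixed
        value with a decay from ``w_max`` to ``w_min``)."""
        kwargs.setdefault("w_max", w)
        kwargs.setdefault("w_min", w)
        kwargs.setdefault("p_mutation", 0.0)
        return cls(**kwargs)


@dataclass
class Particle:
    """Per-particle state in normalized coordinates."""

    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class SwarmState:
    """Final (or in-progress) swarm state.

    ``history[k]`` is the global-best fitness after the initial sweep
    (k = 0) and after each subsequent iteration; it is non-decreasing.
    ``n_evaluations`` counts fitness calls:
    ``n_particles * (max_iterations + 1)`` for a completed run.
    """

    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_fitness: float
    iteration: int
    history: list[float] = field(default_factory=list)
    n_evaluations: int = 0


def inertia_at(config: SwarmConfig, iteration: int) -> float:
    """Linearly decaying inertia weight:
    ``w_max - (w_max - w_min) * iteration / max_iterations``."""
    if not (0 <= iteration <= config.max_iterations):
        raise DomainError(
            f"iteration {iteration} outside [0, {config.max_iterations}]"
        )
    return config.w_max - (config.w_max - config.w_min) * iteration / config.max_iterations


def step_velocity(
    position: np.ndarray,
    velocity: np.ndarray,
    pbest_position: np.ndarray,
    gbest_position: np.ndarray,
    w: float,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One velocity update with fresh per-dimension uniform draws,
    clamped elementwise to ``±v_max_fraction`` (dimensions are unit
    ranged, so the clamp is the fraction itself)."""
    d = position.shape[0]
    r1 = rng.uniform(size=d)
    r2 = rng.uniform(size=d)
    v = (
        w * velocity
        + config.c1 * r1 * (pbest_position - position)
        + config.c2 * r2 * (gbest_position - position)
    )
    return np.clip(v, -config.v_max_fraction, config.v_max_fraction)


def step_position(position: np.ndarray, velocity: np.ndarray) -> np.ndarray:
    """``x <- clip(x + v, 0, 1)``."""
    return np.clip(position + velocity, 0.0, 1.0)


def gaussian_mutation(
    position: np.ndarray, config: SwarmConfig, rng: np.random.Generator
) -> np.ndarray:
    """With probability ``p_mutation`` (one Bernoulli draw per call),
    perturb every coordinate by i.i.d. ``Normal(0, sigma)`` and clip to
    the unit box; otherwise return the position unchanged."""
    if config.p_mutation > 0 and rng.uniform() < config.p_mutation:
        return np.clip(position + rng.normal(0.0, config.sigma, size=position.shape), 0.0, 1.0)
    return position.copy()


def _n_dims(space) -> int:
    if isinstance(space, (int, np.integer)):
        return int(space)
    return int(space.n_dims)


def optimize(
    space,
    fitness: Callable[[np.ndarray], float],
    config: SwarmConfig,
) -> SwarmState:
    """Maximize ``fitness`` over the unit hypercube.

    Parameters
    ----------
    space
        Dimension count, or any object exposing ``n_dims`` (e.g. a
        :class:`cardiopso.search.SearchSpace`).
    fitness
        Callable mapping a normalized position vector to a real score;
        must be deterministic given the position.  An exception inside
        it aborts the run with the offending position attached
        (:class:`FitnessEvaluationError`).
    config
        Swarm control parameters; ``config.seed`` makes the run fully
        reproducible.

    The schedule per iteration is: inertia update, then per particle —
    velocity update, position update, optional mutation, evaluation,
    pbest/gbest update (asynchronous: improvements are visible to later
    particles in the same sweep).  Ties in gbest keep the first-found
    position.
    """
    d = _n_dims(space)
    if d < 1:
        raise DomainError("search space must have at least one dimension")
    rng = np.random.default_rng(config.seed)

    def evaluate(x: np.ndarray) -> float:
        try:
            return float(fitness(x))
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise FitnessEvaluationError(x, exc) from exc

    particles: list[Particle] = []
    gbest_position: np.ndarray | None = None
    gbest_fitness = -np.inf
    n_evaluations = 0
    for _ in range(config.n_particles):
        x = rng.uniform(size=d)
        v = rng.uniform(-config.v_max_fraction, config.v_max_fraction, size=d)
        f = evaluate(x)
        n_evaluations += 1
        particles.append(Particle(position=x, velocity=v, pbest_position=x.copy(), pbest_fitness=f))
        if f > gbest_fitness:
            gbest_fitness = f
            gbest_position = x.copy()

    history = [gbest_fitness]
    for it in range(1, config.max_iterations + 1):
        w = inertia_at(config, it)
        for p in particles:
            p.velocity = step_velocity(
                p.position, p.velocity, p.pbest_position, gbest_position, w, config, rng
            )
            p.position = step_position(p.position, p.velocity)
            p.position = gaussian_mutation(p.position, config, rng)
            f = evaluate(p.position)
            n_evaluations += 1
            if f > p.pbest_fitness:
                p.pbest_fitness = f
                p.pbest_position = p.position.copy()
            if f > gbest_fitness:
                gbest_fitness = f
                gbest_position = p.position.copy()
        history.append(gbest_fitness)

    return SwarmState(
        particles=particles,
        gbest_position=gbest_position,
        gbest_fitness=gbest_fitness,
        iteration=config.max_iterations,
        history=history,
        n_evaluations=n_evaluations,
    )
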