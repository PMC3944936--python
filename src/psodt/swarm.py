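"""Binary particle swarm optimizer over gene-inclusion bit vectors.

Each particle carries a binary position (bit d = 1 means gene d is in the
candidate subset) and a real velocity clamped to ``[vmin, vmax]``.  The
velocity follows the canonical global-best rule

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)

with fresh U(0,1) draws r1, r2 per dimension, and the position is
re-sampled stochastically through a sigmoid: bit d becomes 1 when
``sigmoid(v_d) > U(0,1)``.  Initial bits are 1 when ``U(0,1) > 1 - p``
with p = ``init_one_prob`` (0.5 by default); velocities start at zero.

Defaults follow the usual gene-selection setting for this optimizer:
inertia weight 0.4, acceleration constants c1 = c2 = 2, velocity bounds
-4 and 4, at most 100 iterations with early stop once the best fitness
reaches 1.0, and a swarm of roughly one particle per hundred genes.

Personal/global bests update only on strict improvement, and ties among
particles improving in the same sweep go to the lowest particle index, so
a run is fully determined by (seed, parameters, fitness function).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np

__all__ = [
    "PSOParams",
    "Particle",
    "SwarmState",
    "sigmoid",
    "default_n_particles",
    "init_swarm",
    "update_velocity",
    "update_position",
    "step",
    "run",
]


@dataclass(frozen=True)
class PSOParams:
    w: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    vmin: float = -4.0
    vmax: float = 4.0
    T: int = 100
    n_particles: Optional[int] = None  # None -> max(2, round(n_genes/100))
    init_one_prob: float = 0.5
    target_fitness: float = 1.0

    def __post_init__(self) -> None:
        if not self.vmin < self.vmax:
            raise ValueError("vmin must be < vmax")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.n_particles is not None and self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if not 0.0 <= self.init_one_prob <= 1.0:
            raise ValueError("init_one_prob must be in [0, 1]")


@dataclass
class Particle:
    position: np.ndarray  # binary, length n
    velocity: np.ndarray  # real, length n, within [vmin, vmax]
    pbest_position: Optional[np.ndarray] = None
    pbest_fitness: Optional[float] = None


@dataclass
class SwarmState:
    particles: List[Particle]
    gbest_position: Optional[np.ndarray] = None
    gbest_fitness: float = -np.inf
    iteration: int = 0
    history: List[float] = field(default_factory=list)


def sigmoid(v):
    """Logistic squashing 1/(1+exp(-v)), numerically stable for large |v|."""
    v = np.asarray(v, dtype=float)
    out = np.empty_like(v)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    ev = np.exp(v[~pos])
    out[~pos] = ev / (1.0 + ev)
    return out if out.ndim else float(out)


def default_n_particles(n_genes: int) -> int:
    """Swarm size of about one particle per hundred genes, at least two."""
    return max(2, int(round(n_genes / 100)))


def _resolve_n_particles(n_genes: int, params: PSOParams) -> int:
    return params.n_particles if params.n_particles is not None else default_n_particles(n_genes)


def init_swarm(n_genes: int, params: PSOParams, rng) -> SwarmState:
    """Random initial swarm: bit = 1 iff U(0,1) > 1 - init_one_prob,
    velocities zero, bests unset."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    n_particles = _resolve_n_particles(n_genes, params)
    particles = []
    for _ in range(n_particles):
        u = np.asarray(rng.random(n_genes))
        position = (u > 1.0 - params.init_one_prob).astype(np.int8)
        particles.append(Particle(position=position, velocity=np.zeros(n_genes)))
    return SwarmState(particles=particles)


def update_velocity(
    particle: Particle, gbest_position: np.ndarray, params: PSOParams, rng
) -> np.ndarray:
    """Canonical velocity update with per-dimension r1, r2 and clamping."""
    if particle.pbest_position is None:
        raise ValueError("particle has no personal best yet; evaluate first")
    n = particle.position.size
    r1 = np.asarray(rng.random(n))
    r2 = np.asarray(rng.random(n))
    x = particle.position.astype(float)
    v = (
        params.w * particle.velocity
        + params.c1 * r1 * (particle.pbest_position.astype(float) - x)
        + params.c2 * r2 * (np.asarray(gbest_position, dtype=float) - x)
    )
    return np.clip(v, params.vmin, params.vmax)


def update_position(particle: Particle, rng) -> np.ndarray:
    """Stochastic bit update: bit = 1 iff sigmoid(v) > U(0,1)."""
    u = np.asarray(rng.random(particle.position.size))
    return (sigmoid(particle.velocity) > u).astype(np.int8)


def step(
    swarm: SwarmState,
    fitness_fn: Callable[[np.ndarray], float],
    params: PSOParams,
    rng,
) -> SwarmState:
    """One iteration: evaluate every particle, update bests, then move.

    Bests advance only on strict improvement; among particles improving
    in the same sweep the lowest index wins the global best.  The swarm is
    modified in place and returned; the global-best fitness is appended to
    the history, which is therefore non-decreasing.
    """
    for particle in swarm.particles:
        f = float(fitness_fn(particle.position))
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fitness {f} outside [0, 1]")
        if particle.pbest_fitness is None or f > particle.pbest_fitness:
            particle.pbest_fitness = f
            particle.pbest_position = particle.position.copy()
        if f > swarm.gbest_fitness:
            swarm.gbest_fitness = f
            swarm.gbest_position = particle.position.copy()
    for particle in swarm.particles:
        particle.velocity = update_velocity(
            particle, swarm.gbest_position, params, rng
        )
        particle.position = update_position(particle, rng)
    swarm.iteration += 1
    swarm.history.append(swarm.gbest_fitness)
    return swarm


def run(
    fitness_fn: Callable[[np.ndarray], float],
    n_genes: int,
    params: PSOParams,
    rng,
):
    """Full optimization: iterate :func:`step` until the best fitness
    reaches ``target_fitness`` or ``T`` iterations elapse.

    Returns
    -------
    (gbest_position, gbest_fitness, history)
        Best bit vector found, its fitness, and the per-iteration trace
        of the global best.
    """
    swarm = init_swarm(n_genes, params, rng)
    for _ in range(params.T):
        step(swarm, fitness_fn, params, rng)
        if swarm.gbest_fitness >= params.target_fitness:
            break
    return swarm.gbest_position.copy(), float(swarm.gbest_fitness), list(swarm.history)
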