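"""Speed-constrained multi-objective particle swarm optimization (SMPSO).

Storage-condition optimization maximizes the four predicted quality
responses (hardness, SSC, TA, Vc) simultaneously over the box of feasible
conditions.  SMPSO is a multi-objective PSO variant that prevents "swarm
explosion" with a constriction-factor velocity limit and keeps a bounded
external archive of non-dominated solutions pruned by crowding distance.
Leaders are drawn from the archive by binary crowding tournament and a
polynomial mutation perturbs a fraction of the swarm each generation.

A single compromise solution is picked from the final archive as the member
closest (Euclidean) to the ideal point after min–max normalization of each
objective across the archive.  Fixed-storage-time scenario queries freeze
the time variable and optimize over temperature and maturity only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .design import FactorSpace, _dominates, crowding_distance, wolfberry_space

__all__ = [
    "MOOProblem",
    "SMPSOConfig",
    "ParetoArchive",
    "constriction_factor",
    "update_particle",
    "archive_insert",
    "run_smpso",
    "select_optimal",
    "scenario_query",
]


@dataclass(frozen=True)
class MOOProblem:
    """Maximization of predicted qualities over normalized storage conditions.

    ``evaluate`` maps a normalized point in [0, 1]^d (free variables only)
    to the objective vector, all maximized.  ``frozen`` holds factor name ->
    raw value for variables held fixed during scenario queries.
    """

    evaluate: Callable[[np.ndarray], np.ndarray]
    space: FactorSpace = field(default_factory=wolfberry_space)
    frozen: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        by_name = {f.name: f for f in self.space.factors}
        for name, value in self.frozen.items():
            f = by_name.get(name)
            if f is None:
                raise ValueError(f"unknown frozen factor {name!r}")
            if not f.lower <= value <= f.upper:
                raise ValueError(
                    f"frozen value {value} for {name!r} outside [{f.lower}, {f.upper}]"
                )

    @property
    def free_factors(self) -> list:
        return [f for f in self.space.factors if f.name not in self.frozen]

    @property
    def dimension(self) -> int:
        return len(self.free_factors)


@dataclass(frozen=True)
class SMPSOConfig:
    """SMPSO parameters (swarm of 12 over 50 generations by default)."""

    swarm_size: int = 12
    generations: int = 50
    archive_capacity: int = 100
    c1_range: tuple[float, float] = (1.5, 2.5)
    c2_range: tuple[float, float] = (1.5, 2.5)
    mutation_prob: float = 0.15
    mutation_distribution_index: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.swarm_size, self.generations, self.archive_capacity) < 1:
            raise ValueError("sizes must be positive")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation probability must lie in [0, 1]")


def constriction_factor(c1: float, c2: float) -> float:
    """Velocity constriction coefficient from the learning factors."""
    if c1 < 0 or c2 < 0:
        raise ValueError("learning factors must be non-negative")
    phi = c1 + c2
    if phi <= 4.0:
        return 1.0
    return 2.0 / abs(2.0 - phi - math.sqrt(phi**2 - 4.0 * phi))


@dataclass
class _Particle:
    position: np.ndarray
    velocity: np.ndarray
    objectives: np.ndarray
    pbest_position: np.ndarray
    pbest_objectives: np.ndarray


def update_particle(
    position: np.ndarray,
    velocity: np.ndarray,
    pbest: np.ndarray,
    guide: np.ndarray,
    c1: float,
    c2: float,
    r1: float,
    r2: float,
    lower: np.ndarray,
    upper: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One constricted, velocity-clamped PSO move with bound handling.

    The velocity is clamped componentwise to half the variable range; a
    particle hitting a bound is clamped there with its velocity component
    sign-reversed.
    """
    chi = constriction_factor(c1, c2)
    v = chi * (velocity + c1 * r1 * (pbest - position) + c2 * r2 * (guide - position))
    delta = (upper - lower) / 2.0
    v = np.clip(v, -delta, delta)
    x = position + v
    low_hit = x < lower
    high_hit = x > upper
    x = np.clip(x, lower, upper)
    v = np.where(low_hit | high_hit, -v, v)
    return x, v


def _polynomial_mutation(
    x: np.ndarray, lower: np.ndarray, upper: np.ndarray, eta: float, rng
) -> np.ndarray:
    out = x.copy()
    for j in range(x.size):
        span = upper[j] - lower[j]
        if span <= 0:
            continue
        u = rng.random()
        if u < 0.5:
            delta = (2.0 * u) ** (1.0 / (eta + 1.0)) - 1.0
        else:
            delta = 1.0 - (2.0 * (1.0 - u)) ** (1.0 / (eta + 1.0))
        out[j] = np.clip(out[j] + delta * span, lower[j], upper[j])
    return out


# ---------------------------------------------------------------------------
# archive


@dataclass
class ParetoArchive:
    """Bounded archive of mutually non-dominated solutions."""

    capacity: int = 100
    positions: list = field(default_factory=list)
    objectives: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.positions)

    @property
    def crowding(self) -> np.ndarray:
        if self.size == 0:
            return np.empty(0)
        return crowding_distance(np.array(self.objectives))


def archive_insert(archive: ParetoArchive, position: np.ndarray, objectives: np.ndarray) -> bool:
    """Insert a candidate, keeping the archive non-dominated and bounded.

    Dominated candidates are rejected; members the candidate dominates are
    dropped; over capacity, the most crowded member (smallest crowding
    distance) is evicted.  Returns whether the candidate was kept.
    """
    objectives = np.asarray(objectives, dtype=float)
    if np.any(~np.isfinite(objectives)):
        raise ValueError(f"non-finite objectives {objectives} at {position}")
    for obj in archive.objectives:
        if _dominates(obj, objectives) or np.array_equal(obj, objectives):
            return False
    keep = [
        i for i, obj in enumerate(archive.objectives) if not _dominates(objectives, obj)
    ]
    archive.positions = [archive.positions[i] for i in keep]
    archive.objectives = [archive.objectives[i] for i in keep]
    archive.positions.append(np.asarray(position, dtype=float).copy())
    archive.objectives.append(objectives.copy())
    if archive.size > archive.capacity:
        worst = int(np.argmin(archive.crowding))
        archive.positions.pop(worst)
        archive.objectives.pop(worst)
    return True


def _select_leader(archive: ParetoArchive, rng) -> np.ndarray:
    if archive.size == 1:
        return archive.positions[0]
    crowd = archive.crowding
    i, j = rng.integers(archive.size, size=2)
    return archive.positions[i] if crowd[i] >= crowd[j] else archive.positions[j]


# ---------------------------------------------------------------------------
# main loop


def _evaluate(problem: MOOProblem, x: np.ndarray) -> np.ndarray:
    obj = np.atleast_1d(np.asarray(problem.evaluate(x), dtype=float))
    if np.any(~np.isfinite(obj)):
        raise ValueError(f"non-finite objective value {obj} at point {x}")
    return obj


def run_smpso(problem: MOOProblem, config: SMPSOConfig = SMPSOConfig()) -> ParetoArchive:
    """Run SMPSO on the (possibly frozen-reduced) normalized box."""
    d = problem.dimension
    rng = np.random.default_rng(config.seed)
    lower, upper = np.zeros(d), np.ones(d)
    archive = ParetoArchive(capacity=config.archive_capacity)
    swarm = []
    for _ in range(config.swarm_size):
        x = rng.random(d)
        obj = _evaluate(problem, x)
        swarm.append(_Particle(x, np.zeros(d), obj, x.copy(), obj.copy()))
        archive_insert(archive, x, obj)
    for _ in range(config.generations):
        for particle in swarm:
            guide = _select_leader(archive, rng)
            c1 = rng.uniform(*config.c1_range)
            c2 = rng.uniform(*config.c2_range)
            r1, r2 = rng.random(), rng.random()
            x, v = update_particle(
                particle.position,
                particle.velocity,
                particle.pbest_position,
                guide,
                c1,
                c2,
                r1,
                r2,
                lower,
                upper,
            )
            if rng.random() < config.mutation_prob:
                x = _polynomial_mutation(
                    x, lower, upper, config.mutation_distribution_index, rng
                )
            obj = _evaluate(problem, x)
            particle.position, particle.velocity, particle.objectives = x, v, obj
            # personal best: replace unless the old best dominates the new point
            if not _dominates(particle.pbest_objectives, obj):
                particle.pbest_position = x.copy()
                particle.pbest_objectives = obj.copy()
            archive_insert(archive, x, obj)
    return archive


def select_optimal(archive: ParetoArchive) -> tuple[np.ndarray, np.ndarray]:
    """Compromise member closest to the ideal point.

    Objectives are min–max normalized across the archive; the member with
    the smallest Euclidean distance to the normalized ideal (all ones) wins.
    Ties break by larger crowding distance, then by lower index.
    """
    if archive.size == 0:
        raise ValueError("archive is empty")
    F = np.array(archive.objectives)
    span = F.max(axis=0) - F.min(axis=0)
    span[span == 0] = 1.0
    normalized = (F - F.min(axis=0)) / span
    dist = np.linalg.norm(1.0 - normalized, axis=1)
    crowd = archive.crowding
    best = min(range(archive.size), key=lambda i: (dist[i], -crowd[i], i))
    return archive.positions[best], archive.objectives[best]


def scenario_query(
    problem: MOOProblem,
    frozen_time_days: float,
    config: SMPSOConfig = SMPSOConfig(),
) -> tuple[dict, np.ndarray]:
    """Optimal storage conditions for a fixed storage time.

    Freezes the time factor at ``frozen_time_days`` (raw units), optimizes
    over the remaining factors and returns the selected compromise solution
    denormalized to raw units along with its predicted quality vector.
    """
    space = problem.space
    by_name = {f.name: f for f in space.factors}
    time_factor = by_name["time"]
    if not time_factor.lower <= frozen_time_days <= time_factor.upper:
        raise ValueError(
            f"storage time {frozen_time_days} outside "
            f"[{time_factor.lower}, {time_factor.upper}] days"
        )
    time_unit = (frozen_time_days - time_factor.lower) / time_factor.width
    free = [f for f in space.factors if f.name != "time"]

    def embed(z: np.ndarray) -> np.ndarray:
        full = np.empty(space.dimension)
        k = 0
        for j, f in enumerate(space.factors):
            if f.name == "time":
                full[j] = time_unit
            else:
                full[j] = z[k]
                k += 1
        return full

    sub = MOOProblem(
        evaluate=lambda z: problem.evaluate(embed(z)),
        space=FactorSpace(tuple(free)),
        frozen={},
    )
    archive = run_smpso(sub, config)
    z_best, objectives = select_optimal(archive)
    full_unit = embed(z_best)
    raw = space.lower + full_unit * (space.upper - space.lower)
    conditions = {f.name: float(v) for f, v in zip(space.factors, raw)}
    return conditions, objectives
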