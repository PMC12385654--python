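"""Factor-space handling and space-filling experimental design.

The storage experiment varies three factors — storage temperature, storage
time and initial (harvest) maturity — over fixed physical ranges.  All
modelling happens on the unit cube: raw factor settings are min–max
normalized, ``x = (x_i - x_imin) / (x_imax - x_imin)``, and designs are
Latin hypercubes: for ``n`` runs each factor's column places exactly one
value in each of the ``n`` equal-width bins of [0, 1].

Plain (random) Latin hypercubes are improved by a small multi-objective
evolutionary algorithm that mixes LHS-based local search with classical
selection / crossover / mutation.  Design quality is scored by two standard
space-filling criteria: the maximin (minimum pairwise Euclidean) distance,
maximized, and the centered L2 discrepancy, minimized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import qmc

__all__ = [
    "Factor",
    "FactorSpace",
    "DesignMatrix",
    "MOEAConfig",
    "UniformityReport",
    "Problem",
    "wolfberry_space",
    "normalize_point",
    "denormalize_point",
    "required_sample_size",
    "random_lhs",
    "lhs_neighborhood_search",
    "nondominated_rank",
    "crowding_distance",
    "run_lhs_moea",
    "optimize_design",
    "uniformity_report",
]


# ---------------------------------------------------------------------------
# factor space


@dataclass(frozen=True)
class Factor:
    """One experimental factor with its physical range."""

    name: str
    unit: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"factor {self.name!r}: lower bound {self.lower} must be "
                f"strictly below upper bound {self.upper}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class FactorSpace:
    """Ordered collection of factors spanning the design space."""

    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        if len(self.factors) < 1:
            raise ValueError("a factor space needs at least one factor")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError(f"factor names must be unique, got {names}")

    @property
    def dimension(self) -> int:
        return len(self.factors)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def lower(self) -> np.ndarray:
        return np.array([f.lower for f in self.factors], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([f.upper for f in self.factors], dtype=float)


def wolfberry_space() -> FactorSpace:
    """The storage factor space: temperature, time and initial maturity.

    Ranges are the studied ones: −4–24 °C, 0–28 days, 20–90 % maturity.
    """
    return FactorSpace(
        (
            Factor("temperature", "degC", -4.0, 24.0),
            Factor("time", "day", 0.0, 28.0),
            Factor("maturity", "%", 20.0, 90.0),
        )
    )


def normalize_point(raw: Sequence[float], space: FactorSpace) -> np.ndarray:
    """Map a raw factor setting into the unit cube (min–max scaling)."""
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (space.dimension,):
        raise ValueError(f"expected {space.dimension} components, got {raw.shape}")
    for value, factor in zip(raw, space.factors):
        if not factor.lower <= value <= factor.upper:
            raise ValueError(
                f"factor {factor.name!r}: value {value} outside "
                f"[{factor.lower}, {factor.upper}] {factor.unit}"
            )
    return (raw - space.lower) / (space.upper - space.lower)


def denormalize_point(unit: Sequence[float], space: FactorSpace) -> np.ndarray:
    """Inverse of :func:`normalize_point`."""
    unit = np.asarray(unit, dtype=float)
    if unit.shape != (space.dimension,):
        raise ValueError(f"expected {space.dimension} components, got {unit.shape}")
    if np.any(unit < 0.0) or np.any(unit > 1.0):
        raise ValueError(f"normalized components must lie in [0, 1], got {unit}")
    return space.lower + unit * (space.upper - space.lower)


def required_sample_size(n_factors: int) -> int:
    """Design size rule ``n = 2 (N + 1)(N + 2)`` for ``N`` factors.

    For the three storage factors this yields the 40-run design used
    throughout the analysis.
    """
    if int(n_factors) != n_factors or n_factors < 1:
        raise ValueError(f"number of factors must be a positive integer, got {n_factors}")
    n_factors = int(n_factors)
    return 2 * (n_factors + 1) * (n_factors + 2)


# ---------------------------------------------------------------------------
# Latin hypercube designs


def _latin_bins(column: np.ndarray, n: int) -> np.ndarray:
    """Bin index of each value in an n-bin stratification of [0, 1]."""
    return np.minimum((column * n).astype(int), n - 1)


@dataclass(frozen=True)
class DesignMatrix:
    """``n`` design points in the ``d``-dimensional unit cube."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2:
            raise ValueError("design points must form an n x d matrix")
        if np.any(~np.isfinite(pts)) or np.any(pts < 0.0) or np.any(pts > 1.0):
            raise ValueError("design points must be finite and lie in [0, 1]")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]

    def is_latin(self) -> bool:
        """Exact stratification check: one point per bin in every column."""
        for j in range(self.d):
            bins = _latin_bins(self.points[:, j], self.n)
            if not np.array_equal(np.sort(bins), np.arange(self.n)):
                return False
        return True

    def denormalize(self, space: FactorSpace) -> np.ndarray:
        return space.lower + self.points * (space.upper - space.lower)


def random_lhs(n: int, d: int, seed: int | np.random.Generator) -> DesignMatrix:
    """Plain stratified-random Latin hypercube with in-bin jitter."""
    if n < 1 or d < 1:
        raise ValueError("n and d must be >= 1")
    rng = np.random.default_rng(seed)
    bins = np.column_stack([rng.permutation(n) for _ in range(d)])
    jitter = rng.random((n, d))
    return DesignMatrix((bins + jitter) / n)


def lhs_neighborhood_search(
    center: Sequence[float],
    radius: float,
    count: int,
    seed: int | np.random.Generator,
) -> list[np.ndarray]:
    """Latin-hypercube sample inside the box around ``center``.

    The sampling box ``[center - radius, center + radius]^d`` is clipped to
    the unit cube, so near a boundary the points simply fill the truncated
    box.
    """
    center = np.asarray(center, dtype=float)
    if np.any(center < 0.0) or np.any(center > 1.0):
        raise ValueError("center must lie in the unit cube")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    lo = np.clip(center - radius, 0.0, 1.0)
    hi = np.clip(center + radius, 0.0, 1.0)
    unit = random_lhs(count, center.size, rng).points
    return list(lo + unit * (hi - lo))


# ---------------------------------------------------------------------------
# non-dominated sorting and crowding


def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """Pareto dominance with all objectives maximized."""
    return bool(np.all(a >= b) and np.any(a > b))


def nondominated_rank(objective_vectors: Sequence[Sequence[float]]) -> list[int]:
    """Fronts of mutually non-dominated vectors, all objectives maximized.

    Rank 1 is the non-dominated set; rank k the non-dominated set after
    removing ranks below k.
    """
    F = np.asarray(objective_vectors, dtype=float)
    if F.size == 0:
        return []
    if F.ndim != 2:
        raise ValueError("objective vectors must form an n x m array")
    n = F.shape[0]
    ranks = np.zeros(n, dtype=int)
    remaining = np.arange(n)
    rank = 0
    while remaining.size:
        rank += 1
        front = []
        for i in remaining:
            if not any(_dominates(F[j], F[i]) for j in remaining if j != i):
                front.append(i)
        ranks[front] = rank
        remaining = np.array([i for i in remaining if i not in set(front)])
    return ranks.tolist()


def crowding_distance(objective_vectors: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance within one front (boundary points infinite)."""
    F = np.asarray(objective_vectors, dtype=float)
    n, m = F.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        span = F[order[-1], j] - F[order[0], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0:
            dist[order[1:-1]] += (F[order[2:], j] - F[order[:-2], j]) / span
    return dist


# ---------------------------------------------------------------------------
# individual-based LHS-MOEA


@dataclass(frozen=True)
class MOEAConfig:
    """Parameters of the individual-based LHS-MOEA."""

    population_size: int = 20
    generations: int = 30
    local_search_fraction: float = 0.3
    neighborhood_radius: float = 0.1
    local_sample_count: int = 5
    crossover_prob: float = 0.9
    mutation_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1 or self.generations < 1 or self.local_sample_count < 1:
            raise ValueError("population size, generations and sample count must be >= 1")
        for p in (self.local_search_fraction, self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probabilities must lie in [0, 1], got {p}")
        if self.neighborhood_radius <= 0:
            raise ValueError("neighborhood radius must be positive")


@dataclass(frozen=True)
class Problem:
    """Objective evaluator over the unit cube; all objectives maximized."""

    evaluate: Callable[[np.ndarray], np.ndarray]
    dimension: int


class _ContinuousRep:
    """Real-vector individuals in [0, 1]^d for generic problems."""

    def __init__(self, dimension: int):
        self.d = dimension

    def random(self, rng: np.random.Generator) -> np.ndarray:
        return rng.random(self.d)

    def decode(self, ind: np.ndarray) -> np.ndarray:
        return ind

    def neighbors(self, ind, radius, count, rng) -> list:
        return lhs_neighborhood_search(ind, radius, count, rng)

    def crossover(self, a, b, rng) -> np.ndarray:
        u = rng.random(self.d)
        return a + u * (b - a)

    def mutate(self, ind, rng) -> np.ndarray:
        out = ind.copy()
        mask = rng.random(self.d) < 1.0 / self.d
        if not mask.any():
            mask[rng.integers(self.d)] = True
        out[mask] = rng.random(mask.sum())
        return out


@dataclass
class Individual:
    genome: object
    objectives: np.ndarray
    rank: int = 0
    crowding: float = 0.0


def _evaluate(problem: Problem, rep, genome) -> np.ndarray:
    point = rep.decode(genome)
    obj = np.atleast_1d(np.asarray(problem.evaluate(point), dtype=float))
    if np.any(~np.isfinite(obj)):
        raise ValueError(f"non-finite objective value {obj} at point {point}")
    return obj


def _assign_fronts(pop: list[Individual]) -> None:
    ranks = nondominated_rank([ind.objectives for ind in pop])
    for ind, r in zip(pop, ranks):
        ind.rank = r
    for r in set(ranks):
        members = [ind for ind in pop if ind.rank == r]
        dists = crowding_distance(np.array([m.objectives for m in members]))
        for m, d in zip(members, dists):
            m.crowding = float(d)


def _tournament(pop: list[Individual], rng: np.random.Generator) -> Individual:
    # binary tournament on (rank, crowding)
    i, j = rng.integers(len(pop)), rng.integers(len(pop))
    a, b = pop[i], pop[j]
    if a.rank != b.rank:
        return a if a.rank < b.rank else b
    return a if a.crowding >= b.crowding else b


def _truncate(pop: list[Individual], n: int) -> list[Individual]:
    _assign_fronts(pop)
    order = sorted(
        range(len(pop)),
        key=lambda i: (pop[i].rank, -pop[i].crowding, i),
    )
    return [pop[i] for i in order[:n]]


def run_lhs_moea(
    problem: Problem,
    config: MOEAConfig,
    representation=None,
) -> list[Individual]:
    """Individual-based LHS-MOEA over the unit cube.

    Each generation, a fraction ``p`` of the population budget is spent on
    LHS local search: tournament-selected parents spawn ``H`` Latin-sampled
    neighbours, with radius ``delta`` when the parent is non-dominated and
    ``2 * delta`` otherwise.  The remaining ``(1 - p) N`` offspring come from
    tournament selection with crossover and mutation.  Parents and offspring
    are merged (elite retention) and the best ``N`` survive by
    non-dominated rank, then crowding distance.
    """
    rep = representation if representation is not None else _ContinuousRep(problem.dimension)
    rng = np.random.default_rng(config.seed)
    N = config.population_size
    pop = []
    for _ in range(N):
        g = rep.random(rng)
        pop.append(Individual(g, _evaluate(problem, rep, g)))
    for _ in range(config.generations):
        _assign_fronts(pop)
        merged: list[Individual] = []
        n_local = math.ceil(config.local_search_fraction * N)
        for _ in range(n_local):
            parent = _tournament(pop, rng)
            radius = (
                config.neighborhood_radius
                if parent.rank == 1
                else 2.0 * config.neighborhood_radius
            )
            for g in rep.neighbors(parent.genome, radius, config.local_sample_count, rng):
                merged.append(Individual(g, _evaluate(problem, rep, g)))
        for _ in range(N - n_local):
            a, b = _tournament(pop, rng), _tournament(pop, rng)
            g = (
                rep.crossover(a.genome, b.genome, rng)
                if rng.random() < config.crossover_prob
                else np.copy(a.genome) if isinstance(a.genome, np.ndarray) else a.genome
            )
            if rng.random() < config.mutation_prob:
                g = rep.mutate(g, rng)
            merged.append(Individual(g, _evaluate(problem, rep, g)))
        pop = _truncate(merged + pop, N)
    _assign_fronts(pop)
    return pop


# ---------------------------------------------------------------------------
# design optimization


class _LatinRep:
    """Permutation-encoded Latin hypercubes with in-bin jitter.

    A genome is a pair ``(bins, jitter)``: an ``n x d`` integer matrix whose
    columns are permutations of 0..n-1, plus in-bin offsets in [0, 1).  Every
    genome decodes to an exactly stratified design, so crossover (column-wise
    permutation exchange) and mutation (swap two bins in one column) preserve
    the Latin invariant by construction.
    """

    def __init__(self, n: int, d: int):
        self.n, self.d = n, d

    def random(self, rng):
        bins = np.column_stack([rng.permutation(self.n) for _ in range(self.d)])
        return bins, rng.random((self.n, self.d))

    def decode(self, genome) -> np.ndarray:
        bins, jitter = genome
        return (bins + jitter) / self.n

    def neighbors(self, genome, radius, count, rng) -> list:
        # local search: a few bin swaps (more for larger radius) plus an
        # LHS-style redraw of the jitter within a +-radius band
        bins, jitter = genome
        n_swaps = max(1, round(radius * self.n))
        out = []
        for _ in range(count):
            b = bins.copy()
            for _ in range(n_swaps):
                col = rng.integers(self.d)
                i, j = rng.integers(self.n, size=2)
                b[[i, j], col] = b[[j, i], col]
            jit = np.clip(jitter + rng.uniform(-radius, radius, jitter.shape), 0.0, 1.0 - 1e-12)
            out.append((b, jit))
        return out

    def crossover(self, a, b, rng):
        bins = a[0].copy()
        jitter = a[1].copy()
        take_b = rng.random(self.d) < 0.5
        bins[:, take_b] = b[0][:, take_b]
        jitter[:, take_b] = b[1][:, take_b]
        return bins, jitter

    def mutate(self, genome, rng):
        bins, jitter = genome[0].copy(), genome[1].copy()
        col = rng.integers(self.d)
        i, j = rng.integers(self.n, size=2)
        bins[[i, j], col] = bins[[j, i], col]
        return bins, jitter


def _design_objectives(points: np.ndarray) -> np.ndarray:
    # maximize maximin distance; minimize centered-L2 discrepancy
    return np.array(
        [pdist(points).min(), -qmc.discrepancy(points, method="CD")]
    )


def optimize_design(n: int, d: int, config: MOEAConfig) -> DesignMatrix:
    """Space-filling Latin hypercube via the LHS-MOEA.

    Evolves permutation-encoded Latin hypercubes under two objectives —
    maximin distance (maximized) and centered L2 discrepancy (minimized) —
    and returns the non-dominated design with the best maximin distance
    (ties broken by lower discrepancy).
    """
    if n < 2:
        raise ValueError("design optimization needs n >= 2")
    rep = _LatinRep(n, d)
    problem = Problem(evaluate=_design_objectives, dimension=d)
    pop = run_lhs_moea(problem, config, representation=rep)
    front = [ind for ind in pop if ind.rank == 1]
    best = max(front, key=lambda ind: (ind.objectives[0], ind.objectives[1]))
    return DesignMatrix(rep.decode(best.genome))


@dataclass(frozen=True)
class UniformityReport:
    """Space-filling diagnostics of a design."""

    min_pairwise_distance: float
    centered_l2_discrepancy: float
    per_dimension_bin_occupancy: list = field(default_factory=list)


def uniformity_report(design: DesignMatrix) -> UniformityReport:
    """Min pairwise distance, centered L2 discrepancy and bin occupancy."""
    if design.n < 2:
        raise ValueError("minimum pairwise distance is undefined for n < 2")
    occupancy = []
    for j in range(design.d):
        bins = _latin_bins(design.points[:, j], design.n)
        occupancy.append(np.bincount(bins, minlength=design.n).tolist())
    return UniformityReport(
        min_pairwise_distance=float(pdist(design.points).min()),
        centered_l2_discrepancy=float(qmc.discrepancy(design.points, method="CD")),
        per_dimension_bin_occupancy=occupancy,
    )
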