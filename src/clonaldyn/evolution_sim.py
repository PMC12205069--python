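"""Clone-resolved stochastic simulator of tumor expansion.

The population is a table of clones (genotype classes with cell counts), not
individual agents: spatial structure is abstracted into a logistic growth
envelope, which is what makes carrying capacities of 1e5-1e7 cells tractable.
Each generation g -> g+1 proceeds as:

1. the target size N_{g+1} comes from the closed-form discrete logistic
   solution at t=(g+1)/G (time normalized to [0, 1] in G equipartition steps);
2. the net increment is allocated as cell divisions across clones with
   probability proportional to count * b * (1 + s), so fitter clones divide
   more often under the same global envelope;
3. each division acquires a mutation with probability m; an acquired mutation
   is a driver draw (uniform from the pathogenic catalog partition) with
   probability p, else neutral.  A driver creates a child clone with
   s' = s + alpha * (score - 0.5) (an additive Markov update on the selection
   coefficient); a neutral mutation creates a child in neutral class k+1;
4. baseline deaths remove each cell with probability d; then the ratchet is
   enforced: the carrying capacity of neutral class k is the Poisson mass
   n_k = N e^{-theta} theta^k / k!, and any excess over n_k is removed
   uniformly at random (mutational-burden-dependent apoptosis, the Muller's
   ratchet channel);
5. the population is re-normalized to N_{g+1} by multinomial resampling
   proportional to clone counts, so the realized trajectory is exactly
   logistic.

``theta`` couples the mutation rate to the ratchet's selection coefficient.
Two conventions are available: the classical one (``haigh``, theta = m / s,
so a higher mutation rate erodes the least-loaded class faster — the default)
and its printed inverse (``paper``, theta = s / m), kept selectable because
sources disagree; the choice is echoed in every result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .logistic_core import LogisticParams, discrete_logistic_size
from .mutation_catalog import MutationCatalog, MutationClass, sample_mutation

__all__ = [
    "SimulationParams",
    "CloneRecord",
    "SimulationResult",
    "RegistryEntry",
    "ratchet_class_capacity",
    "initialize_population",
    "step_generation",
    "run_simulation",
]


@dataclass(frozen=True)
class SimulationParams:
    """Simulator configuration.

    Parameters
    ----------
    m : mutation probability per cell division, in [0, 1].
    p : probability that an acquired mutation is a driver draw, in [0, 1].
    r : logistic growth rate on normalized time (the trajectory parameter).
    capacity : carrying capacity C (cells).
    n0 : initial neoplastic population.
    generations : number of equipartition steps G of normalized time [0, 1].
    b : birth weight (baseline division propensity multiplier).
    d : baseline per-cell death probability per generation.
    fitness_scale : alpha, converting a driver's excess score (score - 0.5)
        into a selection-coefficient increment.
    ratchet_s : selection coefficient entering theta for the ratchet.
    theta_convention : "haigh" (theta = m / ratchet_s, classical) or
        "paper" (theta = ratchet_s / m).
    ratchet_enabled : whether the Poisson-class mortality channel runs.
    seed : RNG seed for the single per-run stream.
    """

    m: float = 0.01
    p: float = 0.01
    r: float = 2.0
    capacity: float = 1e7
    n0: float = 1e5
    generations: int = 50
    b: float = 1.0
    d: float = 0.1
    fitness_scale: float = 0.1
    ratchet_s: float = 0.04
    theta_convention: str = "haigh"
    ratchet_enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.m <= 1.0):
            raise ValueError(f"m must be in [0, 1], got {self.m}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if not (0 < self.n0 <= self.capacity):
            raise ValueError(
                f"need 0 < n0 <= capacity, got n0={self.n0}, capacity={self.capacity}"
            )
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.fitness_scale < 0:
            raise ValueError("fitness_scale must be >= 0")
        if not (0.0 <= self.d < 1.0):
            raise ValueError(f"d must be in [0, 1), got {self.d}")
        if self.b <= 0:
            raise ValueError("b must be > 0")
        if self.ratchet_s <= 0:
            raise ValueError("ratchet_s must be > 0")
        if self.theta_convention not in ("haigh", "paper"):
            raise ValueError(
                f"theta_convention must be 'haigh' or 'paper', got {self.theta_convention!r}"
            )

    @property
    def logistic(self) -> LogisticParams:
        return LogisticParams(n0=self.n0, capacity=self.capacity, rate=self.r)

    def theta(self) -> float | None:
        """Composite ratchet parameter, or None when m = 0 (no mutation
        pressure, the ratchet is vacuous)."""
        if self.m == 0:
            return None
        if self.theta_convention == "haigh":
            return self.m / self.ratchet_s
        return self.ratchet_s / self.m


@dataclass
class CloneRecord:
    """One genotype class: a set of driver mutations plus a neutral-class
    index k (count of neutral mutations), with its cell count.

    ``burden`` is the total mutation count D = |drivers| + k; the selection
    coefficient s is zero for clones without drivers.
    """

    clone_id: int
    parent_id: int | None
    driver_mutations: frozenset[str]
    neutral_mutations: frozenset[str]
    k_neutral: int
    s: float
    count: int

    @property
    def burden(self) -> int:
        return len(self.driver_mutations) + self.k_neutral


@dataclass(frozen=True)
class RegistryEntry:
    mutation_class: MutationClass
    score: float
    generation: int


@dataclass
class PopulationState:
    clones: list[CloneRecord]
    generation: int
    next_clone_id: int
    registry: dict[str, RegistryEntry] = field(default_factory=dict)
    trajectory: list[int] = field(default_factory=list)
    extinct: bool = False

    @property
    def total(self) -> int:
        return sum(c.count for c in self.clones)


@dataclass
class SimulationResult:
    params: SimulationParams
    trajectory: np.ndarray
    final_clones: list[CloneRecord]
    mutation_registry: dict[str, RegistryEntry]
    extinct: bool = False

    @property
    def total_cells(self) -> int:
        return int(sum(c.count for c in self.final_clones))

    def surviving_mutation_ids(self) -> set[str]:
        """Mutation IDs carried by at least one surviving cell."""
        ids: set[str] = set()
        for c in self.final_clones:
            if c.count > 0:
                ids |= c.driver_mutations
                ids |= c.neutral_mutations
        return ids

    def burdens(self) -> np.ndarray:
        return np.array([c.burden for c in self.final_clones], dtype=float)

    def counts(self) -> np.ndarray:
        return np.array([c.count for c in self.final_clones], dtype=np.int64)


def ratchet_class_capacity(n: float, theta: float, k: int) -> float:
    """Carrying capacity of neutral class k: ``N e^{-theta} theta^k / k!``.

    Summed over k this is exactly N (Poisson normalization); k = 0 gives the
    fittest-class capacity ``N e^{-theta}``.
    """
    if n < 0:
        raise ValueError(f"population size must be >= 0, got {n}")
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    if k < 0 or int(k) != k:
        raise ValueError(f"class index k must be a non-negative integer, got {k}")
    return n * math.exp(-theta + k * math.log(theta) - math.lgamma(k + 1))


def initialize_population(
    params: SimulationParams, cat: MutationCatalog
) -> PopulationState:
    """A single ancestor clone: burden 0, s = 0, count n0."""
    ancestor = CloneRecord(
        clone_id=0,
        parent_id=None,
        driver_mutations=frozenset(),
        neutral_mutations=frozenset(),
        k_neutral=0,
        s=0.0,
        count=int(round(params.n0)),
    )
    return PopulationState(
        clones=[ancestor],
        generation=0,
        next_clone_id=1,
        trajectory=[ancestor.count],
    )


def _allocate_divisions(
    counts: np.ndarray,
    s: np.ndarray,
    b: float,
    n_div: int,
    rng: np.random.Generator,
) -> np.ndarray:
    w = counts * b * (1.0 + s)
    total = w.sum()
    if total <= 0 or n_div <= 0:
        return np.zeros_like(counts)
    return rng.multinomial(n_div, w / total)


def step_generation(
    state: PopulationState,
    params: SimulationParams,
    cat: MutationCatalog,
    rng: np.random.Generator,
) -> PopulationState:
    """Advance the population one generation (see module docstring for the
    order of operations).  Mutates ``state`` in place and returns it."""
    if state.extinct:
        return state
    g = state.generation
    if g >= params.generations:
        raise ValueError(f"simulation already at final generation {g}")
    target = int(
        round(discrete_logistic_size(params.logistic, (g + 1) / params.generations))
    )

    clones = state.clones
    counts = np.array([c.count for c in clones], dtype=np.int64)
    svals = np.array([c.s for c in clones], dtype=float)
    cur = int(counts.sum())

    # (ii) divisions cover the net logistic increment, fitness-weighted
    n_div = max(target - cur, 0)
    divs = _allocate_divisions(counts, svals, params.b, n_div, rng)

    # (iii) mutation acquisition on each division
    muts = rng.binomial(divs, params.m) if params.m > 0 else np.zeros_like(divs)
    drivers = rng.binomial(muts, params.p) if params.p > 0 else np.zeros_like(muts)
    neutrals = muts - drivers
    counts += divs - muts  # unmutated daughters stay in the parent clone

    new_clones: list[CloneRecord] = []
    for i, parent in enumerate(clones):
        for _ in range(int(drivers[i])):
            mut = sample_mutation(cat, want_driver=True, rng=rng)
            if mut.mutation_id not in state.registry:
                state.registry[mut.mutation_id] = RegistryEntry(
                    mut.mutation_class, mut.score, g + 1
                )
            new_clones.append(
                CloneRecord(
                    clone_id=state.next_clone_id,
                    parent_id=parent.clone_id,
                    driver_mutations=parent.driver_mutations | {mut.mutation_id},
                    neutral_mutations=parent.neutral_mutations,
                    k_neutral=parent.k_neutral,
                    s=parent.s + params.fitness_scale * (mut.score - 0.5),
                    count=1,
                )
            )
            state.next_clone_id += 1
        for _ in range(int(neutrals[i])):
            mut = sample_mutation(cat, want_driver=False, rng=rng)
            if mut.mutation_id not in state.registry:
                state.registry[mut.mutation_id] = RegistryEntry(
                    mut.mutation_class, mut.score, g + 1
                )
            new_clones.append(
                CloneRecord(
                    clone_id=state.next_clone_id,
                    parent_id=parent.clone_id,
                    driver_mutations=parent.driver_mutations,
                    neutral_mutations=parent.neutral_mutations | {mut.mutation_id},
                    k_neutral=parent.k_neutral + 1,
                    s=parent.s,
                    count=1,
                )
            )
            state.next_clone_id += 1

    if new_clones:
        clones = clones + new_clones
        counts = np.concatenate(
            [counts, np.ones(len(new_clones), dtype=np.int64)]
        )

    # (iv) baseline deaths, then ratchet enforcement per neutral class
    if params.d > 0:
        counts = counts - rng.binomial(counts, params.d)
    theta = params.theta()
    if params.ratchet_enabled and theta is not None:
        kvals = np.array([c.k_neutral for c in clones], dtype=np.int64)
        for k in np.unique(kvals):
            mask = kvals == k
            class_total = int(counts[mask].sum())
            cap = int(math.floor(ratchet_class_capacity(target, theta, int(k))))
            if class_total > cap:
                counts[mask] = rng.multivariate_hypergeometric(counts[mask], cap)

    # (v) re-normalize to the logistic target by proportional resampling
    cur = int(counts.sum())
    if cur == 0:
        state.extinct = True
        state.clones = []
        state.generation = g + 1
        state.trajectory.append(0)
        return state
    deficit = target - cur
    if deficit > 0:
        counts = counts + rng.multinomial(deficit, counts / cur)
    elif deficit < 0:
        counts = rng.multivariate_hypergeometric(counts, target)

    # write back, dropping emptied clones
    kept = []
    for c, n in zip(clones, counts):
        if n > 0:
            c.count = int(n)
            kept.append(c)
    state.clones = kept
    state.generation = g + 1
    state.trajectory.append(int(counts.sum()))
    return state


def run_simulation(
    params: SimulationParams, cat: MutationCatalog
) -> SimulationResult:
    """Initialize and run all G generations; deterministic given the seed."""
    rng = np.random.default_rng(params.seed)
    state = initialize_population(params, cat)
    for _ in range(params.generations):
        state = step_generation(state, params, cat, rng)
        if state.extinct:
            break
    return SimulationResult(
        params=params,
        trajectory=np.array(state.trajectory, dtype=np.int64),
        final_clones=state.clones,
        mutation_registry=state.registry,
        extinct=state.extinct,
    )
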