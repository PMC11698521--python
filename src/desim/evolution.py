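"""The directed-evolution simulation loop.

One generation is select -> proliferate -> mutate: each cell is kept with
the probability its fitness percentile earns under the selection function,
the survivors are resampled with replacement back up to the fixed population
size P (a Wright-Fisher-style step that injects demographic stochasticity),
and every site of every genome then mutates independently with per-site rate
``p_I = mu / N`` to a uniformly chosen *different* state.  ``mu`` — the
expected number of changed sites per genome per generation ("mutations per
cell") — is the natural knob because it stays comparable as N varies.

Populations start from a single founder genome cloned P times: a uniformly
random sequence on NK landscapes, the wildtype on empirical ones.

Population splitting (:func:`run_split`) divides P cells into sub-populations
that evolve fully independently — no migration, separate RNG substreams —
and scores the best final outcome across them, mimicking speciation in
parallel directed-evolution replicates.  Each sub-population draws its own
starting location (on NK landscapes; empirical runs always start from the
wildtype); ``shared_founder`` instead clones one founder into all of them.

:func:`run_groups` is a vectorised engine that advances many independent
populations in lock-step through shared array operations; parameter sweeps
use it to simulate thousands of replicate runs cheaply.  It implements the
same per-generation semantics as :func:`run_simulation` but interleaves all
groups through one RNG stream, so individual trajectories differ from the
reference loop while their statistics agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._prng import stable_seed
from .selection import (
    SelectionFunction,
    combine_properties,
    double_round_select,
    select_population,
    single_round_select,
)

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "SplitResult",
    "BatchResult",
    "initialize_population",
    "mutate_population",
    "proliferate",
    "run_simulation",
    "run_split",
    "run_groups",
]


@dataclass
class SimulationConfig:
    """Run parameters for one directed-evolution experiment."""

    population_size: int
    generations: int
    mutations_per_cell: float
    selection: SelectionFunction = field(default_factory=SelectionFunction)
    n_subpopulations: int = 1
    trajectory_seed: int = 0
    record_every: int = 1
    #: weights over properties for multi-property runs (None = single property)
    weights: tuple | None = None
    #: "single_round" (weighted combination) or "double_round" (sequential cuts)
    selection_mode: str = "single_round"
    #: give every sub-population of a split run its own random starting
    #: location (default); set True to clone one founder into all of them,
    #: as when a single physical population is subdivided
    shared_founder: bool = False
    #: clone one founder (default) or draw P independent random genomes
    independent_init: bool = False

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be positive")
        if self.generations < 1:
            raise ValueError("generations must be positive")
        if self.mutations_per_cell < 0:
            raise ValueError("mutations_per_cell must be non-negative")
        if self.n_subpopulations < 1:
            raise ValueError("n_subpopulations must be positive")
        if self.n_subpopulations > self.population_size:
            raise ValueError("more sub-populations than cells")
        if self.record_every < 1:
            raise ValueError("record_every must be positive")
        if self.selection_mode not in ("single_round", "double_round"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")

    def subpopulation_sizes(self) -> np.ndarray:
        """P split as evenly as possible; remainder spread one per sub-pop."""
        base, rem = divmod(self.population_size, self.n_subpopulations)
        sizes = np.full(self.n_subpopulations, base, dtype=np.int64)
        sizes[:rem] += 1
        return sizes


@dataclass
class Trajectory:
    """Recorded history of one population."""

    recorded_generations: np.ndarray
    max_fitness: np.ndarray
    mean_fitness: np.ndarray
    final_genomes: np.ndarray
    final_fitness: np.ndarray
    populations: list | None = None
    normalised_final: float | None = None
    normalisation_exact: bool | None = None

    @property
    def final_max_fitness(self) -> float:
        return float(self.max_fitness[-1])

    @property
    def best_genome(self) -> np.ndarray:
        return self.final_genomes[int(np.argmax(self.final_fitness))]


@dataclass
class SplitResult:
    """Outcome of a split run: independent trajectories, best-of-final."""

    trajectories: list
    subpopulation_sizes: np.ndarray

    @property
    def best_final_fitness(self) -> float:
        return max(t.final_max_fitness for t in self.trajectories)

    @property
    def best_subpopulation(self) -> int:
        return int(np.argmax([t.final_max_fitness for t in self.trajectories]))

    @property
    def best_genome(self) -> np.ndarray:
        return self.trajectories[self.best_subpopulation].best_genome

    def final_genomes_with_labels(self) -> tuple[np.ndarray, np.ndarray]:
        """All final-generation genomes stacked, with sub-population labels."""
        genomes = np.concatenate([t.final_genomes for t in self.trajectories])
        labels = np.repeat(
            np.arange(len(self.trajectories)),
            [len(t.final_genomes) for t in self.trajectories],
        )
        return genomes, labels


# ---------------------------------------------------------------------------
# primitive steps


def initialize_population(
    landscape, population_size: int, rng: np.random.Generator,
    independent: bool = False,
) -> np.ndarray:
    """Founding population: one starting genome cloned P times (random
    location on NK landscapes, wildtype on empirical ones), or P independent
    random genomes when ``independent`` is set."""
    if independent:
        return np.stack(
            [landscape.initial_genome(rng) for _ in range(population_size)]
        )
    founder = landscape.initial_genome(rng)
    return np.tile(founder, (population_size, 1))


def mutate_population(
    population: np.ndarray, mutations_per_cell: float, alphabet_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independently mutate each site with rate p_I = mu/N; a mutated site
    takes a uniform value among the A-1 alternatives.  Returns a new array."""
    pop = np.asarray(population)
    n = pop.shape[1]
    p_site = mutations_per_cell / n
    if not 0.0 <= p_site <= 1.0:
        raise ValueError(
            f"per-site rate mu/N = {p_site} outside [0, 1] "
            f"(mu={mutations_per_cell}, N={n})"
        )
    out = pop.copy()
    if p_site == 0.0:
        return out
    mask = rng.random(pop.shape) < p_site
    hits = int(mask.sum())
    if hits:
        out[mask] = (out[mask] + rng.integers(1, alphabet_size, hits)) % alphabet_size
    return out


def proliferate(
    selected: np.ndarray, population_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Resample P cells uniformly with replacement from the selected ones."""
    sel = np.asarray(selected)
    if sel.ndim != 2 or sel.shape[0] == 0:
        raise ValueError("selected population must be a non-empty (S, N) array")
    parents = rng.integers(0, sel.shape[0], size=population_size)
    return sel[parents]


# ---------------------------------------------------------------------------
# fitness evaluation with duplicate collapsing


def _population_fitness(landscape, population: np.ndarray) -> np.ndarray:
    """Fitness of every cell; duplicate genomes are evaluated once.

    Populations are highly clonal (most cells are unmutated copies of a few
    parents), so genomes are deduplicated by packing each one into a single
    integer key whenever the code space fits into 63 bits.
    """
    pop = np.asarray(population)
    m, n = pop.shape
    if m <= 2:
        return landscape.fitness_many(pop)
    a = landscape.a
    if n * np.log2(a) <= 62:
        keys = pop @ (a ** np.arange(n, dtype=np.int64))
        uniq, first, inverse = np.unique(keys, return_index=True, return_inverse=True)
        if uniq.size == m:
            return landscape.fitness_many(pop)
        return landscape.fitness_many(pop[first])[inverse]
    uniq, inverse = np.unique(pop, axis=0, return_inverse=True)
    return landscape.fitness_many(uniq)[inverse]


def _property_matrix(landscapes, population: np.ndarray) -> np.ndarray:
    return np.stack([_population_fitness(ls, population) for ls in landscapes])


# ---------------------------------------------------------------------------
# reference loop


def run_simulation(
    config: SimulationConfig,
    landscape,
    rng: np.random.Generator | None = None,
    founder: np.ndarray | None = None,
    global_max: float | None = None,
    global_max_exact: bool = True,
    keep_populations: bool = False,
) -> Trajectory:
    """Evolve a single (unsplit) population and record its history.

    ``landscape`` may be a single landscape or a sequence of them for
    multi-property runs (each evaluated on the same genome; selection then
    acts on the weighted combination or via sequential cuts, per
    ``config.selection_mode``).  Deterministic given the landscape seed and
    ``config.trajectory_seed``.  Recording happens after mutation, every
    ``record_every`` generations plus generation 0 and the final one.  If
    ``global_max`` is supplied the trajectory's final maximum is also stored
    as a fraction of it ("normalised fitness"), flagged when the maximum is
    only a hill-climb estimate.
    """
    multi = isinstance(landscape, (list, tuple))
    landscapes = list(landscape) if multi else [landscape]
    first = landscapes[0]
    if any(ls.n != first.n or ls.a != first.a for ls in landscapes):
        raise ValueError("all property landscapes must share N and A")
    if rng is None:
        rng = np.random.default_rng(config.trajectory_seed)
    fn = config.selection
    p = config.population_size

    if founder is None:
        pop = initialize_population(first, p, rng, config.independent_init)
    else:
        founder = np.asarray(founder)
        if founder.ndim == 1:
            pop = np.tile(founder, (p, 1))
        else:
            pop = founder.copy()

    def evaluate(population):
        if multi:
            props = _property_matrix(landscapes, population)
            weights = config.weights if config.weights is not None \
                else np.ones(len(landscapes))
            return props, combine_properties(props, weights)
        fit = _population_fitness(first, population)
        return None, fit

    gens, maxes, means, pops = [], [], [], []
    props, fit = evaluate(pop)

    def record(gen):
        gens.append(gen)
        maxes.append(fit.max())
        means.append(fit.mean())
        if keep_populations:
            pops.append(pop.copy())

    record(0)
    for gen in range(1, config.generations + 1):
        if multi and config.selection_mode == "double_round":
            idx = double_round_select(
                props, fn.selected_fraction, weights=config.weights
            )
        elif multi:
            idx = single_round_select(props, config.weights or np.ones(len(landscapes)), fn, rng)
        else:
            idx = select_population(fit, fn, rng)
        pop = proliferate(pop[idx], p, rng)
        pop = mutate_population(pop, config.mutations_per_cell, first.a, rng)
        props, fit = evaluate(pop)
        if gen % config.record_every == 0 or gen == config.generations:
            record(gen)

    traj = Trajectory(
        recorded_generations=np.array(gens),
        max_fitness=np.array(maxes),
        mean_fitness=np.array(means),
        final_genomes=pop,
        final_fitness=fit,
        populations=pops if keep_populations else None,
    )
    if global_max is not None:
        traj.normalised_final = traj.final_max_fitness / global_max
        traj.normalisation_exact = global_max_exact
    return traj


def run_split(
    config: SimulationConfig,
    landscape,
    global_max: float | None = None,
    global_max_exact: bool = True,
) -> SplitResult:
    """Evolve ``n_subpopulations`` independent sub-populations.

    Each sub-population gets its own RNG substream derived from
    ``trajectory_seed`` and its index, so there is no cross-talk and results
    for one sub-population do not depend on how many others exist.  By
    default each starts from its own random founder; ``shared_founder``
    clones a single founder into all of them.
    """
    sizes = config.subpopulation_sizes()
    if config.n_subpopulations == 1:
        traj = run_simulation(
            config, landscape, global_max=global_max,
            global_max_exact=global_max_exact,
        )
        return SplitResult([traj], sizes)
    first = landscape[0] if isinstance(landscape, (list, tuple)) else landscape
    founder = None
    if config.shared_founder and not config.independent_init:
        founder_rng = np.random.default_rng(
            stable_seed(config.trajectory_seed, "founder")
        )
        founder = first.initial_genome(founder_rng)
    trajectories = []
    for i, size in enumerate(sizes):
        sub_cfg = replace(config, population_size=int(size), n_subpopulations=1)
        sub_rng = np.random.default_rng(
            stable_seed(config.trajectory_seed, "subpop", i)
        )
        trajectories.append(
            run_simulation(
                sub_cfg, landscape, rng=sub_rng, founder=founder,
                global_max=global_max, global_max_exact=global_max_exact,
            )
        )
    return SplitResult(trajectories, sizes)


# ---------------------------------------------------------------------------
# vectorised multi-population engine


@dataclass
class BatchResult:
    """Final state of many independently evolving populations."""

    final_genomes: np.ndarray
    final_fitness: np.ndarray
    group_ids: np.ndarray
    group_max_fitness: np.ndarray
    group_best_genomes: np.ndarray


def run_groups(
    landscape,
    group_sizes,
    generations: int,
    selection: SelectionFunction,
    mutations_per_cell: float,
    rng: np.random.Generator,
    founders: np.ndarray | None = None,
) -> BatchResult:
    """Advance many independent populations in lock-step.

    ``group_sizes`` gives the size of each population; all share one
    landscape and one RNG stream but never exchange cells: selection
    percentiles, the zero-survivor fallback and proliferation are all applied
    within each group separately.  ``selection`` is one
    :class:`SelectionFunction` for all groups or a sequence with one per
    group (so populations run under different strategies in the same batch).
    ``founders`` is an optional (G, N) array of per-group founder genomes
    (default: an independent random start per group, or the wildtype for
    empirical landscapes).
    """
    sizes = np.asarray(group_sizes, dtype=np.int64)
    if sizes.ndim != 1 or sizes.size == 0 or (sizes < 1).any():
        raise ValueError("group_sizes must be positive integers")
    n_groups = sizes.size
    total = int(sizes.sum())
    n, a = landscape.n, landscape.a
    p_site = mutations_per_cell / n
    if not 0.0 <= p_site <= 1.0:
        raise ValueError(f"per-site rate mu/N = {p_site} outside [0, 1]")

    gid = np.repeat(np.arange(n_groups), sizes)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    ends = np.cumsum(sizes) - 1
    denom = np.maximum(sizes - 1, 1).astype(float)
    singleton = sizes == 1

    if founders is None:
        founders = np.stack(
            [landscape.initial_genome(rng) for _ in range(n_groups)]
        )
    founders = np.asarray(founders)
    if founders.shape != (n_groups, n):
        raise ValueError(f"founders must have shape ({n_groups}, {n})")
    genomes = np.repeat(founders, sizes, axis=0)

    if isinstance(selection, SelectionFunction):
        fns = [selection] * n_groups
    else:
        fns = list(selection)
        if len(fns) != n_groups:
            raise ValueError("need one selection function per group")
    threshold = np.array([fn.fitness_threshold for fn in fns])[gid]
    base = np.array([fn.base_chance for fn in fns])[gid]
    sigma = np.array([fn.noise_sigma for fn in fns])[gid]
    fitness = _population_fitness(landscape, genomes)

    for _ in range(generations):
        f_sel = fitness
        if sigma.any():
            f_sel = fitness + sigma * rng.normal(0.0, 1.0, total)
        # within-group strictly-below counts (ties share a percentile)
        order = np.lexsort((f_sel, gid))
        f_sorted = f_sel[order]
        pos = np.arange(total)
        new_run = np.empty(total, dtype=bool)
        new_run[0] = True
        new_run[1:] = (f_sorted[1:] != f_sorted[:-1]) | (gid[order][1:] != gid[order][:-1])
        first_of_run = np.maximum.accumulate(np.where(new_run, pos, 0))
        below = np.empty(total, dtype=np.int64)
        below[order] = first_of_run - starts[gid[order]]
        pct = below / denom[gid]
        pct[singleton[gid]] = 1.0

        prob = np.where(pct >= threshold, 1.0, base)
        sel = rng.random(total) < prob
        # zero-survivor fallback: keep each starved group's fittest cell
        counts = np.bincount(gid, weights=sel, minlength=n_groups)
        empty = counts == 0
        if empty.any():
            sel[order[ends[empty]]] = True
            counts[empty] = 1

        # within-group resampling with replacement up to each group's size
        sel_idx = np.flatnonzero(sel)  # ascending, hence grouped by gid
        sel_counts = counts.astype(np.int64)
        sel_offsets = np.concatenate([[0], np.cumsum(sel_counts)[:-1]])
        draw = (rng.random(total) * sel_counts[gid]).astype(np.int64)
        parents = sel_idx[sel_offsets[gid] + draw]
        genomes = genomes[parents]

        if p_site > 0:
            mask = rng.random(genomes.shape) < p_site
            hits = int(mask.sum())
            if hits:
                genomes[mask] = (genomes[mask] + rng.integers(1, a, hits)) % a
        fitness = _population_fitness(landscape, genomes)

    group_max = np.full(n_groups, -np.inf)
    np.maximum.at(group_max, gid, fitness)
    best_rows = np.empty(n_groups, dtype=np.int64)
    # last argmax per group via the sorted order of the final fitnesses
    final_order = np.lexsort((fitness, gid))
    best_rows = final_order[ends]
    return BatchResult(
        final_genomes=genomes,
        final_fitness=fitness,
        group_ids=gid,
        group_max_fitness=group_max,
        group_best_genomes=genomes[best_rows],
    )
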