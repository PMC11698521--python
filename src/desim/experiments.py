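"""Config-driven simulation studies and parameter sweeps.

Two layers:

* :func:`run_sweep` — a general grid sweep using the reference simulation
  loop, producing one row per (grid cell, replicate) with final and
  normalised fitness plus reached-global / trapped-at-local flags where the
  landscape makes those decidable.

* :func:`run_strategy_ranking` — the robustness study that ranks a panel of
  30 base-chance x splitting strategies against one another over a grid of
  NK landscapes, population sizes and mutation rates, and reads off each
  strategy's mean percentile.  All strategies of one grid cell run inside a
  single vectorised batch (:func:`desim.evolution.run_groups`) so thousands of replicate
  populations stay cheap.

Every cell, replicate and strategy draws its RNG substream from a stable
hash of the master seed and its own parameters, so results are exactly
reproducible and adding grid cells never perturbs existing ones.
"""

from __future__ import annotations

import itertools
import logging
import warnings


import numpy as np
import pandas as pd

from ._prng import stable_seed
from .analysis import StrategyRanking, rank_strategies
from .empirical_landscape import EmpiricalLandscape
from .evolution import SimulationConfig, run_groups, run_split
from .nk_landscape import (
    DEFAULT_ENUMERATION_CAP,
    NKConfig,
    NKLandscape,
    find_global_optimum,
)
from .selection import SelectionFunction

__all__ = [
    "preset_standard_nk",
    "apply_preset",
    "run_sweep",
    "replicate_outcomes",
    "s4_parameter_grid",
    "s4_strategies",
    "run_strategy_ranking",
]

logger = logging.getLogger(__name__)

#: Sub-population sizes below this trigger a warning when applying presets:
#: very small sub-populations search their neighbourhood poorly.
_TINY_SUBPOP = 10


def preset_standard_nk() -> dict:
    """The shipped no-prior-knowledge strategy preset.

    When nothing is known about the landscape, splitting the population (up
    to 20 ways) with zero base chance and the usual 20% selected fraction is
    the most robust default found by the strategy-ranking sweep.
    """
    return {
        "base_chance": 0.0,
        "selected_fraction": 0.2,
        "n_subpopulations": 20,
    }


def apply_preset(user_config: dict, preset: dict | None = None) -> dict:
    """Merge a strategy preset over a user config dict.

    The preset supplies only strategy keys; the user's population size,
    mutation rate, generations etc. are preserved.  ``n_subpopulations`` is
    capped at the population size, and tiny sub-populations draw a warning.
    """
    preset = dict(preset_standard_nk() if preset is None else preset)
    merged = {**user_config, **preset}
    p = merged.get("population_size")
    n_sub = merged.get("n_subpopulations", 1)
    if p is not None:
        n_sub = min(n_sub, p)
        merged["n_subpopulations"] = n_sub
        if p // n_sub < _TINY_SUBPOP:
            warnings.warn(
                f"population {p} split {n_sub} ways leaves sub-populations "
                f"of ~{p // n_sub} cells; very small sub-populations "
                "search poorly and splitting may hurt"
            )
    return merged


def _split_sizes(population_size: int, n_subpopulations: int) -> np.ndarray:
    base, rem = divmod(population_size, n_subpopulations)
    sizes = np.full(n_subpopulations, base, dtype=np.int64)
    sizes[:rem] += 1
    return sizes


# ---------------------------------------------------------------------------
# generic grid sweep


_GRID_KEYS = (
    "n", "k", "a", "population_size", "mutations_per_cell",
    "base_chance", "n_subpopulations", "selected_fraction", "noise_sigma",
)


def run_sweep(
    grid: dict,
    reps: int,
    generations: int,
    master_seed: int = 0,
    landscape: EmpiricalLandscape | None = None,
    normalise: bool = False,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Run every cell of a parameter grid for ``reps`` replicates.

    ``grid`` maps parameter names (``n``, ``k``, ``a``, ``population_size``,
    ``mutations_per_cell``, ``base_chance``, ``n_subpopulations``, ...) to
    lists of values; the sweep covers the Cartesian product.  An NK
    landscape is drawn freshly per (cell, replicate) unless an empirical
    ``landscape`` is supplied, in which case ``n``/``k``/``a`` are ignored.

    ``scale`` multiplies reps and generations (each at least 1) so a study
    can be re-run smaller or larger without touching its definition; the
    factor is recorded in the output.  Invalid cells (e.g. base chance above
    the selected fraction) are skipped with a logged reason.

    Per row: final max fitness, plus, when decidable, normalised fitness,
    whether the run reached the landscape's global optimum and whether it
    ended trapped on a strictly suboptimal local optimum.  On enumerable
    landscapes "reached" means exact argmax membership; empirical lookups
    use a 1e-9 relative tolerance.
    """
    reps = max(1, int(round(reps * scale)))
    generations = max(1, int(round(generations * scale)))
    unknown = set(grid) - set(_GRID_KEYS)
    if unknown:
        raise ValueError(f"unknown grid parameter(s): {sorted(unknown)}")
    names = list(grid)
    rows = []
    for values in itertools.product(*(grid[name] for name in names)):
        cell = dict(zip(names, values))
        cell_token = repr(sorted(cell.items()))
        try:
            fn = SelectionFunction(
                base_chance=cell.get("base_chance", 0.0),
                selected_fraction=cell.get("selected_fraction", 0.2),
                noise_sigma=cell.get("noise_sigma", 0.0),
            )
        except ValueError as exc:
            logger.warning("skipping cell %s: %s", cell, exc)
            continue
        for rep in range(reps):
            seed = stable_seed(master_seed, "sweep", cell_token, rep)
            if landscape is None:
                ls = NKLandscape(
                    NKConfig(
                        n=cell["n"], k=cell["k"], a=cell.get("a", 2),
                        landscape_seed=stable_seed(seed, "landscape"),
                    )
                )
            else:
                ls = landscape
            cfg = SimulationConfig(
                population_size=cell.get("population_size", 1000),
                generations=generations,
                mutations_per_cell=cell.get("mutations_per_cell", 0.1),
                selection=fn,
                n_subpopulations=cell.get("n_subpopulations", 1),
                trajectory_seed=seed,
            )
            rows.append(
                {**cell, "rep": rep, "seed": seed, "scale": scale,
                 **_run_cell(cfg, ls, normalise)}
            )
    return pd.DataFrame(rows)


def _run_cell(cfg: SimulationConfig, ls, normalise: bool) -> dict:
    gmax = gmax_exact = None
    if isinstance(ls, EmpiricalLandscape):
        _, gmax = ls.global_optimum()
        gmax_exact = True
    elif normalise:
        exhaustive = ls.n_genomes <= DEFAULT_ENUMERATION_CAP
        opt = find_global_optimum(
            ls, mode="exhaustive" if exhaustive else "hillclimb"
        )
        gmax, gmax_exact = opt.fitness, opt.exact
    result = run_split(cfg, ls, global_max=gmax, global_max_exact=gmax_exact)
    best = result.best_final_fitness
    out = {
        "final_fitness": best,
        "normalised_fitness": best / gmax if gmax is not None else np.nan,
        "normalisation_exact": gmax_exact,
        "reached_global": np.nan,
        "trapped_local": np.nan,
    }
    if isinstance(ls, EmpiricalLandscape):
        best_seq = ls.coords_to_seq(result.best_genome)
        opt_seq, _ = ls.global_optimum()
        out["reached_global"] = bool(
            best_seq == opt_seq or abs(best - gmax) <= 1e-9 * abs(gmax)
        )
        optima = (
            ls.manifest.get("local_optima") if ls.manifest else None
        ) or ls.local_optima()
        out["trapped_local"] = bool(
            best_seq in optima and best_seq != opt_seq
        )
    elif gmax is not None and gmax_exact:
        out["reached_global"] = bool(abs(best - gmax) <= 1e-12 * max(1, abs(gmax)))
    return out


def replicate_outcomes(
    landscape: EmpiricalLandscape,
    base_chance: float,
    n_subpopulations: int,
    reps: int,
    population_size: int,
    generations: int,
    mutations_per_cell: float,
    selected_fraction: float = 0.2,
    master_seed: int = 0,
) -> dict:
    """Replicate one strategy many times on a manifest-carrying landscape.

    Runs ``reps`` independent replicates (vectorised in one batch), each a
    split run whose outcome is the best final genome across its
    sub-populations, and classifies every replicate against the landscape
    manifest: reached the global optimum, or trapped on a strictly
    suboptimal local optimum.  Returns the two fractions plus the mean best
    final fitness.
    """
    if landscape.manifest is None:
        raise ValueError("landscape must carry a manifest (see make_toy_landscape)")
    man = landscape.manifest
    optima = set(man["local_optima"])
    sizes = np.tile(_split_sizes(population_size, n_subpopulations), reps)
    fn = SelectionFunction(base_chance, selected_fraction)
    rng = np.random.default_rng(
        stable_seed(master_seed, "replicate-outcomes", f"{base_chance:g}",
                    n_subpopulations)
    )
    result = run_groups(
        landscape, sizes, generations, fn, mutations_per_cell, rng
    )
    rep_of_group = np.repeat(np.arange(reps), n_subpopulations)
    reached = trapped = 0
    best_fits = []
    for r in range(reps):
        groups = np.flatnonzero(rep_of_group == r)
        best = groups[np.argmax(result.group_max_fitness[groups])]
        seq = landscape.coords_to_seq(result.group_best_genomes[best])
        best_fits.append(result.group_max_fitness[best])
        if seq == man["global_optimum"]:
            reached += 1
        elif seq in optima:
            trapped += 1
    return {
        "reached_global": reached / reps,
        "trapped_local": trapped / reps,
        "mean_best_fitness": float(np.mean(best_fits)),
        "reps": reps,
    }


# ---------------------------------------------------------------------------
# strategy-ranking sweep


def s4_parameter_grid(include_largest_population: bool = False) -> list[dict]:
    """Grid of NK landscape shapes, population sizes and mutation rates.

    N in {50, 25}; K/N in {0, 0.05, …, 0.25} (K rounded half-up); per-site
    mutation rates {0.05/N … 0.25/N}, i.e. 0.05–0.25 expected mutations per
    cell; population sizes {1000, 100}, plus 5000 when
    ``include_largest_population`` is set (the default study drops it; the
    flag restores the full grid).
    """
    sizes = [5000, 1000, 100] if include_largest_population else [1000, 100]
    grid = []
    for n in (50, 25):
        for kfrac in (0.0, 0.05, 0.10, 0.15, 0.20, 0.25):
            k = int(np.floor(kfrac * n + 0.5))
            for p in sizes:
                for mu in (0.05, 0.10, 0.15, 0.20, 0.25):
                    grid.append(
                        {"n": n, "k": k, "population_size": p,
                         "mutations_per_cell": mu}
                    )
    return grid


def s4_strategies() -> list[dict]:
    """The 30-strategy panel: base chance x number of splits.

    Base chances {0, 0.05, 0.1, 0.15, 0.2} crossed with sub-population
    counts {1, 2, 5, 10, 20, 50}; includes the standard greedy strategy
    (no splits, no base chance) and the up-to-20-splits / zero-base-chance
    default recommended by the ranking.
    """
    return [
        {"base_chance": bc, "n_subpopulations": s}
        for bc in (0.0, 0.05, 0.10, 0.15, 0.20)
        for s in (1, 2, 5, 10, 20, 50)
    ]


def _strategy_name(strategy: dict) -> str:
    return f"bc{strategy['base_chance']:g}-s{strategy['n_subpopulations']}"


def run_strategy_ranking(
    master_seed: int = 0,
    reps: int = 5,
    generations: int = 50,
    include_largest_population: bool = False,
    selected_fraction: float = 0.2,
    grid: list[dict] | None = None,
    strategies: list[dict] | None = None,
) -> tuple[pd.DataFrame, StrategyRanking]:
    """Rank the strategy panel across the parameter grid.

    For every grid cell and replicate a fresh NK landscape, shared by all
    strategies, is drawn; all strategies' sub-populations advance together
    in one vectorised batch, each from its own random starting location.
    A split strategy's score for a replicate is its best final maximum
    fitness across its sub-populations.  Because every replicate carries its
    own landscape draw, the ranking treats each (cell, replicate) landscape
    as one parameter set, weighting all landscapes equally; percentile
    100 = best.

    Returns the row-level results table and the :class:`StrategyRanking`.
    """
    grid = s4_parameter_grid(include_largest_population) if grid is None else grid
    strategies = s4_strategies() if strategies is None else strategies
    landscapes: dict[tuple, NKLandscape] = {}
    rows = []
    for cell in grid:
        n, k = cell["n"], cell["k"]
        p, mu = cell["population_size"], cell["mutations_per_cell"]
        param_set = f"N{n}-K{k}-P{p}-mu{mu:g}"
        group_sizes = []
        fns = []
        bounds = [0]
        for strat in strategies:
            sizes = _split_sizes(p, strat["n_subpopulations"])
            group_sizes.append(sizes)
            fns.extend(
                [SelectionFunction(strat["base_chance"], selected_fraction)]
                * len(sizes)
            )
            bounds.append(bounds[-1] + len(sizes))
        group_sizes = np.concatenate(group_sizes)
        for rep in range(reps):
            key = (n, k, rep)
            if key not in landscapes:
                landscapes[key] = NKLandscape(
                    NKConfig(
                        n=n, k=k,
                        landscape_seed=stable_seed(
                            master_seed, "ranking-landscape", n, k, rep
                        ),
                    )
                )
            ls = landscapes[key]
            rng = np.random.default_rng(
                stable_seed(master_seed, "ranking-run", param_set, rep)
            )
            result = run_groups(ls, group_sizes, generations, fns, mu, rng)
            for s_i, strat in enumerate(strategies):
                best = float(
                    result.group_max_fitness[bounds[s_i]:bounds[s_i + 1]].max()
                )
                rows.append(
                    {"param_set": f"{param_set}-L{rep}", "cell": param_set,
                     "strategy": _strategy_name(strat),
                     "rep": rep, "fitness": best, **cell,
                     **{f"strategy_{k_}": v for k_, v in strat.items()}}
                )
        logger.info("ranking sweep: finished %s", param_set)
    results = pd.DataFrame(rows)
    return results, rank_strategies(results)
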