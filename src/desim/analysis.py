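"""Post-hoc diversity and strategy-performance analysis.

Covers the descriptive statistics used to compare directed-evolution
strategies: normalised Hamming diversity within and between sub-populations,
2-D PCA projections of final-generation sequences, head-to-head strategy
competitions on freshly drawn landscapes, and percentile ranking of many
strategies across a parameter grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from ._prng import stable_seed
from .evolution import SimulationConfig, run_split
from .nk_landscape import NKConfig, NKLandscape

__all__ = [
    "HammingSummary",
    "StrategyRanking",
    "hamming_stats",
    "pca_projection",
    "competition",
    "rank_strategies",
]


@dataclass
class HammingSummary:
    """Mean normalised Hamming distances within/between labelled groups.

    Distances are fractions of differing sites (in [0, 1], symmetric, zero on
    identical pairs).  ``mean_between`` is None when fewer than two labels
    are present.
    """

    mean_within: float
    mean_between: float | None
    matrix: np.ndarray | None = None


def hamming_stats(
    sequences: np.ndarray,
    labels: np.ndarray | None = None,
    keep_matrix: bool = False,
) -> HammingSummary:
    """Pairwise normalised Hamming statistics over a set of genomes.

    With ``labels`` (e.g. sub-population ids), "within" averages over pairs
    sharing a label and "between" over pairs with different labels; without
    labels all pairs count as within.
    """
    seqs = np.asarray(sequences)
    if seqs.ndim != 2 or seqs.shape[0] < 2:
        raise ValueError("need at least two sequences of equal length")
    dist = pdist(seqs, metric="hamming")  # already normalised by N
    n = seqs.shape[0]
    if labels is None:
        labels = np.zeros(n, dtype=np.int64)
    labels = np.asarray(labels)
    if labels.shape != (n,):
        raise ValueError("labels must match the number of sequences")
    ii, jj = np.triu_indices(n, k=1)
    same = labels[ii] == labels[jj]
    mean_within = float(dist[same].mean()) if same.any() else float("nan")
    mean_between = float(dist[~same].mean()) if (~same).any() else None
    return HammingSummary(
        mean_within=mean_within,
        mean_between=mean_between,
        matrix=squareform(dist) if keep_matrix else None,
    )


def pca_projection(
    sequences: np.ndarray, alphabet_size: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Project genomes onto their top two principal components.

    Binary genomes are used as-is; for larger alphabets sites are one-hot
    encoded first (category identity carries no order).  Returns the (M, 2)
    coordinates and the explained-variance fractions, components ordered by
    explained variance.  Zero-variance input yields all-zero coordinates
    with a warning.
    """
    seqs = np.asarray(sequences)
    if seqs.ndim != 2 or seqs.shape[0] < 3:
        raise ValueError("need at least three sequences")
    a = int(alphabet_size or seqs.max() + 1)
    if a > 2:
        m, n = seqs.shape
        x = np.zeros((m, n * a))
        x[np.repeat(np.arange(m), n),
          (np.arange(n) * a)[None, :].repeat(m, 0).ravel() + seqs.ravel()] = 1.0
    else:
        x = seqs.astype(float)
    if np.allclose(x.var(axis=0), 0.0):
        warnings.warn("zero-variance input: PCA projection is identically zero")
        return np.zeros((seqs.shape[0], 2)), np.zeros(2)
    pca = PCA(n_components=2, random_state=0)
    coords = pca.fit_transform(x)
    return coords, pca.explained_variance_ratio_


def competition(
    strategy_a: dict,
    strategy_b: dict,
    shared_params: dict,
    reps: int,
    rng: np.random.Generator,
) -> float:
    """Signed head-to-head score of two strategies over fresh landscapes.

    Per repetition a new NK landscape is drawn and both strategies — dicts of
    :class:`SimulationConfig` / selection overrides (``base_chance``,
    ``n_subpopulations``) — are run on it with the same trajectory seed.
    A strictly greater final maximum fitness wins the rep; exact ties score
    zero.  Returns (wins_a - wins_b) / reps, in [-1, 1].
    """
    if reps < 1:
        raise ValueError("reps must be positive")
    wins_a = wins_b = 0
    for rep in range(reps):
        landscape = NKLandscape(
            NKConfig(
                n=shared_params["n"],
                k=shared_params["k"],
                a=shared_params.get("a", 2),
                landscape_seed=int(rng.integers(2**31)),
            )
        )
        traj_seed = int(rng.integers(2**31))
        finals = []
        for strat in (strategy_a, strategy_b):
            cfg = _config_with_overrides(shared_params, strat, traj_seed)
            finals.append(run_split(cfg, landscape).best_final_fitness)
        if finals[0] > finals[1]:
            wins_a += 1
        elif finals[1] > finals[0]:
            wins_b += 1
    return (wins_a - wins_b) / reps


def _config_with_overrides(shared: dict, strategy: dict, traj_seed: int):
    from .selection import SelectionFunction

    fn = SelectionFunction(
        base_chance=strategy.get("base_chance", 0.0),
        selected_fraction=strategy.get(
            "selected_fraction", shared.get("selected_fraction", 0.2)
        ),
        noise_sigma=shared.get("noise_sigma", 0.0),
    )
    return SimulationConfig(
        population_size=shared["population_size"],
        generations=shared["generations"],
        mutations_per_cell=shared["mutations_per_cell"],
        selection=fn,
        n_subpopulations=strategy.get("n_subpopulations", 1),
        trajectory_seed=stable_seed(traj_seed, str(sorted(strategy.items()))),
    )


@dataclass
class StrategyRanking:
    """Per-strategy mean rank/percentile plus the per-parameter-set table."""

    summary: pd.DataFrame  # index strategy; columns mean_rank, percentile
    rank_table: pd.DataFrame  # parameter sets x strategies


def rank_strategies(results: pd.DataFrame) -> StrategyRanking:
    """Rank strategies against one another within each parameter set.

    ``results`` needs columns ``strategy``, ``param_set`` and ``fitness``
    (mean final fitness; repeated rows per cell are averaged first).  Within
    each parameter set strategies are ranked by fitness (rank 1 = best, ties
    averaged); ranks are then averaged weighting every parameter set equally
    and converted to percentiles with 100 = best possible, via
    ``100 * (S - rank) / (S - 1)``.
    """
    required = {"strategy", "param_set", "fitness"}
    if not required <= set(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    scores = (
        results.groupby(["param_set", "strategy"])["fitness"].mean().unstack()
    )
    if scores.isna().any().any():
        missing = scores.isna().stack()
        raise ValueError(
            f"missing strategy/parameter-set cells: "
            f"{list(missing[missing].index[:5])}"
        )
    n_strategies = scores.shape[1]
    if n_strategies < 2:
        raise ValueError("need at least two strategies to rank")
    ranks = scores.rank(axis=1, ascending=False, method="average")
    mean_rank = ranks.mean(axis=0)
    percentile = 100.0 * (n_strategies - mean_rank) / (n_strategies - 1)
    summary = pd.DataFrame(
        {"mean_rank": mean_rank, "percentile": percentile}
    ).sort_values("mean_rank")
    return StrategyRanking(summary=summary, rank_table=ranks)
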