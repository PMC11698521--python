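"""Two-parameter selection functions and multi-property selection.

A selection function maps a cell's *fitness percentile* — the fraction of
other cells in the population it is strictly fitter than — to a probability
of being carried into the next generation:

    P(select) = 1            if percentile >= fitness_threshold
              = base_chance  otherwise

The threshold is not free: fixing the expected selected fraction ``s`` (20%
throughout the sorting-based protocols modelled here, so proliferation time
per round stays constant) ties it to the base chance ``b`` through the
integral of the selection function,

    fitness_threshold = (1 - s) / (1 - b),

leaving base chance as the single exploration knob.  ``b = 0`` recovers
greedy top-fraction sorting; raising ``b`` lets unconditionally selected
cells drift downhill and escape local optima.  Valid configurations need
``b <= s`` (otherwise the threshold would exceed 1 and the base chance alone
would select more than ``s``).

Multi-property selection supports the two sorting modes of interest:
one cut on a weighted combination of all properties (single-round,
microfluidics-style) versus sequential per-property top-fraction cuts
(double-round, FACS-style).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SelectionFunction",
    "ObjectiveWeights",
    "threshold_from_base_chance",
    "fitness_percentiles",
    "selection_probability",
    "select_population",
    "combine_properties",
    "single_round_select",
    "double_round_select",
]


def threshold_from_base_chance(base_chance: float, selected_fraction: float) -> float:
    """Percentile threshold implied by a base chance and selected fraction.

    Solves ``integral of the selection function = selected_fraction`` for the
    threshold: ``t = (1 - s) / (1 - b)``.
    """
    if not 0.0 <= base_chance < 1.0:
        raise ValueError(f"base_chance must be in [0, 1), got {base_chance}")
    if not 0.0 < selected_fraction <= 1.0:
        raise ValueError(
            f"selected_fraction must be in (0, 1], got {selected_fraction}"
        )
    threshold = (1.0 - selected_fraction) / (1.0 - base_chance)
    if threshold > 1.0:
        raise ValueError(
            f"base_chance {base_chance} exceeds selected_fraction "
            f"{selected_fraction}: the implied threshold {threshold:.4f} > 1, "
            "i.e. base-chance draws alone would already select more than the "
            "target fraction"
        )
    return threshold


@dataclass(frozen=True)
class SelectionFunction:
    """Step selection function with derived threshold.

    Parameters
    ----------
    base_chance
        Selection probability below the threshold, in [0, selected_fraction].
    selected_fraction
        Expected fraction of the population selected per round (default 0.2).
    noise_sigma
        Standard deviation of additive N(0, sigma^2) fitness noise applied to
        a transient copy of the fitnesses before ranking, resampled every
        round; models measurement error and never persists.
    """

    base_chance: float = 0.0
    selected_fraction: float = 0.2
    noise_sigma: float = 0.0
    fitness_threshold: float = field(init=False)

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        object.__setattr__(
            self,
            "fitness_threshold",
            threshold_from_base_chance(self.base_chance, self.selected_fraction),
        )


def fitness_percentiles(fitnesses: np.ndarray) -> np.ndarray:
    """Percentile of each cell: fraction of *other* cells it is strictly
    fitter than, i.e. (# strictly below) / (P - 1).  Tied cells share a
    percentile; a population of one is at percentile 1."""
    f = np.asarray(fitnesses, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise ValueError("fitnesses must be a non-empty 1-D array")
    p = f.size
    if p == 1:
        return np.ones(1)
    order = np.argsort(f, kind="stable")
    sorted_f = f[order]
    # strictly-below count = index of the first element of each tie run
    first_of_run = np.zeros(p, dtype=np.int64)
    new_run = np.empty(p, dtype=bool)
    new_run[0] = True
    new_run[1:] = sorted_f[1:] != sorted_f[:-1]
    idx = np.arange(p)
    first_of_run = np.maximum.accumulate(np.where(new_run, idx, 0))
    below = np.empty(p, dtype=np.int64)
    below[order] = first_of_run
    return below / (p - 1)


def selection_probability(percentile, fn: SelectionFunction):
    """Eq-style step rule: 1 at or above the threshold, base chance below."""
    percentile = np.asarray(percentile, dtype=float)
    return np.where(
        percentile >= fn.fitness_threshold, 1.0, fn.base_chance
    )[()]


def select_population(
    fitnesses: np.ndarray,
    fn: SelectionFunction,
    rng: np.random.Generator,
    exact_fraction: bool = False,
) -> np.ndarray:
    """Indices of the cells selected in one round.

    Each cell is selected by an independent Bernoulli draw with its own
    selection probability, so the realised fraction is stochastic with
    expectation ``selected_fraction``.  If no cell is selected, the single
    fittest cell is kept as a fallback so the population cannot go extinct.
    With ``exact_fraction=True`` the Bernoulli sampling is replaced by a
    fixed quota: the top ``ceil(s * P)`` cells by (noisy) fitness.
    """
    f = np.asarray(fitnesses, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise ValueError("fitnesses must be a non-empty 1-D array")
    if fn.noise_sigma > 0:
        f = f + rng.normal(0.0, fn.noise_sigma, size=f.size)
    if exact_fraction:
        quota = int(np.ceil(fn.selected_fraction * f.size))
        return np.sort(np.argsort(-f, kind="stable")[:quota])
    pct = fitness_percentiles(f)
    prob = np.where(pct >= fn.fitness_threshold, 1.0, fn.base_chance)
    selected = np.flatnonzero(rng.random(f.size) < prob)
    if selected.size == 0:
        selected = np.array([int(np.argmax(f))])
    return selected


@dataclass(frozen=True)
class ObjectiveWeights:
    """Non-negative weights, one per measured property."""

    weights: tuple

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a non-empty 1-D sequence")
        if (w < 0).any() or not w.any():
            raise ValueError("weights must be non-negative and not all zero")
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights)


def combine_properties(values: np.ndarray, weights) -> np.ndarray:
    """Weighted combined fitness F = sum_i w_i f_i.

    ``values`` is either a length-M vector (one cell) or an (M, P) matrix of
    per-property fitnesses for P cells.
    """
    if isinstance(weights, ObjectiveWeights):
        w = weights.as_array()
    else:
        w = ObjectiveWeights(tuple(np.asarray(weights, dtype=float))).as_array()
    v = np.asarray(values, dtype=float)
    if v.shape[0] != w.size:
        raise ValueError(
            f"got {v.shape[0]} properties but {w.size} weights"
        )
    return w @ v


def single_round_select(
    property_values: np.ndarray,
    weights,
    fn: SelectionFunction,
    rng: np.random.Generator,
    exact_fraction: bool = False,
) -> np.ndarray:
    """One selection round on the weighted combination of all properties."""
    combined = combine_properties(property_values, weights)
    return select_population(combined, fn, rng, exact_fraction=exact_fraction)


def double_round_select(
    property_values: np.ndarray,
    selected_fraction: float = 0.2,
    per_round_fraction: float | None = None,
    weights=None,
) -> np.ndarray:
    """Sequential per-property top-fraction cuts (FACS-style).

    Survivors of the cut on property m enter the cut on property m+1.  The
    per-round fraction defaults to ``selected_fraction ** (1/M)`` so that
    under independent properties the expected final fraction matches a
    single-round cut of ``selected_fraction``.  Cells that are poor in one
    property but excel in another are eliminated, which is exactly the
    systematic error this mode exhibits relative to single-round selection.

    If every cell is cut, the single best cell by (equal- or user-) weighted
    combined fitness is kept.
    """
    v = np.asarray(property_values, dtype=float)
    if v.ndim != 2:
        raise ValueError("property_values must be an (M, P) matrix")
    m, p = v.shape
    if not 0.0 < selected_fraction <= 1.0:
        raise ValueError("selected_fraction must be in (0, 1]")
    frac = per_round_fraction if per_round_fraction is not None \
        else selected_fraction ** (1.0 / m)
    survivors = np.arange(p)
    for prop in range(m):
        keep = int(np.ceil(frac * survivors.size))
        order = np.argsort(-v[prop, survivors], kind="stable")
        survivors = np.sort(survivors[order[:keep]])
        if survivors.size == 0:
            break
    if survivors.size == 0:
        w = weights if weights is not None else np.ones(m)
        combined = combine_properties(v, w)
        survivors = np.array([int(np.argmax(combined))])
    return survivors
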