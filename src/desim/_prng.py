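"""Stable counter-based pseudorandom primitives.

Fitness contributions of an NK landscape are never stored in full: each one
is recomputed on demand from a stable 64-bit hash of its index tuple
(landscape seed, locus, locus states).  The hash must be identical across
runs, platforms and Python versions, so a fixed SplitMix64 mixing chain is
used rather than any language-default hash.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri

_U64 = np.uint64
_MIX1 = _U64(0x9E3779B97F4A7C15)
_MIX2 = _U64(0xBF58476D1CE4E5B9)
_MIX3 = _U64(0x94D049BB133111EB)
_S30 = _U64(30)
_S27 = _U64(27)
_S31 = _U64(31)
_S11 = _U64(11)
_ONE = _U64(1)

#: 2**-53, scale factor taking the top 53 hash bits to a unit-interval float
_INV53 = float(np.ldexp(1.0, -53))


def splitmix64(x: np.ndarray) -> np.ndarray:
    """One round of the SplitMix64 finaliser, element-wise on uint64."""
    with np.errstate(over="ignore"):  # wrap-around is the point
        x = (x + _MIX1)
        x = (x ^ (x >> _S30)) * _MIX2
        x = (x ^ (x >> _S27)) * _MIX3
        return x ^ (x >> _S31)


def as_u64_seed(seed: int) -> np.uint64:
    """Fold an arbitrary Python integer into uint64 (two's complement)."""
    return _U64(int(seed) % (1 << 64))


def hash_tuples(seed: int | np.uint64, components: np.ndarray) -> np.ndarray:
    """Hash integer tuples to uint64 values.

    Parameters
    ----------
    seed
        Stream seed, folded into the state before any component.
    components
        Integer array of shape ``(..., m)``; each length-``m`` tuple along the
        last axis is hashed independently of the others.
    """
    comp = np.asarray(components)
    if comp.ndim == 0:
        raise ValueError("components must have at least one axis")
    state = np.empty(comp.shape[:-1], dtype=_U64)
    state[...] = splitmix64(np.asarray(as_u64_seed(int(seed)), dtype=_U64))
    for j in range(comp.shape[-1]):
        # +1 keeps a zero component from being a no-op against a zero state
        state = splitmix64(state ^ (comp[..., j].astype(_U64) + _ONE))
    return state


def hash_to_uniform(hashed: np.ndarray) -> np.ndarray:
    """Map uint64 hashes to floats strictly inside (0, 1)."""
    return ((hashed >> _S11).astype(np.float64) + 0.5) * _INV53


def hash_to_normal(hashed: np.ndarray) -> np.ndarray:
    """Map uint64 hashes to standard-normal deviates via the inverse CDF."""
    return ndtri(hash_to_uniform(hashed))


def stable_seed(*parts) -> int:
    """Derive a reproducible 31-bit seed from a tuple of ints/strings.

    Used to give every sweep cell, replicate and sub-population its own
    substream such that adding cells to a grid never perturbs the streams of
    existing cells.
    """
    state = np.asarray(as_u64_seed(0x5EED), dtype=_U64)
    for part in parts:
        if isinstance(part, str):
            data = part.encode()
            state = splitmix64(state ^ (_U64(len(data)) + _ONE))
            for b in data:
                state = splitmix64(state ^ (_U64(b) + _ONE))
        else:
            state = splitmix64(state ^ (as_u64_seed(int(part)) + _ONE))
    return int(state) % (1 << 31)
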