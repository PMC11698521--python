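"""NK fitness landscapes with tunable ruggedness.

The NK model represents a gene as ``N`` loci, each taking one of ``A`` states
(binary by default).  Locus ``a`` interacts epistatically with ``K`` other
uniformly chosen loci, and contributes a fitness term that depends on its own
state plus the states of its partners.  Total fitness is the sum of the ``N``
locus contributions, so ``K = 0`` yields an additive, single-peaked landscape
while ``K = N − 1`` is maximally rugged.

Contributions are i.i.d. standard normal across distinct index tuples, but
they are *not* stored: the full table has ``N · A^(K+1)`` entries, so each
contribution is recomputed on demand from a stable hash of
``(landscape_seed, locus, states)`` (see :mod:`desim._prng`).  When the table
is small enough it is materialised once from the same hash as a lookup-table
cache, which changes nothing numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._prng import hash_to_normal, hash_tuples, stable_seed

__all__ = [
    "NKConfig",
    "NKLandscape",
    "OptimumResult",
    "build_interaction_map",
    "find_global_optimum",
    "count_local_optima",
    "local_optima_mask",
    "enumerate_genomes",
]

#: Largest A**N for which exhaustive enumeration is attempted by default.
DEFAULT_ENUMERATION_CAP = 2**20

#: Largest N * A**(K+1) contribution table that will be cached in memory.
DEFAULT_TABLE_CAP = 2**24


@dataclass(frozen=True)
class NKConfig:
    """Parameters fully determining one NK landscape.

    Two equal configs always describe bitwise-identical landscapes: the seed
    fixes both the locus interaction map and every fitness contribution.
    """

    n: int
    k: int
    a: int = 2
    landscape_seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"N must be positive, got {self.n}")
        if not 0 <= self.k <= self.n - 1:
            raise ValueError(f"K must lie in [0, N-1]=[0, {self.n - 1}], got {self.k}")
        if self.a < 2:
            raise ValueError(f"alphabet size A must be >= 2, got {self.a}")


def build_interaction_map(config: NKConfig) -> np.ndarray:
    """Draw the locus interaction map L.

    Each locus gets exactly ``K`` distinct partner loci sampled uniformly
    without replacement from the other ``N − 1`` loci, independently per
    locus.  The result is a ``(N, K)`` integer array, a pure function of the
    config; ``interaction_matrix`` converts it to the equivalent N x N binary
    storage form.
    """
    rng = np.random.default_rng(stable_seed(config.landscape_seed, "interaction-map"))
    n, k = config.n, config.k
    partners = np.empty((n, k), dtype=np.int64)
    others = np.arange(n - 1)
    for locus in range(n):
        chosen = rng.choice(others, size=k, replace=False)
        # skip over the locus itself so partners are drawn from the other N-1
        partners[locus] = chosen + (chosen >= locus)
    return partners


class NKLandscape:
    """An evaluable NK landscape (deterministic, side-effect free)."""

    def __init__(self, config: NKConfig, table_cap: int = DEFAULT_TABLE_CAP):
        self.config = config
        self.interaction_map = build_interaction_map(config)
        # column 0 is the locus itself (its state enters as i0 in every tuple)
        self._state_index = np.concatenate(
            [np.arange(config.n)[:, None], self.interaction_map], axis=1
        )
        self._table: np.ndarray | None = None
        self._table_cap = table_cap

    # -- basic descriptors -------------------------------------------------

    @property
    def n(self) -> int:
        return self.config.n

    @property
    def a(self) -> int:
        return self.config.a

    @property
    def n_genomes(self) -> int:
        return self.config.a**self.config.n

    @property
    def interaction_matrix(self) -> np.ndarray:
        """The map L as an N x N binary matrix (row = locus, col = partner)."""
        mat = np.zeros((self.n, self.n), dtype=np.int8)
        rows = np.repeat(np.arange(self.n), self.config.k)
        mat[rows, self.interaction_map.ravel()] = 1
        return mat

    # -- contributions -----------------------------------------------------

    def fitness_contribution(self, locus: int, states) -> float:
        """The contribution X^locus_{i0,...,iK} for one index tuple.

        ``states`` holds the state of the locus itself followed by the states
        of its K partners, each in ``{0..A-1}``.  Loci are 0-based.  The value
        is a deterministic function of ``(landscape_seed, locus, states)`` and
        is standard normal across distinct tuples.
        """
        states = np.asarray(states, dtype=np.int64)
        if not 0 <= locus < self.n:
            raise ValueError(f"locus {locus} outside [0, {self.n - 1}]")
        if states.shape != (self.config.k + 1,):
            raise ValueError(
                f"expected {self.config.k + 1} states (locus + K partners), "
                f"got shape {states.shape}"
            )
        if states.min() < 0 or states.max() >= self.a:
            raise ValueError(f"states must lie in [0, {self.a - 1}]")
        tup = np.concatenate([[locus], states])[None, :]
        return float(
            hash_to_normal(hash_tuples(self.config.landscape_seed, tup))[0]
        )

    def _contributions(self, states: np.ndarray) -> np.ndarray:
        """Vectorised contributions for ``states`` of shape (..., N, K+1)."""
        n = self.n
        loci = np.broadcast_to(
            np.arange(n, dtype=np.int64)[:, None], states.shape[:-1] + (1,)
        )
        tuples = np.concatenate([loci, states], axis=-1)
        return hash_to_normal(hash_tuples(self.config.landscape_seed, tuples))

    @property
    def table_size(self) -> int:
        return self.n * self.a ** (self.config.k + 1)

    def _ensure_table(self) -> np.ndarray | None:
        """Materialise the full contribution table when it is small enough.

        The table is generated by the very same hash as on-demand evaluation,
        flattened as ``table[locus * A**(K+1) + code]`` where ``code`` is the
        mixed-radix packing of (i0..iK) with i0 as the least-significant digit.
        """
        if self._table is None and self.table_size <= self._table_cap:
            k1 = self.config.k + 1
            codes = np.arange(self.a**k1, dtype=np.int64)
            digits = np.empty((self.a**k1, k1), dtype=np.int64)
            rem = codes
            for j in range(k1):
                digits[:, j] = rem % self.a
                rem = rem // self.a
            states = np.broadcast_to(digits[None, :, :], (self.n,) + digits.shape)
            self._table = np.ascontiguousarray(
                self._contributions(np.swapaxes(states, 0, 1))
            ).T.ravel()
        return self._table

    # -- fitness -----------------------------------------------------------

    def fitness_many(self, genomes: np.ndarray) -> np.ndarray:
        """Fitness F(g) — the sum of the N locus contributions — for an
        (M, N) array of genomes."""
        genomes = np.asarray(genomes)
        if genomes.ndim != 2 or genomes.shape[1] != self.n:
            raise ValueError(
                f"genomes must have shape (M, {self.n}), got {genomes.shape}"
            )
        table = self._ensure_table()
        if table is None:
            states = genomes[:, self._state_index]  # (M, N, K+1)
            return self._contributions(states).sum(axis=1)
        # packed-code path: codes = g @ W with W[p, a] = A**rank of p in locus a
        k1 = self.config.k + 1
        if getattr(self, "_weights", None) is None:
            weights = np.zeros((self.n, self.n), dtype=np.float64)
            pows = self.a ** np.arange(k1)
            for locus in range(self.n):
                weights[self._state_index[locus], locus] += pows
            self._weights = weights
            self._offsets = np.arange(self.n, dtype=np.int64) * (self.a**k1)
        codes = np.rint(genomes.astype(np.float64) @ self._weights).astype(np.int64)
        return table[codes + self._offsets].sum(axis=1)

    def fitness(self, genome) -> float:
        """Fitness of a single genome (length-N integer sequence)."""
        genome = np.asarray(genome, dtype=np.int64)
        if genome.shape != (self.n,):
            raise ValueError(f"genome must have length {self.n}, got {genome.shape}")
        if genome.min() < 0 or genome.max() >= self.a:
            raise ValueError(f"genome sites must lie in [0, {self.a - 1}]")
        return float(self.fitness_many(genome[None, :])[0])

    # -- population plumbing ----------------------------------------------

    def initial_genome(self, rng: np.random.Generator) -> np.ndarray:
        """A uniformly random starting genome."""
        return rng.integers(0, self.a, size=self.n, dtype=np.int64)

    def export_table(self, path) -> None:
        """Write genome -> fitness for every genome (enumerable landscapes)."""
        genomes = enumerate_genomes(self.n, self.a)
        fits = self.fitness_many(genomes)
        with open(path, "w") as fh:
            fh.write("genome\tfitness\n")
            for g, f in zip(genomes, fits):
                fh.write("".join(map(str, g)) + f"\t{f!r}\n")


@dataclass
class OptimumResult:
    """Outcome of a global-optimum search.

    ``exact`` is True only for exhaustive enumeration; hill-climb estimates
    are lower bounds on the true maximum.
    """

    genome: np.ndarray
    fitness: float
    exact: bool
    mode: str = "exhaustive"


def enumerate_genomes(n: int, a: int) -> np.ndarray:
    """All A**N genomes as an (A**N, N) array; row index is the mixed-radix
    packing of the genome with site 0 least significant."""
    codes = np.arange(a**n, dtype=np.int64)
    out = np.empty((a**n, n), dtype=np.int64)
    rem = codes
    for j in range(n):
        out[:, j] = rem % a
        rem = rem // a
    return out


def _require_enumerable(landscape_size: int, cap: int, what: str) -> None:
    if landscape_size > cap:
        raise ValueError(
            f"{what} would enumerate {landscape_size} genomes, above the cap "
            f"{cap}; use mode='hillclimb' (global optimum) or raise the cap "
            "explicitly if memory allows"
        )


def find_global_optimum(
    landscape: NKLandscape,
    mode: str = "exhaustive",
    budget: int = 10_000,
    cap: int = DEFAULT_ENUMERATION_CAP,
    rng: np.random.Generator | None = None,
) -> OptimumResult:
    """Locate (exhaustive) or estimate (hillclimb) the landscape maximum.

    Exhaustive mode enumerates all ``A**N`` genomes and is refused above
    ``cap``.  Hill-climb mode runs ``budget`` independent random-start
    steepest-ascent climbs over single-site moves and returns the best
    endpoint, which is a lower bound on the true maximum.
    """
    if mode == "exhaustive":
        _require_enumerable(landscape.n_genomes, cap, "exhaustive search")
        best_fit = -np.inf
        best_genome = None
        for chunk in _genome_chunks(landscape.n, landscape.a):
            fits = landscape.fitness_many(chunk)
            i = int(np.argmax(fits))
            if fits[i] > best_fit:
                best_fit = float(fits[i])
                best_genome = chunk[i].copy()
        return OptimumResult(best_genome, best_fit, exact=True, mode=mode)
    if mode == "hillclimb":
        rng = rng or np.random.default_rng(
            stable_seed(landscape.config.landscape_seed, "hillclimb")
        )
        genomes = rng.integers(0, landscape.a, size=(budget, landscape.n))
        fits = landscape.fitness_many(genomes)
        active = np.ones(budget, dtype=bool)
        while active.any():
            g = genomes[active]
            f = fits[active]
            nb_fit = np.full(g.shape[0], -np.inf)
            nb_site = np.zeros(g.shape[0], dtype=np.int64)
            nb_val = np.zeros(g.shape[0], dtype=np.int64)
            for site in range(landscape.n):
                for delta in range(1, landscape.a):
                    cand = g.copy()
                    cand[:, site] = (cand[:, site] + delta) % landscape.a
                    cf = landscape.fitness_many(cand)
                    better = cf > nb_fit
                    nb_fit[better] = cf[better]
                    nb_site[better] = site
                    nb_val[better] = cand[better, site]
            improved = nb_fit > f
            idx = np.flatnonzero(active)
            move = idx[improved]
            genomes[move, nb_site[improved]] = nb_val[improved]
            fits[move] = nb_fit[improved]
            active[idx[~improved]] = False
        i = int(np.argmax(fits))
        return OptimumResult(genomes[i].copy(), float(fits[i]), exact=False, mode=mode)
    raise ValueError(f"unknown mode {mode!r}; use 'exhaustive' or 'hillclimb'")


def _genome_chunks(n: int, a: int, chunk: int = 1 << 16):
    total = a**n
    if total <= chunk:
        yield enumerate_genomes(n, a)
        return
    for start in range(0, total, chunk):
        codes = np.arange(start, min(start + chunk, total), dtype=np.int64)
        out = np.empty((codes.size, n), dtype=np.int64)
        rem = codes
        for j in range(n):
            out[:, j] = rem % a
            rem = rem // a
        yield out


def local_optima_mask(fitness_flat: np.ndarray, n: int, a: int) -> np.ndarray:
    """Boolean mask over all genomes: strictly fitter than every single-site
    neighbour.  ``fitness_flat`` is indexed by the mixed-radix genome code
    (site 0 least significant), as produced by :func:`enumerate_genomes`."""
    total = a**n
    if fitness_flat.shape != (total,):
        raise ValueError(f"expected flat fitness of length {total}")
    codes = np.arange(total, dtype=np.int64)
    mask = np.ones(total, dtype=bool)
    for site in range(n):
        digit = (codes // a**site) % a
        for delta in range(1, a):
            nb = codes + ((digit + delta) % a - digit) * a**site
            mask &= fitness_flat > fitness_flat[nb]
    return mask


def count_local_optima(
    landscape: NKLandscape, cap: int = DEFAULT_ENUMERATION_CAP
) -> int:
    """Number of genomes strictly fitter than all single-site neighbours."""
    _require_enumerable(landscape.n_genomes, cap, "local-optima counting")
    fits = landscape.fitness_many(enumerate_genomes(landscape.n, landscape.a))
    return int(local_optima_mask(fits, landscape.n, landscape.a).sum())
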