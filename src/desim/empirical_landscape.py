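"""Combinatorially complete empirical fitness landscapes.

Landscapes like GB1 (IgG-Fc binding of protein G's B1 domain) and TrpB
(tryptophan synthase activity) measure fitness for essentially every variant
of a short stretch of protein — four variable residues by twenty amino acids,
160,000 variants.  Here such a landscape is stored as a dense
``alphabet_size ** n_sites`` array: assigning every residue an index turns a
sequence into the coordinates of its fitness value.

The published GB1/TrpB tables are not bundled and no imputation model is
provided: the loader accepts complete (or pre-imputed) tables, and missing
variants either raise or are filled with an explicit constant and flagged in
``missing_mask``.  :func:`make_toy_landscape` generates small fully known
landscapes with the same shape — a designated wildtype sitting next to a
deceptive local optimum and a distant global optimum — so every simulation
study and test can run without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nk_landscape import enumerate_genomes, local_optima_mask

__all__ = [
    "AMINO_ACIDS",
    "EmpiricalLandscape",
    "load_landscape",
    "make_toy_landscape",
]

#: Canonical residue order; toy alphabets use its leading letters.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class EmpiricalLandscape:
    """Dense lookup-table fitness landscape over fixed-length sequences."""

    n_sites: int
    alphabet: str
    fitness_array: np.ndarray
    wildtype: str
    missing_mask: np.ndarray
    manifest: dict | None = None

    def __post_init__(self) -> None:
        a = len(self.alphabet)
        expect = (a,) * self.n_sites
        if self.fitness_array.shape != expect:
            raise ValueError(
                f"fitness array shape {self.fitness_array.shape} != {expect}"
            )
        if self.missing_mask.shape != expect:
            raise ValueError("missing mask shape mismatch")
        if len(set(self.alphabet)) != a:
            raise ValueError("alphabet letters must be unique")
        wt = self.seq_to_coords(self.wildtype)
        if not np.isfinite(self.fitness_array[tuple(wt)]):
            raise ValueError(f"wildtype {self.wildtype!r} has non-finite fitness")
        self._index = {c: i for i, c in enumerate(self.alphabet)}

    # -- coordinates -------------------------------------------------------

    @property
    def a(self) -> int:
        return len(self.alphabet)

    @property
    def n(self) -> int:
        return self.n_sites

    @property
    def n_variants(self) -> int:
        return self.a**self.n_sites

    @property
    def coverage(self) -> int:
        """Number of cells backed by measured (non-filled) values."""
        return int((~self.missing_mask).sum())

    def seq_to_coords(self, sequence: str) -> np.ndarray:
        if len(sequence) != self.n_sites:
            raise ValueError(
                f"sequence {sequence!r} has length {len(sequence)}, "
                f"expected {self.n_sites}"
            )
        try:
            idx = {c: i for i, c in enumerate(self.alphabet)}
            return np.array([idx[c] for c in sequence], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(
                f"residue {exc.args[0]!r} not in alphabet {self.alphabet!r}"
            ) from None

    def coords_to_seq(self, coords) -> str:
        return "".join(self.alphabet[int(i)] for i in coords)

    # -- fitness -----------------------------------------------------------

    def lookup_fitness(self, sequence: str) -> float:
        """Stored fitness of a residue string."""
        return float(self.fitness_array[tuple(self.seq_to_coords(sequence))])

    def relative_fitness(self, sequence: str) -> float:
        """Fitness relative to wildtype (wildtype maps to exactly 1.0)."""
        return self.lookup_fitness(sequence) / self.lookup_fitness(self.wildtype)

    def fitness_many(self, genomes: np.ndarray) -> np.ndarray:
        """Fitness for an (M, n_sites) integer coordinate array."""
        genomes = np.asarray(genomes)
        if genomes.ndim != 2 or genomes.shape[1] != self.n_sites:
            raise ValueError(
                f"genomes must have shape (M, {self.n_sites}), got {genomes.shape}"
            )
        return self.fitness_array[tuple(genomes.T)]

    def fitness(self, genome) -> float:
        genome = np.asarray(genome, dtype=np.int64)
        return float(self.fitness_array[tuple(genome)])

    # -- population plumbing ----------------------------------------------

    def initial_genome(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Evolution starts from the wildtype sequence."""
        return self.seq_to_coords(self.wildtype)

    def local_optima(self) -> list[str]:
        """All sequences strictly fitter than every single-residue neighbour."""
        flat = np.empty(self.n_variants)
        genomes = enumerate_genomes(self.n_sites, self.a)
        flat[:] = self.fitness_many(genomes)
        mask = local_optima_mask(flat, self.n_sites, self.a)
        return [self.coords_to_seq(g) for g in genomes[mask]]

    def global_optimum(self) -> tuple[str, float]:
        flat_idx = int(np.argmax(self.fitness_array))
        coords = np.unravel_index(flat_idx, self.fitness_array.shape)
        return self.coords_to_seq(coords), float(self.fitness_array[coords])

    # -- round-trip --------------------------------------------------------

    def to_table(self) -> pd.DataFrame:
        """Complete sequence/fitness table (one row per array cell)."""
        genomes = enumerate_genomes(self.n_sites, self.a)
        seqs = ["".join(self.alphabet[i] for i in g) for g in genomes]
        return pd.DataFrame(
            {"sequence": seqs, "fitness": self.fitness_many(genomes)}
        )

    def write_table(self, path, sep: str = ",") -> None:
        self.to_table().to_csv(path, sep=sep, index=False)

    def write_manifest(self, path) -> None:
        seq, fit = self.global_optimum()
        manifest = {
            "n_sites": self.n_sites,
            "alphabet": self.alphabet,
            "wildtype": self.wildtype,
            "wildtype_fitness": self.lookup_fitness(self.wildtype),
            "global_optimum": seq,
            "global_optimum_fitness": fit,
            "coverage": self.coverage,
            "masked": int(self.missing_mask.sum()),
        }
        if self.manifest:
            manifest.update(self.manifest)
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2)


def load_landscape(
    table,
    wildtype: str,
    alphabet: str | None = None,
    fill_value: float | None = None,
    sep: str | None = None,
) -> EmpiricalLandscape:
    """Build a dense landscape from a sequence/fitness table.

    Parameters
    ----------
    table
        Path to a delimited text file with columns ``sequence`` and
        ``fitness`` (separator sniffed unless ``sep`` is given), or an
        equivalent :class:`pandas.DataFrame`.
    wildtype
        The reference sequence; must be present (never defaulted silently).
    alphabet
        Residue order; defaults to the 20 canonical amino acids for
        20-letter data, otherwise to the distinct residues actually observed,
        in canonical order.
    fill_value
        Variants absent from the table raise by default; passing a constant
        fills them instead, always flagged in ``missing_mask``.  No silent
        imputation happens either way.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep=sep, engine="python" if sep is None else "c")
    missing_cols = {"sequence", "fitness"} - set(df.columns)
    if missing_cols:
        raise ValueError(f"table lacks required column(s): {sorted(missing_cols)}")
    seqs = df["sequence"].astype(str)
    lengths = seqs.str.len().unique()
    if len(lengths) != 1:
        raise ValueError(f"sequences have mixed lengths: {sorted(lengths)}")
    n_sites = int(lengths[0])

    observed = set("".join(seqs))
    if alphabet is None:
        if observed <= set(AMINO_ACIDS) and len(observed) == 20:
            alphabet = AMINO_ACIDS
        else:
            canonical = [c for c in AMINO_ACIDS if c in observed]
            extra = sorted(observed - set(AMINO_ACIDS))
            alphabet = "".join(canonical + extra)
    unknown = observed - set(alphabet)
    if unknown:
        raise ValueError(f"unknown residue letter(s): {sorted(unknown)}")

    dup = df.groupby("sequence")["fitness"].nunique()
    conflicts = dup[dup > 1]
    if len(conflicts):
        raise ValueError(
            f"duplicate sequences with conflicting fitness: "
            f"{list(conflicts.index[:5])}"
        )
    df = df.drop_duplicates("sequence")

    a = len(alphabet)
    shape = (a,) * n_sites
    arr = np.full(shape, np.nan)
    index = {c: i for i, c in enumerate(alphabet)}
    coords = np.array(
        [[index[c] for c in s] for s in df["sequence"]], dtype=np.int64
    )
    arr[tuple(coords.T)] = df["fitness"].to_numpy(dtype=float)

    mask = np.isnan(arr)
    if mask.any():
        if fill_value is None:
            raise ValueError(
                f"{int(mask.sum())} of {a**n_sites} variants are missing; "
                "pass fill_value=<constant> to fill them explicitly"
            )
        arr[mask] = fill_value
    if wildtype not in set(seqs):
        raise ValueError(f"wildtype {wildtype!r} absent from the table")
    return EmpiricalLandscape(
        n_sites=n_sites,
        alphabet=alphabet,
        fitness_array=arr,
        wildtype=wildtype,
        missing_mask=mask,
    )


def make_toy_landscape(
    n_sites: int = 6,
    alphabet_size: int = 4,
    ruggedness_seed: int = 0,
    noise_scale: float = 1.2,
) -> EmpiricalLandscape:
    """Generate a small, fully known, deliberately deceptive landscape.

    The construction mimics the qualitative geometry of rugged empirical
    protein landscapes: a smooth hill rises from the wildtype towards a
    deceptive peak one mutation away — a strictly suboptimal local optimum —
    while the unique global optimum sits a few mutations from the wildtype
    (three, or ``n_sites - 1`` if smaller) behind a fitness valley, with a
    basin of radius one.  I.i.d. uniform noise of amplitude ``noise_scale``
    superimposes many minor local optima.  Greedy hill-climbing populations
    are funnelled up the deceptive hill; reaching the global peak requires
    drifting through the valley, which is exactly what base chance and
    population splitting are meant to enable.

    The returned landscape carries a ``manifest`` recording the wildtype,
    the global optimum, the deceptive local optimum and the full
    local-optima list obtained by enumeration.
    """
    if alphabet_size < 2 or alphabet_size > len(AMINO_ACIDS):
        raise ValueError("alphabet_size must be in [2, 20]")
    if alphabet_size**n_sites > 2**20:
        raise ValueError("toy landscape too large to enumerate")
    if n_sites < 2:
        raise ValueError("need at least two sites")
    rng = np.random.default_rng(ruggedness_seed)
    alphabet = AMINO_ACIDS[:alphabet_size]
    a, n = alphabet_size, n_sites

    wt = rng.integers(0, a, size=n)
    local = wt.copy()
    local[0] = (local[0] + 1) % a  # deceptive peak is one step from wildtype
    glob = wt.copy()  # global peak: a few steps away, behind a valley
    d_gw = min(3, n - 1)
    sites = rng.choice(np.arange(1, n), size=d_gw, replace=False)
    glob[sites] = (glob[sites] + 1 + rng.integers(0, a - 1, size=d_gw)) % a

    genomes = enumerate_genomes(n, a)
    d_local = (genomes != local).sum(axis=1)
    d_glob = (genomes != glob).sum(axis=1)

    # broad hill toward the deceptive peak + narrow spike at the global peak
    flat = 2.0 * (n - d_local) / n
    flat += np.where(d_glob == 0, 6.0, 0.0)
    flat += np.where(d_glob == 1, 2.5, 0.0)
    flat += noise_scale * rng.random(genomes.shape[0])
    # keep all fitnesses positive so wildtype-relative values behave
    flat += 0.5
    # pin the deceptive peak above the noise ceiling of its neighbours so it
    # is a local optimum by construction, yet still far below the global peak
    flat[(d_local == 0).nonzero()[0]] = 2.0 + noise_scale + 1.0

    arr = np.empty((a,) * n)
    arr[tuple(genomes.T)] = flat

    landscape = EmpiricalLandscape(
        n_sites=n,
        alphabet=alphabet,
        fitness_array=arr,
        wildtype="".join(alphabet[i] for i in wt),
        missing_mask=np.zeros((a,) * n, dtype=bool),
    )
    opt_seq, opt_fit = landscape.global_optimum()
    optima = landscape.local_optima()
    landscape.manifest = {
        "wildtype": landscape.wildtype,
        "global_optimum": opt_seq,
        "global_optimum_fitness": opt_fit,
        "deceptive_local_optimum": landscape.coords_to_seq(local),
        "local_optima": optima,
        "ruggedness_seed": int(ruggedness_seed),
    }
    return landscape
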