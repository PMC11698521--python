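# Methods

`desim` simulates sorting-based directed evolution — the workflow in which a
cell population carrying a mutagenised gene is iteratively screened (e.g. by
FACS or microfluidic sorting), the selected cells are regrown, and the cycle
repeats — and provides the machinery to compare *selection strategies* on
synthetic (NK) and empirical fitness landscapes. This note records the model,
its assumptions, the defaults, and the design decisions taken where the
problem was genuinely open.

## The simulation cycle

A genetic variant is an array `g` of `N` integer sites, each in `{0..A-1}`.
A population holds `P` such genomes. One generation applies, in order:

1. **Selection.** Each cell's fitness is ranked into a *fitness percentile*:
   the fraction of other cells it is strictly fitter than, i.e.
   `(# strictly below) / (P − 1)`; tied cells share a percentile, and a
   population of one cell is at percentile 1. The selection function is a
   two-parameter step: probability 1 at or above the *fitness threshold*,
   otherwise the *base chance* `b`. Fixing the expected selected fraction
   `s` (0.2 by default) ties the threshold to the base chance through the
   integral of the step function, `t = (1 − s)/(1 − b)`, valid for `b ≤ s`.
   Each cell is kept by an independent Bernoulli draw of its probability.
   If no cell survives (possible when `b = 0` and the top fitness is tied
   across many clones, since tied cells share a percentile below the
   threshold), the single fittest cell is kept so the population cannot go
   extinct. An `exact_fraction` mode replaces the Bernoulli draws by a fixed
   top-`⌈sP⌉` quota for users needing deterministic counts.
2. **Proliferation.** A new population of exactly `P` cells is resampled
   uniformly *with replacement* from the survivors (Wright–Fisher style),
   injecting demographic stochasticity.
3. **Mutation.** Every site of every genome independently mutates with
   per-site probability `p_I = μ/N` to a uniformly chosen *different* state.
   `μ`, the expected number of changed sites per genome per generation
   ("mutations per cell"), is the natural control because it is comparable
   across `N`. Defaults in the bundled studies are `μ = 0.1` on `N = 25`
   landscapes.

Populations start from a single founder cloned `P` times: a uniformly random
genome on NK landscapes, the wildtype on empirical ones (an option draws `P`
independent random genomes instead). Recording happens after the mutation
step; the headline statistic of a run is the maximum fitness in the final
population, optionally divided by the landscape's global maximum
("normalised fitness", flagged when the maximum is only a hill-climb
estimate).

**Tie handling** is the one place where the percentile definition has real
dynamical consequences: highly clonal populations (the norm at `μ ≈ 0.1`)
have large fitness ties, so under `b = 0` a fixated population repeatedly
falls back to its single fittest cell. We checked the alternative —
randomised tie-breaking, which always selects ~`sP` cells — and kept the
strict shared-percentile definition: it follows the percentile's definition
literally and reproduces the expected qualitative behaviour (zero base
chance optimal on smooth landscapes, base chance ≈ 0.1 optimal on rugged
ones) more cleanly than the randomised variant.

## NK landscapes

The NK model draws a random fitness function over `A^N` genomes with
ruggedness tuned by `K`: locus `a` contributes a term depending on its own
state and the states of `K` distinct partner loci drawn uniformly (without
replacement, excluding `a` itself) per locus; total fitness is the sum of
the `N` contributions. `K = 0` is additive and single-peaked; `K = N − 1` is
i.i.d. noise. Contributions are standard normal across distinct index
tuples and are *not* stored: each is recomputed on demand by hashing
`(landscape_seed, locus, states)` with a fixed SplitMix64 chain, mapping the
top 53 bits to a uniform in (0, 1) and applying the inverse normal CDF. The
hash is stable across runs, platforms and Python versions — a language
default hash would not be. When `N·A^(K+1)` is small enough (default cap
2^24 entries) the full table is materialised once *from the same hash* as a
lookup cache; the two paths are bitwise identical and tested as such.
Contributions are summed raw (no `1/N` scaling), so fitness can be negative
and grows with `N`; only within-landscape comparisons and normalised values
are meaningful.

Global optima are found exhaustively for `A^N ≤ 2^20` (configurable) and
otherwise estimated by steepest-ascent hill climbing from (default) 10^4
random starts, reported as an explicit lower-bound estimate. Local optima —
genomes strictly fitter than all single-site neighbours — are counted by
enumeration; their mean count grows from 1 at `K = 0` towards `2^N/(N+1)`
at `K = N − 1`, the classical i.i.d. expectation, which the test suite
verifies.

## Empirical landscapes

Combinatorially complete landscapes (GB1- and TrpB-shaped: 4 variable
residues × 20 amino acids = 160,000 variants) are dense `A^n` arrays indexed
by residue coordinates, with residue order fixed to the canonical 20-letter
amino-acid alphabet (`ACDEFGHIKLMNPQRSTVWY`); toy alphabets use its leading
letters. The published GB1/TrpB tables are not bundled, and the imputation
model used upstream to fill their missing variants is not reproduced: the
loader takes complete or pre-imputed `sequence,fitness` tables, raises on
missing variants by default, and can fill them with an explicit constant
that is always flagged in a missing-value mask. Results that depend on
imputed cells are therefore treated as non-reproducible here; wildtype
sequences are never defaulted silently.

### The deceptive toy landscape

`make_toy_landscape` generates small, fully known stand-ins (default 6 sites
× 4 residues = 4096 variants, all synthetic) with the geometry that makes
exploration strategies matter on real protein landscapes: a smooth hill
rises from the wildtype to a *deceptive* peak one mutation away (pinned
above the noise ceiling of its neighbours so it is a strict local optimum),
the unique global optimum sits three mutations from the wildtype behind a
fitness valley with a basin of radius one, and uniform noise (amplitude 1.2
by default) superimposes tens of minor local optima. A manifest records the
wildtype, global optimum, deceptive optimum and the enumerated local-optima
list, so replicate studies can classify every run as "reached the global
optimum" / "trapped on a local optimum". How deceptive a particular seed's
landscape is varies; the default seed's landscape traps the greedy standard
strategy in over 80% of replicates under the bundled study conditions
(`P = 200`, 80 generations, `μ = 0.2`). This generator emulates the
*geometry* of empirical landscapes, not their measurement noise, missing
data, or assay-specific fitness units — toy-landscape results demonstrate
mechanisms, not quantitative predictions for GB1/TrpB.

## Strategies

* **Base chance** trades exploitation for exploration: below-threshold
  cells keep probability `b` of surviving, letting lineages drift through
  fitness valleys. Valid range `0 ≤ b ≤ s`.
* **Population splitting** divides `P` cells into `n` sub-populations
  (sizes as even as possible, remainder spread one per sub-population) that
  evolve with zero migration and independent RNG substreams; the result of
  a split run is the best final maximum across sub-populations. Each
  sub-population starts from its own random founder by default
  (`shared_founder` clones one founder into all, as when a single physical
  population is subdivided).
* **Multi-property selection** evaluates `M` landscapes on the same genome
  and either cuts once on the weighted combination `F = Σ wᵢfᵢ`
  (single-round, microfluidics-style) or applies sequential per-property
  top-fraction cuts (double-round, FACS-style) with per-round fraction
  `s^(1/M)` so the expected yield matches under independence (the per-round
  cut is configurable because published protocols differ). Single-round
  selection dominates on the combined objective; the sequential cuts
  discard cells that are poor in one property but excellent overall.

The shipped no-prior-knowledge preset (`preset_standard_nk`) is 20
sub-populations, zero base chance, 20% selected fraction — the most robust
strategy in the ranking sweep below; merging it over a user config preserves
the user's population size, mutation rate and generations, and warns when
the split would leave sub-populations below 10 cells.

## The strategy-ranking sweep

`run_strategy_ranking` ranks a panel of 30 strategies — base chances
{0, 0.05, 0.1, 0.15, 0.2} × sub-population counts {1, 2, 5, 10, 20, 50};
the exact panel is a design choice, as is the half-up rounding of the
`K = {0, 0.05N, …, 0.25N}` ruggedness grid — over NK landscapes with
`N ∈ {25, 50}`, population sizes {1000, 100} (5000 available via a flag,
dropped in the default study), and mutations per cell
{0.05 … 0.25}. Per grid cell and replicate a fresh landscape is drawn and
shared by all strategies, whose sub-populations advance together in one
vectorised batch (`run_groups`) through a single RNG stream — the groups
never exchange cells, and the batch statistics agree with the reference
loop (tested). Because each replicate carries its own landscape draw, the
ranking treats every (cell, replicate) landscape as one ranking unit,
weighting all landscapes equally, with ties averaged and percentile
100 = best.

Default problem sizes here and in the other bundled studies (5 replicates
per cell, 50 generations in the ranking sweep; 20 replicates in the
splitting-diversity study; 200 replicates in the toy-landscape escape study)
are the package's default study sizes; `run_sweep` exposes a single `scale`
factor, recorded in its output, to shrink or grow a study without editing
its definition. Strategy percentiles depend on the horizon: short runs
flatter greedy exploitation (the no-split/no-base-chance strategy's mean
percentile falls from ≈59 at 50 generations to ≈48 at 300 on the `N = 25`
half-grid), so rankings should be compared only at matched generation
counts.

## Reproducibility and numerics

Every stochastic component draws from `numpy.random.Generator` substreams
derived by a stable hash (`desim._prng.stable_seed`) of a master seed and
the component's own parameters, so identical configs reproduce bitwise
identical results, sub-populations evolve without cross-talk (permuting
their indices permutes results), and adding cells to a sweep grid never
perturbs existing cells. Landscape generation and trajectory stochasticity
use separate streams. Fitness evaluation deduplicates clonal genomes by
packing each genome into a 63-bit key when possible; "reached the global
optimum" uses exact argmax membership on enumerable landscapes and a 1e-9
relative tolerance on empirical lookups. Degenerate inputs are handled
explicitly: single-cell populations are always selected, empty survivor
sets fall back to the fittest cell (selection) or the best combined score
(double-round), zero-variance PCA inputs return the origin with a warning,
and exhaustive enumeration above the cap is refused with a pointer to the
hill-climb estimator.

## Known limitations

* The real GB1/TrpB tables (and hence the published fold-gains on them) are
  out of reach without the external datasets and their unspecified
  imputation; the toy-landscape escape study substitutes directional,
  sign-level checks of the same mechanisms.
* NK landscapes with per-site `K` distributions, neutral-drift variants, or
  substitution-matrix-informed contributions are not implemented.
* No migration between sub-populations, no variable population sizes, no
  growth-coupled selection dynamics.
* The strict-tie percentile definition makes `b = 0` dynamics at fixation
  depend on the single-fittest fallback; this is documented behaviour, not
  an accident, but other reasonable tie conventions exist and would change
  quantitative outcomes.
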