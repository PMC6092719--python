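# Methods

## The selection problem

A collection `A` holds `n` accessions; a core is any subset `C ⊂ A`
with `|C| = k`, `2 ≤ k ≤ n − 1` (`k = 1` is excluded because
entry-to-nearest-entry needs a "closest other entry"). The tool seeks
`argmax F(C)` over all such subsets for a chosen evaluation measure
`F`; measures meant to be minimized (A-NE) are maximized as `−F`.
Fractional core sizes (e.g. 20% of the collection) round half up and
clamp to the feasible range. Variable-size core sampling is out of
scope: the provided measures are not comparable across sizes (smaller
cores trivially look more diverse, larger ones more representative).

## Distances

**Modified Roger's** distance between allele-frequency profiles:
`MR(i,j) = sqrt( Σ_l Σ_a (p_ila − p_jla)² / (2L) )`, which lies in
[0, 1] with 1 for fully disjoint homozygotes. **Gower's** distance
averages per-trait dissimilarities: range-scaled absolute differences
for quantitative traits (0 when the trait range is 0) and 0/1 matching
for qualitative ones. Ordinal traits are not modelled separately: users
should code them numerically or treat them as categories.

Missing data are handled by pairwise deletion: a locus (or trait)
enters `MR(i,j)` (or Gower) only when observed in both accessions, and
`L` becomes the mutually observed count. A pair sharing no observed
locus is an error, not a guess. Allele-frequency vectors must sum to 1
within 1e-6; renormalization is refused so that evaluation stays a pure
function of the input file.

## Objectives

E-NE, A-NE, HE, DMIN and avg-EE are defined in the README. Design
points worth recording:

- **HE pooling.** Core allele frequencies `p̂_la` are unweighted means
  of the entries' frequency vectors (over entries with observed data at
  the locus), generalizing allele counting to frequency-valued entries.
  A locus missing in every core entry is dropped from the average.
- **DMIN is report-only.** Many swaps leave the minimum distance
  unchanged, so a local search gets no signal from it; the evaluator
  refuses DMIN as an optimization target and E-NE serves as its proxy.
  Every evaluation report includes DMIN whenever distances exist.
- **Weighted index.** `F = Σ α_i F'_i` with weights in (0, 1] summing
  to 1. Each sign-adjusted measure is normalized by bounds computed
  from single-objective searches: upper = best value found for that
  measure alone; lower = the worst value the measure takes at any of
  those single-objective optima (the Pareto minimum). The bound
  searches use random descent with sub-seeds derived from the caller's
  seed and the caller's stop condition, so ranges are reproducible.
  Degenerate measures (upper = lower, e.g. when one subset optimizes
  everything) are treated as the constant 1 with a warning.
- **Clamping.** The *reported* normalized values are clamped to [0, 1].
  The *search* score uses the unclamped affine map: a random starting
  core typically scores below the Pareto-minimum lower bound on every
  measure, and clamping there would flatten the whole reachable
  landscape to exactly 0, blinding the search. The unclamped map keeps
  the gradient and changes no argmax.
- Single-objective runs are optimized unnormalized (normalization is an
  increasing affine map, so the optimum is unchanged and one search per
  bound is saved).

## Search engines

All engines sample uniformly from the `k(n − k)` single-swap moves and
are deterministic given their seed.

- **Random descent** accepts strictly improving moves only.
- **Parallel tempering** runs 10 replicas at fixed temperatures equally
  spaced (linearly) in [1e-8, 1e-4], each accepting a move with
  probability 1 if Δ > 0 and `exp(Δ/t)` otherwise — ties are therefore
  accepted, which lets replicas drift across plateaus (e.g. among
  duplicate accessions). After every 500 steps per replica, adjacent
  pairs (cold to hot, one pass) exchange their current selections with
  probability 1 if the hotter replica is better, else
  `exp((1/t_r − 1/t_{r+1})Δ_r)`. Replicas are executed sequentially in
  a fixed round-robin schedule with per-replica sub-streams, so results
  are bit-reproducible; the schedule is equivalent to concurrent
  replicas synchronizing at exchange barriers.
- **Genetic algorithm**: population 25; per generation 5 children, each
  from two tournament-of-5 parents, crossover by sampling `k`
  accessions uniformly without replacement from the union of the
  parents' selections, mutation by random descent until 5000
  consecutive proposals fail to improve; then roulette discard of 5
  solutions with weight `1/F` (scores are shifted by `|min F| + 1e-9`
  first when any is non-positive, since `1/F` is undefined there),
  keeping the population at 25.
- **Brute force** enumerates all subsets (guarded at 1e6) in
  lexicographic order, keeping strict improvements, so ties resolve to
  the lexicographically smallest index set. It is the oracle in tests,
  never a production path.

Stop conditions combine wall-clock limits, time-without-improvement
(default 10 s in the CLI), and evaluation-count limits; the count-based
conditions make tests and benchmarks machine-independent. Proposed
moves count as evaluations; initial evaluations are free, so a
zero-evaluation budget returns the evaluated random start.

**Incremental evaluation.** Engines probe 1e5–1e7 neighbours, so each
measure keeps a per-swap cache: nearest and recomputed-on-invalidation
nearest-other-entry per core member (E-NE), nearest core entry per
accession (A-NE), allele-frequency sums and per-locus observation
counts (HE), and the running pair sum (avg-EE). Patches pick exact
matrix entries, so the caches do not drift (HE sums accumulate at most
~1e-14 over 1e3 swaps); agreement with full re-evaluation to 1e-12 is
asserted in the tests. The hot kernels are numba-jitted when numba is
importable, with an equivalent vectorized numpy fallback that tests
cross-check against the kernels.

## Baselines

**GDOpt** clusters the distance matrix with PAM (BUILD then best-
improvement SWAP) into `k` clusters and selects the medoids. By
definition its A-NE equals PAM cost / n. PAM is exchange-locally
optimal; on tiny non-metric random matrices this occasionally differs
from the exhaustive k-medoids optimum, which is inherent to the
algorithm, not a defect — on clustered instances it matches.

**SimEli** eliminates, `n − k` times, one member of the currently
closest remaining pair: the candidate whose removal leaves the higher
criterion value, where the criterion is the mean distance from the
candidate to the remaining accessions excluding the pair partner
(A-RA), or the expected heterozygosity of the reduced collection (HE).
Closest-pair ties resolve to the lexicographically smallest pair and
criterion ties eliminate the lower index, for determinism.

## Synthetic data

The generators emulate the structure of typical panels rather than any
particular dataset: biallelic SNP matrices (per-locus population
frequency from Beta(s, s), dosages Binomial(2, p); `s → 0` drives loci
monomorphic), multiallelic SSR panels (2–10 alleles per locus,
Dirichlet(s) population frequencies, two sampled allele copies per
accession), trait tables with 28 qualitative and 11 quantitative
columns by default, planted groups of exact duplicates, and raw
symmetric distance matrices, optionally with latent clusters whose
between-group distances (0.5–1.0) always exceed within-group ones
(0.02–0.15). Missing data are planted at a configurable rate with one
always-observed anchor locus so every pair shares data. Uniform random
matrices deliberately ignore the triangle inequality: the nearest-entry
measures read entries directly and metricity is never assumed.

What passing tests on these data do *not* show: behaviour under linkage
disequilibrium, pedigree or population structure, genotyping error, or
the marker ascertainment of real panels. The generators provide known
ground truth (planted optima, duplicates, cluster structure), not
population-genetic realism.

## Benchmark problem sizes

The repeated-run experiments use sizes chosen so that every engine
passes its convergence knee while the whole suite stays desk-scale:

- oracle suite: 30 clustered instances, n = 12, k = 4 (495 subsets
  enumerable), 5e4 evaluations per run;
- engine comparison: one synthetic SNP panel, n = 500, L = 200,
  k = 100 (20%), 10 runs per engine at an equal budget of 5e5
  evaluations — random descent stalls near 1.5e5 evaluations on this
  instance, so the budget leaves all engines well past their last
  improvement regime;
- duplicate recovery: n = 12 with 4 planted triplets, k = 4;
- weight sweep vs SimEli: one SSR panel, n = 200, k = 40 (20%),
  21 weights at step 0.05, 3e4 evaluations per run.

## Known limitations

- Distance matrices are dense `n × n` float64; collections beyond
  ~2e4 accessions need a precomputed-distance workflow and memory.
- PT temperatures are fixed constants tuned to score scales of order
  1; they are appropriate for raw distances in [0, 1] and normalized
  indexes, but a user optimizing an unnormalized measure on a very
  different scale should rescale or adjust the range.
- The genetic algorithm's roulette shift constant (1e-9) is arbitrary
  where fitness is non-positive; normalized indexes are non-negative in
  practice so the path is rarely taken.
- SimEli recomputes the closest pair by masked scan each step, O(n²)
  per elimination; fine to a few thousand accessions, not beyond.
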