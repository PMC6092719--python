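# coreselect

Fixed-size core subset selection for germplasm collections.

Genebanks and breeding programs often need a *core collection*: a subset
of `k` accessions out of `n` that represents the diversity of the whole
collection with minimum redundancy. `coreselect` samples such cores from
genotypes (allele frequencies or SNP dosages), phenotypic traits, a
precomputed distance matrix, or any combination, by direct optimization
of the evaluation measure of interest.

## Measures and model

Given pairwise distances `d(i, j)` (Modified Roger's for markers,
Gower's for mixed traits, or user-supplied) and a core `C` of size `k`
from a collection `A` of size `n`:

- **E-NE** (entry-to-nearest-entry), maximized for diversity:
  `(1/k) Σ_{i∈C} min_{j∈C, j≠i} d(i, j)`
- **A-NE** (accession-to-nearest-entry), minimized for
  representativeness: `(1/n) Σ_{a∈A} min_{j∈C} d(a, j)`
- **HE** (expected heterozygosity), maximized for allelic richness:
  `(1/L) Σ_l (1 − Σ_a p̂²_la)` with `p̂_la` the mean allele frequencies
  over core entries
- **DMIN** (minimum pairwise distance in the core) and **avg-EE** (mean
  pairwise distance) are reported; DMIN is never optimized directly —
  its landscape is too flat for local search, but maximizing E-NE drags
  it up indirectly.

Several measures combine into a weighted index `F = Σ α_i F'_i`
(`Σ α_i = 1`, minimized measures sign-flipped), with each measure
normalized to [0, 1] by per-measure bounds: the best single-objective
value (upper) and the Pareto minimum over the single-objective optima
(lower).

The optimizers move through the single-swap neighbourhood (replace one
selected accession by an unselected one): **random descent** (strict
improvement hill-climber), **parallel tempering** (10 Metropolis
replicas at temperatures equally spaced in [1e-8, 1e-4], exchanging
solutions every 500 steps per replica — the default), and a **genetic
algorithm** (tournament selection, union crossover, random-descent
mutation, inverse-fitness roulette survival). PAM-based **GDOpt** and
**SimEli** iterated elimination are included as baselines, and a
brute-force enumerator serves as an exact oracle on small instances.

## Worked example

Simulate a SNP panel of 100 accessions and sample a 20% core maximizing
E-NE with parallel tempering:

```
$ coreselect simulate --kind snp --n 100 --loci 200 --seed 7 --out snp100.csv
wrote snp dataset with n=100 to snp100.csv

$ coreselect sample --genotypes snp100.csv --genotype-dialect frequency \
      --fraction 0.2 --method pt --seed 1 --max-evals 100000 --out core.txt
best value 0.361767 after 100000 evaluations
  E-NE: 0.361767
  DMIN: 0.351781
```

`core.txt` lists the 20 selected accession ids after a header with the
evaluated measures: the chosen core has a mean nearest-entry distance
(E-NE, Modified Roger's scale, 0–1) of 0.3618, and even the two closest
selected accessions are 0.3518 apart (DMIN), i.e. no near-duplicates
were selected. Same seed, same core — every run is reproducible.

The same machinery is available from Python:

```python
from coreselect import (Dataset, Objective, ObjectiveConfig, StopCondition,
                        parallel_tempering, read_genotypes)

dataset = Dataset(genotypes=read_genotypes("snp100.csv", dialect="frequency"))
result = parallel_tempering(
    dataset, ObjectiveConfig([Objective("E-NE")]), k=20,
    stop=StopCondition(max_evals=100_000), seed=1,
)
print(sorted(result.core.ids(dataset.accession_ids))[:3], result.value)
```

Other subcommands: `coreselect sweep` (Pareto weight sweep over two
objectives), `coreselect compare` (repeated seeded engine comparison),
`coreselect simulate` (synthetic SNP/SSR/trait/distance data).

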