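"""Seeded generators for synthetic collections.

The generators emulate the structural features of typical germplasm
panels: biallelic SNP matrices (maize-like, ~10^2 accessions x
10^2-10^3 markers), multiallelic SSR panels with 2-10 alleles per locus
(coconut-like, ~30 loci), mixed trait tables with 28 qualitative and 11
quantitative traits (rice-like), planted groups of exact duplicate
accessions, and raw distance matrices with or without latent cluster
structure. They produce valid containers bit-identically for equal
seeds; they do not attempt population-genetic realism (no linkage,
drift or pedigree structure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    DataError,
    DistanceMatrix,
    GenotypeMatrix,
    Locus,
    PhenotypeTable,
    QUALITATIVE,
    QUANTITATIVE,
    Trait,
)

SNP = "biallelic-SNP"
SSR = "multiallelic-SSR"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic collection.

    ``freq_prior_spread`` is the symmetric concentration of the
    per-locus population allele-frequency prior (Beta(s, s) for SNPs,
    Dirichlet(s, ..., s) for SSRs): small values push loci toward
    monomorphism, large values toward balanced frequencies. Defaults
    give a mid-sized panel with intermediate frequency spread and no
    missing data.
    """

    n: int = 100
    marker_model: str = SNP
    n_loci: int = 200
    alleles_range: tuple[int, int] = (2, 10)
    freq_prior_spread: float = 0.5
    missing_rate: float = 0.0
    n_qualitative: int = 28
    n_quantitative: int = 11
    categories_range: tuple[int, int] = (2, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise DataError("need n >= 3 accessions")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise DataError("missing rate must lie in [0, 1]")
        if self.marker_model not in (SNP, SSR):
            raise DataError(f"unknown marker model {self.marker_model!r}")
        if self.freq_prior_spread <= 0:
            raise DataError("freq_prior_spread must be positive")


def _accession_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"acc{str(i).zfill(width)}" for i in range(n)]


def generate_genotypes(spec: SyntheticSpec) -> GenotypeMatrix:
    """Sample a genotype matrix under the spec's marker model."""
    rng = np.random.default_rng(spec.seed)
    ids = _accession_ids(spec.n)
    s = spec.freq_prior_spread
    if spec.marker_model == SNP:
        p = rng.beta(s, s, size=spec.n_loci)
        dosages = rng.binomial(2, p[None, :], size=(spec.n, spec.n_loci)).astype(float)
        dosages = _mask_missing(dosages, spec.missing_rate, rng)
        return GenotypeMatrix.from_dosages(ids, [f"m{l}" for l in range(spec.n_loci)], dosages)
    lo, hi = spec.alleles_range
    loci: list[Locus] = []
    blocks: list[np.ndarray] = []
    for l in range(spec.n_loci):
        n_alleles = int(rng.integers(lo, hi + 1))
        pop = rng.dirichlet(np.full(n_alleles, s))
        # each accession carries two allele copies at an SSR locus
        counts = rng.multinomial(2, pop, size=spec.n).astype(float)
        blocks.append(counts / 2.0)
        loci.append(Locus(f"ssr{l}", tuple(f"a{j}" for j in range(n_alleles))))
    freq = np.hstack(blocks)
    if spec.missing_rate > 0:
        miss = rng.random((spec.n, spec.n_loci)) < spec.missing_rate
        miss[:, 0] = False  # keep one locus shared by every pair
        offsets = np.cumsum([0] + [len(l.alleles) for l in loci])
        for l in range(spec.n_loci):
            freq[miss[:, l], offsets[l] : offsets[l + 1]] = np.nan
    return GenotypeMatrix(ids, loci, freq)


def _mask_missing(values: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return values
    miss = rng.random(values.shape) < rate
    miss[:, 0] = False  # keep one column shared by every pair
    out = values.copy()
    out[miss] = np.nan
    return out


def generate_phenotypes(spec: SyntheticSpec) -> PhenotypeTable:
    """Sample a mixed qualitative/quantitative trait table."""
    rng = np.random.default_rng(spec.seed)
    ids = _accession_ids(spec.n)
    traits: list[Trait] = []
    columns: dict[str, object] = {}
    lo, hi = spec.categories_range
    for t in range(spec.n_qualitative):
        n_cat = int(rng.integers(lo, hi + 1))
        values = np.array([f"cat{c}" for c in rng.integers(0, n_cat, size=spec.n)], dtype=object)
        name = f"qual{t}"
        columns[name] = values
        traits.append(Trait(name, QUALITATIVE))
    for t in range(spec.n_quantitative):
        scale = float(rng.uniform(1.0, 100.0))
        values = rng.uniform(0.0, scale, size=spec.n)
        name = f"quant{t}"
        columns[name] = values
        obs = values
        traits.append(Trait(name, QUANTITATIVE, (float(obs.min()), float(obs.max()))))
    df = pd.DataFrame(columns, index=ids)
    if spec.missing_rate > 0:
        miss = rng.random(df.shape) < spec.missing_rate
        miss[:, 0] = False
        df = df.mask(pd.DataFrame(miss, index=df.index, columns=df.columns))
        # ranges may shrink after masking; recompute quantitative ranges
        return PhenotypeTable.from_values(ids, {t.name: t.kind for t in traits}, df)
    return PhenotypeTable(ids, traits, df)


def inject_duplicates(
    data: GenotypeMatrix | PhenotypeTable,
    groups: int,
    copies: int,
    seed: int = 0,
):
    """Plant groups of exact duplicate accessions into a collection.

    Picks ``groups * copies`` accessions at random; within each group,
    every member becomes an exact copy of the group's first member, so
    all within-group distances are zero under any measure. Returns the
    modified data and a mapping group index -> member accession indices.
    """
    n = data.n
    if groups * copies > n:
        raise DataError(f"{groups} groups x {copies} copies exceed n={n}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=groups * copies, replace=False)
    group_map = {g: sorted(chosen[g * copies : (g + 1) * copies].tolist()) for g in range(groups)}
    if isinstance(data, GenotypeMatrix):
        freq = data.frequencies.copy()
        for members in group_map.values():
            freq[members[1:]] = freq[members[0]]
        return GenotypeMatrix(data.accession_ids, data.loci, freq), group_map
    values = data.values.copy()
    for members in group_map.values():
        for m in members[1:]:
            values.iloc[m] = values.iloc[members[0]]
    return PhenotypeTable(data.accession_ids, data.traits, values), group_map


def generate_distance_matrix(
    n: int,
    seed: int = 0,
    structure: str = "uniform",
    n_groups: int = 4,
) -> DistanceMatrix:
    """Sample a symmetric random distance matrix in [0, 1].

    ``clustered`` places accessions in latent balanced groups with
    within-group distances in [0.02, 0.15] and between-group distances
    in [0.5, 1.0], so the smallest between-group distance always exceeds
    the largest within-group distance. Triangle inequality is not
    enforced: the nearest-entry measures read entries directly.
    """
    if n < 3:
        raise DataError("need n >= 3")
    rng = np.random.default_rng(seed)
    if structure == "uniform":
        d = rng.uniform(0.0, 1.0, size=(n, n))
    elif structure == "clustered":
        labels = np.arange(n) % n_groups
        same = labels[:, None] == labels[None, :]
        within = rng.uniform(0.02, 0.15, size=(n, n))
        between = rng.uniform(0.5, 1.0, size=(n, n))
        d = np.where(same, within, between)
    else:
        raise ValueError(f"unknown structure {structure!r}")
    d = np.triu(d, 1)
    d = d + d.T
    return DistanceMatrix(_accession_ids(n), d)
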