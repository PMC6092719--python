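"""Pairwise dissimilarity measures.

Modified Roger's distance compares allele-frequency profiles,

    MR(i, j) = sqrt( sum_l sum_a (p_ila - p_jla)^2 / (2 L) ),

with ``L`` replaced by the number of loci observed in both accessions
when data are missing (pairwise deletion). Gower's distance averages
per-trait dissimilarities over mutually observed traits: range-scaled
absolute differences for quantitative traits, 0/1 matching for
qualitative traits. Both measures map into [0, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import (
    QUANTITATIVE,
    DataError,
    Dataset,
    DistanceMatrix,
    GenotypeMatrix,
    PhenotypeTable,
)

MODIFIED_ROGERS = "modified_rogers"
GOWER = "gower"
PRECOMPUTED = "precomputed"


def modified_rogers(geno: GenotypeMatrix, i: int, j: int) -> float:
    """Modified Roger's distance between accessions ``i`` and ``j``."""
    if i == j:
        raise ValueError("i and j must differ")
    shared = geno.observed[i] & geno.observed[j]
    if not shared.any():
        raise DataError(f"accessions {i} and {j} share no observed locus")
    sq = 0.0
    for l in np.flatnonzero(shared):
        diff = geno.locus_frequencies(i, int(l)) - geno.locus_frequencies(j, int(l))
        sq += float(diff @ diff)
    return min(np.sqrt(sq / (2.0 * shared.sum())), 1.0)


def modified_rogers_matrix(geno: GenotypeMatrix) -> DistanceMatrix:
    """Full Modified Roger's matrix, vectorized with pairwise deletion."""
    x = np.nan_to_num(geno.frequencies)
    obs = geno.observed.astype(float)
    # per-locus squared norms of each accession's frequency vector
    locus_sq = np.add.reduceat(x * x, geno.offsets[:-1], axis=1)
    cross = x @ x.T
    norm_part = locus_sq @ obs.T  # (i, j): sum over loci observed in j of |x_il|^2
    shared = obs @ obs.T
    if np.any(shared[~np.eye(geno.n, dtype=bool)] == 0):
        raise DataError("an accession pair shares no observed locus")
    with np.errstate(invalid="ignore", divide="ignore"):
        sq = (norm_part + norm_part.T - 2.0 * cross) / (2.0 * shared)
    d = np.sqrt(np.clip(sq, 0.0, 1.0))
    d = np.triu(d, 1)
    d = d + d.T
    return DistanceMatrix(geno.accession_ids, d)


def gower(pheno: PhenotypeTable, i: int, j: int) -> float:
    """Gower's mixed-type dissimilarity between accessions ``i`` and ``j``."""
    if i == j:
        raise ValueError("i and j must differ")
    num = 0.0
    cnt = 0
    for t in pheno.traits:
        xi = pheno.values[t.name].iloc[i]
        xj = pheno.values[t.name].iloc[j]
        if pd.isna(xi) or pd.isna(xj):
            continue
        cnt += 1
        if t.kind == QUANTITATIVE:
            width = t.range[1] - t.range[0]
            if width > 0:
                num += abs(float(xi) - float(xj)) / width
        else:
            num += 0.0 if xi == xj else 1.0
    if cnt == 0:
        raise DataError(f"accessions {i} and {j} share no observed trait")
    return min(num / cnt, 1.0)


def gower_matrix(pheno: PhenotypeTable) -> DistanceMatrix:
    """Full Gower matrix, accumulated trait by trait."""
    n = pheno.n
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for t in pheno.traits:
        col = pheno.values[t.name]
        if t.kind == QUANTITATIVE:
            v = col.to_numpy(dtype=float)
            obs = ~np.isnan(v)
            width = t.range[1] - t.range[0]
            contrib = (
                np.abs(v[:, None] - v[None, :]) / width if width > 0 else np.zeros((n, n))
            )
        else:
            codes = pd.Categorical(col).codes  # -1 for missing
            obs = codes >= 0
            contrib = (codes[:, None] != codes[None, :]).astype(float)
        both = obs[:, None] & obs[None, :]
        num += np.where(both, contrib, 0.0)
        cnt += both
    off = ~np.eye(n, dtype=bool)
    if np.any(cnt[off] == 0):
        raise DataError("an accession pair shares no observed trait")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(cnt > 0, num / np.maximum(cnt, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    d = np.clip(np.triu(d, 1), 0.0, 1.0)
    d = d + d.T
    return DistanceMatrix(pheno.accession_ids, d)


def pairwise_matrix(dataset: Dataset, kind: str) -> DistanceMatrix:
    """Distance matrix of the requested kind from the matching component."""
    if kind == MODIFIED_ROGERS:
        if dataset.genotypes is None:
            raise DataError("modified_rogers requires genotype data")
        return modified_rogers_matrix(dataset.genotypes)
    if kind == GOWER:
        if dataset.phenotypes is None:
            raise DataError("gower requires phenotype data")
        return gower_matrix(dataset.phenotypes)
    if kind == PRECOMPUTED:
        if dataset.distances is None:
            raise DataError("no precomputed distance matrix in dataset")
        return dataset.distances
    raise ValueError(f"unknown distance kind {kind!r}")


def resolve_distance(dataset: Dataset, source: str = "auto") -> DistanceMatrix:
    """Distance matrix for a data source, computed once and cached.

    ``auto`` prefers a precomputed matrix, then genotypes (Modified
    Roger's), then phenotypes (Gower).
    """
    if source == "auto":
        if dataset.distances is not None:
            source = PRECOMPUTED
        elif dataset.genotypes is not None:
            source = MODIFIED_ROGERS
        elif dataset.phenotypes is not None:
            source = GOWER
    aliases = {"genotype": MODIFIED_ROGERS, "phenotype": GOWER, "distance": PRECOMPUTED}
    source = aliases.get(source, source)
    if source not in dataset._resolved:
        dataset._resolved[source] = pairwise_matrix(dataset, source)
    return dataset._resolved[source]
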