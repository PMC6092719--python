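"""Baseline core selection strategies: GDOpt and SimEli.

GDOpt clusters the collection with PAM (partitioning around medoids,
BUILD + SWAP phases) into ``k`` clusters and selects the medoids as the
core; it targets representativeness, and by construction the A-NE of
its core equals the PAM cost divided by ``n``.

SimEli repeatedly finds the two most similar remaining accessions and
eliminates one of them — the one whose removal leaves the higher value
of the chosen criterion: mean distance to the remaining accessions
(A-RA) or expected heterozygosity of the reduced collection (HE) —
until ``k`` accessions remain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import CoreSubset, DataError, Dataset, DistanceMatrix
from .distances import resolve_distance

A_RA = "A-RA"
HE_CRITERION = "HE"


def pam_kmedoids(
    d: DistanceMatrix, k: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """PAM k-medoids clustering of a distance matrix.

    BUILD greedily adds the medoid that most reduces the total
    point-to-nearest-medoid distance; SWAP repeatedly performs the best
    improving medoid/non-medoid exchange until none remains. Returns
    (sorted medoid indices, per-point medoid assignment, total cost).
    The algorithm is deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic engines.
    """
    dm = d.d
    n = dm.shape[0]
    if not 1 <= k <= n:
        raise DataError(f"cluster count k={k} must satisfy 1 <= k <= {n}")
    is_medoid = np.zeros(n, dtype=bool)
    # BUILD
    first = int(dm.sum(axis=1).argmin())
    is_medoid[first] = True
    dn = dm[:, first].copy()
    for _ in range(k - 1):
        cand = np.flatnonzero(~is_medoid)
        gains = np.maximum(dn[:, None] - dm[:, cand], 0.0).sum(axis=0)
        best = cand[int(gains.argmax())]
        is_medoid[best] = True
        dn = np.minimum(dn, dm[:, best])
    # SWAP
    while True:
        medoids = np.flatnonzero(is_medoid)
        others = np.flatnonzero(~is_medoid)
        if others.size == 0:
            break
        sub = dm[:, medoids]
        order = np.argsort(sub, axis=1, kind="stable")
        dn = sub[np.arange(n), order[:, 0]]
        nearest = medoids[order[:, 0]]
        ds = (
            sub[np.arange(n), order[:, 1]]
            if k > 1
            else np.full(n, np.inf)
        )
        d_others = dm[:, others]
        base = np.minimum(d_others - dn[:, None], 0.0).sum(axis=0)
        best_delta = 0.0
        best_pair: tuple[int, int] | None = None
        for mi, m in enumerate(medoids):
            mask = nearest == m
            if mask.any():
                block = d_others[mask]
                removed_part = np.minimum(block - dn[mask, None], 0.0).sum(axis=0)
                new_part = (np.minimum(block, ds[mask, None]) - dn[mask, None]).sum(axis=0)
                deltas = base - removed_part + new_part
            else:
                deltas = base
            hi = int(deltas.argmin())
            if deltas[hi] < best_delta - 1e-12:
                best_delta = float(deltas[hi])
                best_pair = (int(m), int(others[hi]))
        if best_pair is None:
            break
        is_medoid[best_pair[0]] = False
        is_medoid[best_pair[1]] = True
    medoids = np.flatnonzero(is_medoid)
    sub = dm[:, medoids]
    assignment = medoids[sub.argmin(axis=1)]
    cost = float(sub.min(axis=1).sum())
    return medoids, assignment, cost


def gdopt_select(dataset: Dataset, k: int, seed: int | None = None) -> CoreSubset:
    """GDOpt: select the k PAM medoids as the core collection."""
    if k < 2:
        raise DataError("core size must be at least 2")
    d = resolve_distance(dataset, "auto")
    medoids, _, _ = pam_kmedoids(d, k, seed)
    core = CoreSubset(medoids.tolist())
    core.validate_for(dataset.n)
    return core


@dataclass(frozen=True)
class Elimination:
    """One SimEli step: the closest pair considered and the loser."""

    pair: tuple[int, int]
    eliminated: int


def simeli_select(
    dataset: Dataset,
    k: int,
    criterion: str = A_RA,
    seed: int | None = None,
    return_trace: bool = False,
):
    """SimEli: iterated elimination from the closest remaining pair.

    At each of the ``n - k`` steps the globally closest remaining pair
    (i, j) is found (ties toward the lexicographically smallest pair)
    and the member whose removal leaves the higher criterion value is
    eliminated (criterion ties eliminate the lower index).
    """
    n = dataset.n
    if not 2 <= k <= n - 1:
        raise DataError(f"core size k={k} must satisfy 2 <= k <= n - 1")
    if criterion not in (A_RA, HE_CRITERION):
        raise ValueError(f"unknown elimination criterion {criterion!r}")
    d = resolve_distance(dataset, "auto").d
    if criterion == HE_CRITERION:
        geno = dataset.genotypes
        if geno is None:
            raise DataError("the HE elimination criterion requires genotype data")
        freq0 = np.nan_to_num(geno.frequencies)
        obs = geno.observed.astype(np.int64)
        sums = freq0.sum(axis=0)
        counts = obs.sum(axis=0)
        locus_of_allele = np.repeat(np.arange(geno.n_loci), np.diff(geno.offsets))

        def he_without(x: int) -> float:
            s = sums - freq0[x]
            c = counts - obs[x]
            valid = c > 0
            if not valid.any():
                raise DataError("no locus observed in the reduced collection")
            per_allele = c[locus_of_allele]
            p = np.divide(s, per_allele, out=np.zeros_like(s), where=per_allele > 0)
            locus_sq = np.add.reduceat(p * p, geno.offsets[:-1])
            return float(np.mean(1.0 - locus_sq[valid]))

    work = d.copy()
    np.fill_diagonal(work, np.inf)
    remaining = np.ones(n, dtype=bool)
    trace: list[Elimination] = []
    for _ in range(n - k):
        flat = int(work.argmin())
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        if criterion == A_RA:
            others = remaining.copy()
            others[[i, j]] = False
            score_i = float(d[i, others].mean())
            score_j = float(d[j, others].mean())
            loser = i if score_i <= score_j else j
        else:
            loser = i if he_without(i) >= he_without(j) else j
        remaining[loser] = False
        work[loser, :] = np.inf
        work[:, loser] = np.inf
        if criterion == HE_CRITERION:
            sums -= freq0[loser]
            counts -= obs[loser]
        trace.append(Elimination(pair=(i, j), eliminated=loser))
    core = CoreSubset(np.flatnonzero(remaining).tolist())
    if return_trace:
        return core, trace
    return core
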