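"""Hot inner-loop kernels for swap-incremental evaluation.

Compiled with numba when available; the evaluator classes fall back to
vectorized numpy updates otherwise. Both paths implement the same
update rules and are cross-checked against full re-evaluation in tests.
"""

from __future__ import annotations

import numpy as np

try:  # optional acceleration
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def ene_apply(d, sel, nn_idx, nn_dist, removed, added, pos):
    """Patch the nearest-other-entry cache after swapping sel[pos]."""
    k = sel.shape[0]
    best = np.inf
    bidx = -1
    for p in range(k):
        if p == pos:
            continue
        v = d[added, sel[p]]
        if v < best:
            best = v
            bidx = sel[p]
    nn_dist[pos] = best
    nn_idx[pos] = bidx
    total = nn_dist[pos]
    for p in range(k):
        if p == pos:
            continue
        m = sel[p]
        if nn_idx[p] == removed:
            best = np.inf
            bidx = -1
            for q in range(k):
                if q == p:
                    continue
                v = d[m, sel[q]]
                if v < best:
                    best = v
                    bidx = sel[q]
            nn_dist[p] = best
            nn_idx[p] = bidx
        else:
            v = d[m, added]
            if v < nn_dist[p]:
                nn_dist[p] = v
                nn_idx[p] = added
        total += nn_dist[p]
    return total / k


@njit(cache=True)
def ane_apply(d, sel, nn_idx, nn_dist, removed, added):
    """Patch the nearest-core-entry cache for every accession."""
    n = d.shape[0]
    k = sel.shape[0]
    total = 0.0
    for x in range(n):
        v = d[x, added]
        if v < nn_dist[x]:
            nn_dist[x] = v
            nn_idx[x] = added
        elif nn_idx[x] == removed:
            best = np.inf
            bidx = -1
            for q in range(k):
                vv = d[x, sel[q]]
                if vv < best:
                    best = vv
                    bidx = sel[q]
            nn_dist[x] = best
            nn_idx[x] = bidx
        total += nn_dist[x]
    return total / n


@njit(cache=True)
def he_value_uniform(sums, offsets, k):
    """HE from allele-frequency sums when every locus is fully observed."""
    n_loci = offsets.shape[0] - 1
    total = 0.0
    for l in range(n_loci):
        sq = 0.0
        for a in range(offsets[l], offsets[l + 1]):
            p = sums[a] / k
            sq += p * p
        total += 1.0 - sq
    return total / n_loci


@njit(cache=True)
def he_value_masked(sums, counts, offsets):
    """HE from sums and per-locus observation counts under missing data."""
    n_loci = offsets.shape[0] - 1
    total = 0.0
    valid = 0
    for l in range(n_loci):
        c = counts[l]
        if c <= 0:
            continue
        sq = 0.0
        for a in range(offsets[l], offsets[l + 1]):
            p = sums[a] / c
            sq += p * p
        total += 1.0 - sq
        valid += 1
    if valid == 0:
        return np.nan
    return total / valid
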