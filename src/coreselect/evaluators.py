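"""Incrementally updated objective evaluation under single-swap moves.

The search engines probe on the order of 10^5-10^7 single-swap
neighbours, so each measure keeps a small cache that is patched per swap
instead of re-evaluated from scratch:

* E-NE: nearest other entry (index and distance) per core entry;
* A-NE: nearest core entry per accession of the whole collection;
* HE: per-allele frequency sums and per-locus observation counts over
  the core;
* avg-EE: the running sum over selected pairs.

Patched values are exact (they pick actual matrix entries), so a swap
followed by its reverse restores the state; agreement with full
re-evaluation is guarded by tests.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .datamodel import DataError, Dataset
from .distances import resolve_distance
from .objectives import (
    ANE,
    AVG_EE,
    DMIN,
    ENE,
    GENOTYPE_MEASURES,
    NormalizationRanges,
    ObjectiveConfig,
)


class _EntryNearestState:
    """E-NE cache: nearest other core entry per selected accession."""

    def __init__(self, d: np.ndarray) -> None:
        self.d = d
        self.nn_idx: np.ndarray | None = None
        self.nn_dist: np.ndarray | None = None

    def reset(self, sel: np.ndarray) -> float:
        sub = self.d[np.ix_(sel, sel)].copy()
        np.fill_diagonal(sub, np.inf)
        am = sub.argmin(axis=1)
        self.nn_dist = sub[np.arange(sel.size), am]
        self.nn_idx = sel[am]
        self.value = float(self.nn_dist.sum() / sel.size)
        return self.value

    def apply(self, removed: int, added: int, pos: int, sel: np.ndarray) -> float:
        if _kernels.HAVE_NUMBA:
            self.value = float(
                _kernels.ene_apply(self.d, sel, self.nn_idx, self.nn_dist, removed, added, pos)
            )
            return self.value
        return self._apply_numpy(removed, added, pos, sel)

    def _apply_numpy(self, removed: int, added: int, pos: int, sel: np.ndarray) -> float:
        d, nn_idx, nn_dist = self.d, self.nn_idx, self.nn_dist
        k = sel.size
        # the new entry's nearest neighbour
        row = d[added, sel].copy()
        row[pos] = np.inf
        p = int(row.argmin())
        nn_dist[pos] = row[p]
        nn_idx[pos] = sel[p]
        # entries whose cached nearest neighbour left the core
        stale = nn_idx == removed
        stale[pos] = False
        if stale.any():
            where = np.flatnonzero(stale)
            sub = d[np.ix_(sel[where], sel)]
            sub[np.arange(where.size), where] = np.inf
            am = sub.argmin(axis=1)
            nn_dist[where] = sub[np.arange(where.size), am]
            nn_idx[where] = sel[am]
        # remaining entries: the new entry may be closer than the cache
        da = d[sel, added]
        fresh = ~stale
        fresh[pos] = False
        better = fresh & (da < nn_dist)
        if better.any():
            nn_dist[better] = da[better]
            nn_idx[better] = added
        self.value = float(nn_dist.sum() / k)
        return self.value


class _AccessionNearestState:
    """A-NE cache: nearest core entry per accession of the collection."""

    def __init__(self, d: np.ndarray) -> None:
        self.d = d
        self.n = d.shape[0]

    def reset(self, sel: np.ndarray) -> float:
        sub = self.d[:, sel]
        am = sub.argmin(axis=1)
        self.nn_dist = sub[np.arange(self.n), am]
        self.nn_idx = sel[am]
        self.value = float(self.nn_dist.sum() / self.n)
        return self.value

    def apply(self, removed: int, added: int, pos: int, sel: np.ndarray) -> float:
        if _kernels.HAVE_NUMBA:
            self.value = float(
                _kernels.ane_apply(self.d, sel, self.nn_idx, self.nn_dist, removed, added)
            )
            return self.value
        return self._apply_numpy(removed, added, sel)

    def _apply_numpy(self, removed: int, added: int, sel: np.ndarray) -> float:
        d = self.d
        da = d[:, added]
        better = da < self.nn_dist
        if better.any():
            self.nn_dist[better] = da[better]
            self.nn_idx[better] = added
        stale = self.nn_idx == removed
        if stale.any():
            where = np.flatnonzero(stale)
            sub = d[np.ix_(where, sel)]
            am = sub.argmin(axis=1)
            self.nn_dist[where] = sub[np.arange(where.size), am]
            self.nn_idx[where] = sel[am]
        self.value = float(self.nn_dist.sum() / self.n)
        return self.value


class _HeterozygosityState:
    """HE cache: allele-frequency sums and observation counts over the core."""

    def __init__(self, geno) -> None:
        self.freq0 = np.nan_to_num(geno.frequencies)  # zero-filled
        self.obs = geno.observed.astype(np.int64)
        self.offsets = geno.offsets
        self.locus_of_allele = np.repeat(
            np.arange(geno.n_loci), np.diff(geno.offsets)
        )
        self.all_observed = bool(geno.observed.all())

    def reset(self, sel: np.ndarray) -> float:
        self.sums = self.freq0[sel].sum(axis=0)
        self.counts = self.obs[sel].sum(axis=0)
        return self._value(sel.size)

    def apply(self, removed: int, added: int, pos: int, sel: np.ndarray) -> float:
        self.sums += self.freq0[added] - self.freq0[removed]
        self.counts += self.obs[added] - self.obs[removed]
        return self._value(sel.size)

    def _value(self, k: int) -> float:
        if _kernels.HAVE_NUMBA:
            if self.all_observed:
                self.value = float(_kernels.he_value_uniform(self.sums, self.offsets, k))
                return self.value
            if not (self.counts > 0).any():
                raise DataError("no locus observed in any core entry")
            self.value = float(_kernels.he_value_masked(self.sums, self.counts, self.offsets))
            return self.value
        if self.all_observed:
            p = self.sums / k
            locus_sq = np.add.reduceat(p * p, self.offsets[:-1])
            self.value = float(1.0 - locus_sq.mean())
            return self.value
        counts = self.counts
        valid = counts > 0
        if not valid.any():
            raise DataError("no locus observed in any core entry")
        per_allele = counts[self.locus_of_allele]
        p = np.divide(self.sums, per_allele, out=np.zeros_like(self.sums), where=per_allele > 0)
        locus_sq = np.add.reduceat(p * p, self.offsets[:-1])
        self.value = float(np.mean(1.0 - locus_sq[valid]))
        return self.value


class _AvgEntryToEntryState:
    """avg-EE cache: running sum over selected pairs."""

    def __init__(self, d: np.ndarray) -> None:
        self.d = d

    def reset(self, sel: np.ndarray) -> float:
        sub = self.d[np.ix_(sel, sel)]
        self.pair_sum = float(sub.sum() / 2.0)
        self.k = sel.size
        self.value = self.pair_sum / (self.k * (self.k - 1) / 2.0)
        return self.value

    def apply(self, removed: int, added: int, pos: int, sel: np.ndarray) -> float:
        gained = float(self.d[added, sel].sum())
        lost = float(self.d[removed, sel].sum()) - float(self.d[removed, added])
        self.pair_sum += gained - lost
        self.value = self.pair_sum / (self.k * (self.k - 1) / 2.0)
        return self.value


_DISTANCE_STATES = {
    ENE: _EntryNearestState,
    ANE: _AccessionNearestState,
    AVG_EE: _AvgEntryToEntryState,
}


class CompositeEvaluator:
    """Swap-aware evaluator of an objective configuration on one dataset.

    Owns the current selection (``sel``/``unsel`` index arrays) and one
    incremental state per objective. ``swap`` applies a move and returns
    the new scalar score (sign-adjusted raw value for a single
    unnormalized objective, otherwise the normalized weighted index);
    ``revert`` undoes the last swap.
    """

    def __init__(
        self,
        dataset: Dataset,
        objectives: ObjectiveConfig,
        ranges: NormalizationRanges | None = None,
    ) -> None:
        self.dataset = dataset
        self.objectives = objectives
        self.ranges = ranges
        if len(objectives) > 1 and ranges is None:
            raise DataError("multiple objectives require normalization ranges")
        self.states: list = []
        for obj in objectives:
            if obj.measure == DMIN:
                raise DataError(
                    "DMIN cannot be optimized directly; maximize E-NE instead"
                )
            if obj.measure in GENOTYPE_MEASURES:
                if dataset.genotypes is None:
                    raise DataError(f"{obj.measure} requires genotype data")
                self.states.append(_HeterozygosityState(dataset.genotypes))
            else:
                d = resolve_distance(dataset, obj.source).d
                self.states.append(_DISTANCE_STATES[obj.measure](d))
        self.n = dataset.n
        self._last: tuple[int, int] | None = None

    def reset(self, sel: np.ndarray, unsel: np.ndarray | None = None) -> float:
        self.sel = np.asarray(sel, dtype=np.int64).copy()
        if unsel is None:
            mask = np.ones(self.n, dtype=bool)
            mask[self.sel] = False
            unsel = np.flatnonzero(mask)
        self.unsel = np.asarray(unsel, dtype=np.int64).copy()
        raws = [st.reset(self.sel) for st in self.states]
        self._last = None
        return self._score(raws)

    def swap(self, i: int, j: int) -> float:
        """Swap selected position ``i`` with unselected position ``j``."""
        r = int(self.sel[i])
        a = int(self.unsel[j])
        self.sel[i] = a
        self.unsel[j] = r
        raws = [st.apply(r, a, i, self.sel) for st in self.states]
        self._last = (i, j)
        return self._score(raws)

    def revert(self) -> None:
        if self._last is None:
            raise RuntimeError("no swap to revert")
        i, j = self._last
        a = int(self.sel[i])
        r = int(self.unsel[j])
        self.sel[i] = r
        self.unsel[j] = a
        for st in self.states:
            st.apply(a, r, i, self.sel)
        self._last = None

    def raws(self) -> dict[str, float]:
        return {o.measure: st.value for o, st in zip(self.objectives, self.states)}

    def _score(self, raws: list[float]) -> float:
        objs = self.objectives.objectives
        if self.ranges is None:
            return objs[0].sign_adjusted(raws[0])
        total = 0.0
        for obj, raw in zip(objs, raws):
            total += obj.weight * self.ranges.normalize(
                obj.measure, obj.sign_adjusted(raw), clamp=False
            )
        return total
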