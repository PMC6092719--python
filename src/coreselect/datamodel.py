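"""Core data containers for germplasm collections and core subsets.

A collection of ``n`` accessions may carry genotypes (allele-frequency
vectors per locus), phenotypes (qualitative and quantitative traits), a
precomputed pairwise distance matrix, or any combination of these. A core
subset is a fixed-size selection of ``k`` accessions, ``2 <= k <= n - 1``.

Accession identity is the string id; integer indices are internal and
0-based. All components of one :class:`Dataset` share the same accession
ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

QUALITATIVE = "qualitative"
QUANTITATIVE = "quantitative"

#: tolerance for allele-frequency vectors summing to one
FREQ_SUM_TOL = 1e-6
#: tolerance for distance-matrix symmetry
SYMMETRY_TOL = 1e-9


class DataError(ValueError):
    """Raised when input data violate a container invariant."""


def _check_unique_ids(accession_ids: Sequence[str]) -> list[str]:
    ids = [str(a) for a in accession_ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for a in ids:
            (dups if a in seen else seen).add(a)
        raise DataError(f"duplicate accession ids: {sorted(dups)}")
    return ids


@dataclass(frozen=True)
class Locus:
    """A marker locus with an ordered tuple of named alleles (>= 2)."""

    name: str
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) < 2:
            raise DataError(f"locus {self.name!r} needs >= 2 alleles")


class GenotypeMatrix:
    """Per-accession, per-locus allele-frequency vectors.

    Frequencies are stored as one flat ``(n, A)`` float array where ``A``
    is the total allele count over all loci; ``offsets[l]:offsets[l+1]``
    delimits locus ``l``. A locus that is missing for an accession is a
    block of NaN. Every observed block sums to 1 (tolerance 1e-6).
    """

    def __init__(
        self,
        accession_ids: Sequence[str],
        loci: Sequence[Locus],
        frequencies: np.ndarray,
    ) -> None:
        self.accession_ids = _check_unique_ids(accession_ids)
        self.loci = list(loci)
        freq = np.asarray(frequencies, dtype=float)
        if self.n < 3:
            raise DataError(f"need at least 3 accessions, got {self.n}")
        if not self.loci:
            raise DataError("need at least one locus")
        offsets = np.cumsum([0] + [len(l.alleles) for l in self.loci])
        self.offsets = offsets
        if freq.shape != (self.n, offsets[-1]):
            raise DataError(
                f"frequency array has shape {freq.shape}, "
                f"expected {(self.n, int(offsets[-1]))}"
            )
        self.frequencies = freq
        self.observed = np.zeros((self.n, self.n_loci), dtype=bool)
        for l in range(self.n_loci):
            block = freq[:, offsets[l] : offsets[l + 1]]
            nan = np.isnan(block)
            partial = nan.any(axis=1) & ~nan.all(axis=1)
            if partial.any():
                bad = self.accession_ids[int(np.flatnonzero(partial)[0])]
                raise DataError(
                    f"accession {bad!r}, locus {self.loci[l].name!r}: "
                    "frequency vector is partially missing"
                )
            self.observed[:, l] = ~nan.any(axis=1)
        with np.errstate(invalid="ignore"):
            if np.nanmin(freq, initial=0.0) < -1e-12 or np.nanmax(freq, initial=0.0) > 1 + 1e-12:
                raise DataError("allele frequencies must lie in [0, 1]")
        for l in range(self.n_loci):
            block = freq[:, offsets[l] : offsets[l + 1]]
            sums = np.nansum(block, axis=1)[self.observed[:, l]]
            if sums.size and np.max(np.abs(sums - 1.0)) > FREQ_SUM_TOL:
                raise DataError(
                    f"locus {self.loci[l].name!r}: allele frequencies do not "
                    f"sum to 1 within {FREQ_SUM_TOL}"
                )

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_slice(self, l: int) -> slice:
        return slice(int(self.offsets[l]), int(self.offsets[l + 1]))

    def locus_frequencies(self, accession: int, locus: int) -> np.ndarray:
        """Frequency vector of one accession at one locus (NaN if missing)."""
        return self.frequencies[accession, self.locus_slice(locus)]

    @classmethod
    def from_dosages(
        cls,
        accession_ids: Sequence[str],
        marker_names: Sequence[str],
        dosages: np.ndarray,
    ) -> "GenotypeMatrix":
        """Build a biallelic matrix from 0/1/2 reference-allele dosages.

        Dosage ``g`` maps to frequencies ``(g/2, 1 - g/2)`` for the two
        alleles of each marker; NaN marks a missing call.
        """
        d = np.asarray(dosages, dtype=float)
        obs = ~np.isnan(d)
        if obs.any():
            vals = d[obs]
            if not np.isin(vals, (0.0, 1.0, 2.0)).all():
                raise DataError("dosages must be 0, 1 or 2 (or missing)")
        n, m = d.shape
        freq = np.empty((n, 2 * m), dtype=float)
        freq[:, 0::2] = d / 2.0
        freq[:, 1::2] = 1.0 - d / 2.0
        loci = [Locus(str(name), ("A", "a")) for name in marker_names]
        return cls(accession_ids, loci, freq)


@dataclass(frozen=True)
class Trait:
    """A phenotypic trait descriptor.

    Quantitative traits carry the observed (min, max) range used by
    Gower's distance; qualitative traits compare by category equality.
    """

    name: str
    kind: str
    range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in (QUALITATIVE, QUANTITATIVE):
            raise DataError(f"unknown trait kind {self.kind!r}")
        if self.kind == QUANTITATIVE:
            if self.range is None:
                raise DataError(f"quantitative trait {self.name!r} needs a range")
            lo, hi = self.range
            if not hi >= lo:
                raise DataError(f"trait {self.name!r}: range max < min")


class PhenotypeTable:
    """Per-accession trait values with mixed qualitative/quantitative traits.

    ``values`` is a DataFrame indexed by accession id with one column per
    trait; missing cells are NaN/None.
    """

    def __init__(
        self,
        accession_ids: Sequence[str],
        traits: Sequence[Trait],
        values: pd.DataFrame,
    ) -> None:
        self.accession_ids = _check_unique_ids(accession_ids)
        self.traits = list(traits)
        if list(values.columns) != [t.name for t in self.traits]:
            raise DataError("value columns must match trait names in order")
        if len(values) != self.n:
            raise DataError("value rows must match accession count")
        values = values.copy()
        values.index = pd.Index(self.accession_ids)
        for t in self.traits:
            col = values[t.name]
            if col.isna().all():
                raise DataError(f"trait {t.name!r} has no observed values")
            if t.kind == QUANTITATIVE:
                numeric = pd.to_numeric(col, errors="coerce")
                if (numeric.isna() & col.notna()).any():
                    raise DataError(f"non-numeric value in quantitative trait {t.name!r}")
                values[t.name] = numeric
                lo, hi = t.range
                if hi == lo and numeric.dropna().nunique() > 1:
                    raise DataError(f"trait {t.name!r}: zero-width range but varying values")
        self.values = values

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    @classmethod
    def from_values(
        cls,
        accession_ids: Sequence[str],
        kinds: dict[str, str],
        values: pd.DataFrame,
    ) -> "PhenotypeTable":
        """Build a table computing quantitative ranges from observed data."""
        traits = []
        for name in values.columns:
            try:
                kind = kinds[str(name)]
            except KeyError:
                raise DataError(f"no kind declared for trait {name!r}") from None
            if kind == QUANTITATIVE:
                numeric = pd.to_numeric(values[name], errors="coerce")
                if (numeric.isna() & values[name].notna()).any():
                    raise DataError(f"non-numeric value in quantitative trait {name!r}")
                obs = numeric.dropna()
                if obs.empty:
                    raise DataError(f"trait {name!r} has no observed values")
                traits.append(Trait(str(name), QUANTITATIVE, (float(obs.min()), float(obs.max()))))
            else:
                traits.append(Trait(str(name), kind))
        extra = set(kinds) - {str(c) for c in values.columns}
        if extra:
            raise DataError(f"trait spec names unknown columns: {sorted(extra)}")
        return cls(accession_ids, traits, values)


class DistanceMatrix:
    """A symmetric n x n pairwise dissimilarity matrix with zero diagonal."""

    def __init__(self, accession_ids: Sequence[str], d: np.ndarray) -> None:
        self.accession_ids = _check_unique_ids(accession_ids)
        d = np.asarray(d, dtype=float)
        n = self.n
        if d.shape != (n, n):
            raise DataError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if np.abs(d - d.T).max(initial=0.0) > SYMMETRY_TOL:
            raise DataError(f"distance matrix asymmetric beyond {SYMMETRY_TOL}")
        if np.any(np.diag(d) != 0.0):
            raise DataError("distance matrix diagonal must be exactly zero")
        if d.min(initial=0.0) < 0.0:
            raise DataError("distances must be non-negative")
        self.d = d

    @property
    def n(self) -> int:
        return len(self.accession_ids)


@dataclass(frozen=True)
class CoreSubset:
    """A fixed-size selection of accession indices (0-based)."""

    selected: frozenset[int]
    k: int

    def __init__(self, selected: Iterable[int], k: int | None = None) -> None:
        sel = frozenset(int(i) for i in selected)
        if k is None:
            k = len(sel)
        object.__setattr__(self, "selected", sel)
        object.__setattr__(self, "k", int(k))
        if len(sel) != self.k:
            raise DataError(f"core holds {len(sel)} accessions, expected k={self.k}")
        if self.k < 2:
            raise DataError("core size must be at least 2")
        if any(i < 0 for i in sel):
            raise DataError("negative accession index in core")

    def indices(self) -> np.ndarray:
        """Sorted index array of the selection."""
        return np.fromiter(sorted(self.selected), dtype=np.int64, count=self.k)

    def validate_for(self, n: int) -> None:
        if self.k > n - 1:
            raise DataError(f"core size {self.k} must be <= n - 1 = {n - 1}")
        if max(self.selected) >= n:
            raise DataError("core references accession index beyond collection")

    def ids(self, accession_ids: Sequence[str]) -> list[str]:
        return [accession_ids[i] for i in sorted(self.selected)]


@dataclass
class Dataset:
    """A collection with any combination of data components.

    At least one of genotypes/phenotypes/distances must be present, and
    all present components must list identical accession ids in identical
    order.
    """

    genotypes: GenotypeMatrix | None = None
    phenotypes: PhenotypeTable | None = None
    distances: DistanceMatrix | None = None
    _resolved: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        parts = [p for p in (self.genotypes, self.phenotypes, self.distances) if p is not None]
        if not parts:
            raise DataError("dataset needs at least one data component")
        ids = parts[0].accession_ids
        for p in parts[1:]:
            if p.accession_ids != ids:
                raise DataError("data components disagree on accession ids/order")
        if len(ids) < 3:
            raise DataError("dataset needs at least 3 accessions")

    @property
    def accession_ids(self) -> list[str]:
        for p in (self.genotypes, self.phenotypes, self.distances):
            if p is not None:
                return p.accession_ids
        raise AssertionError("unreachable")

    @property
    def n(self) -> int:
        return len(self.accession_ids)
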