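"""Evaluation measures over core subsets and the weighted multi-objective index.

Measures
--------
E-NE (entry-to-nearest-entry)
    Mean distance from each core entry to the closest *other* entry;
    maximized for within-core diversity.
A-NE (accession-to-nearest-entry)
    Mean distance from each accession of the whole collection to its
    closest core entry (selected accessions contribute 0); minimized for
    representativeness.
HE (expected heterozygosity)
    Per-locus average of ``1 - sum_a p_hat_la^2`` where ``p_hat_la`` is
    the mean allele frequency over core entries; proxy for allelic
    richness, maximized.
DMIN
    Minimum pairwise distance among core entries. Reported only: its
    landscape is too flat for local search, so it is never offered as an
    optimization target, and a high E-NE drags it up indirectly.
avg-EE
    Mean pairwise distance among core entries (legacy diversity measure).

Multiple measures are combined as a weighted index ``F = sum_i a_i F'_i``
with weights summing to one; minimized measures enter sign-flipped
(``F' = -F``) and every measure is normalized to [0, 1] using per-measure
upper/lower bounds (best single-objective value vs Pareto minimum over
the single-objective optima).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .datamodel import CoreSubset, DataError, Dataset, DistanceMatrix, GenotypeMatrix
from .distances import resolve_distance

ENE = "E-NE"
ANE = "A-NE"
HE = "HE"
DMIN = "DMIN"
AVG_EE = "avg-EE"

MEASURES = (ENE, ANE, HE, DMIN, AVG_EE)
#: measures whose raw value is minimized (all others are maximized)
MINIMIZED = frozenset({ANE})
#: measures that read genotype data rather than a distance matrix
GENOTYPE_MEASURES = frozenset({HE})

WEIGHT_SUM_TOL = 1e-9


def _core_indices(d: DistanceMatrix, core: CoreSubset, min_k: int = 2) -> np.ndarray:
    core.validate_for(d.n)
    if core.k < min_k:
        raise DataError(f"measure undefined for core size {core.k} < {min_k}")
    return core.indices()


def entry_to_nearest_entry(d: DistanceMatrix, core: CoreSubset) -> float:
    """E-NE: mean distance from each entry to the closest other entry."""
    sel = _core_indices(d, core)
    sub = d.d[np.ix_(sel, sel)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def accession_to_nearest_entry(d: DistanceMatrix, core: CoreSubset) -> float:
    """A-NE: mean distance from every accession to its closest core entry."""
    sel = _core_indices(d, core, min_k=2)
    return float(d.d[:, sel].min(axis=1).mean())


def min_distance(d: DistanceMatrix, core: CoreSubset) -> float:
    """DMIN: minimum pairwise distance among core entries (report only)."""
    sel = _core_indices(d, core)
    sub = d.d[np.ix_(sel, sel)]
    return float(sub[np.triu_indices(core.k, 1)].min())


def average_entry_to_entry(d: DistanceMatrix, core: CoreSubset) -> float:
    """avg-EE: mean over all selected pairs."""
    sel = _core_indices(d, core)
    sub = d.d[np.ix_(sel, sel)]
    return float(sub[np.triu_indices(core.k, 1)].mean())


def expected_heterozygosity(geno: GenotypeMatrix, core: CoreSubset) -> float:
    """Average expected heterozygosity per locus of the core.

    Allele frequencies ``p_hat_la`` are unweighted means of the entry
    frequency vectors over core entries with observed data at the locus;
    loci unobserved in the whole core are dropped from the average.
    """
    core.validate_for(geno.n)
    if core.k < 2:
        raise DataError("HE needs a core of size >= 2")
    sel = core.indices()
    counts = geno.observed[sel].sum(axis=0)
    if not (counts > 0).any():
        raise DataError("no locus observed in any core entry")
    sums = np.nansum(geno.frequencies[sel], axis=0)
    per_allele_counts = np.repeat(counts, np.diff(geno.offsets))
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.where(per_allele_counts > 0, sums / np.maximum(per_allele_counts, 1), 0.0)
    locus_sq = np.add.reduceat(p_hat * p_hat, geno.offsets[:-1])
    valid = counts > 0
    return float(np.mean(1.0 - locus_sq[valid]))


_MEASURE_FUNCS = {
    ENE: entry_to_nearest_entry,
    ANE: accession_to_nearest_entry,
    DMIN: min_distance,
    AVG_EE: average_entry_to_entry,
}


@dataclass(frozen=True)
class Objective:
    """One evaluation measure with its optimization direction and weight.

    ``source`` names the data component the measure reads: ``auto``,
    ``genotype``, ``phenotype`` or ``distance`` (ignored for HE, which
    always reads genotypes).
    """

    measure: str
    weight: float = 1.0
    source: str = "auto"

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("objective weight must lie in (0, 1]")

    @property
    def maximize(self) -> bool:
        return self.measure not in MINIMIZED

    def sign_adjusted(self, raw: float) -> float:
        """Raw value on the maximization scale (minimized measures flip sign)."""
        return raw if self.maximize else -raw


class ObjectiveConfig:
    """An ordered list of objectives with weights summing to one."""

    def __init__(self, objectives: Sequence[Objective]) -> None:
        self.objectives = list(objectives)
        if not self.objectives:
            raise ValueError("need at least one objective")
        measures = [o.measure for o in self.objectives]
        if len(set(measures)) != len(measures):
            raise ValueError("duplicate measures in objective config")
        total = sum(o.weight for o in self.objectives)
        if abs(total - 1.0) > WEIGHT_SUM_TOL:
            raise ValueError(f"objective weights sum to {total}, expected 1")

    def __iter__(self):
        return iter(self.objectives)

    def __len__(self) -> int:
        return len(self.objectives)


def raw_value(dataset: Dataset, core: CoreSubset, objective: Objective) -> float:
    """Evaluate one measure from scratch on its data component."""
    if objective.measure in GENOTYPE_MEASURES:
        if dataset.genotypes is None:
            raise DataError(f"{objective.measure} requires genotype data")
        return expected_heterozygosity(dataset.genotypes, core)
    d = resolve_distance(dataset, objective.source)
    return _MEASURE_FUNCS[objective.measure](d, core)


class NormalizationRanges:
    """Per-measure [lower, upper] bounds on the sign-adjusted value.

    The upper bound is the best value found by a single-objective search
    on the measure alone; the lower bound is the Pareto minimum, i.e. the
    worst value the measure takes at any of those single-objective
    optima. Degenerate measures (upper == lower) are treated as the
    constant 1 with a warning.
    """

    def __init__(self, bounds: Mapping[str, tuple[float, float]]) -> None:
        self.bounds: dict[str, tuple[float, float]] = {}
        self.degenerate: set[str] = set()
        for measure, (lo, hi) in bounds.items():
            if hi > lo:
                self.bounds[measure] = (float(lo), float(hi))
            else:
                warnings.warn(
                    f"degenerate normalization range for {measure}; treated as constant",
                    stacklevel=2,
                )
                self.degenerate.add(measure)

    def normalize(self, measure: str, sign_adjusted: float, clamp: bool = True) -> float:
        """Map a sign-adjusted raw value onto the [lower, upper] scale.

        Reported values are clamped to [0, 1]; the search engines use
        the unclamped affine map (``clamp=False``) so that solutions
        outside the bounds still see a gradient.
        """
        if measure in self.degenerate:
            return 1.0
        try:
            lo, hi = self.bounds[measure]
        except KeyError:
            raise DataError(f"no normalization range for {measure}") from None
        v = (sign_adjusted - lo) / (hi - lo)
        return float(np.clip(v, 0.0, 1.0)) if clamp else float(v)


def compute_normalization_ranges(
    dataset: Dataset,
    objectives: ObjectiveConfig,
    k: int,
    stop,
    seed: int,
) -> NormalizationRanges:
    """Upper/lower normalization bounds via single-objective searches.

    One random-descent run per objective (sub-seeded from ``seed``)
    yields the upper bound; cross-evaluating every measure on every
    single-objective optimum yields the Pareto-minimum lower bound.
    Deterministic given the seed.
    """
    from .search import random_descent  # deferred: search builds on objectives

    if len(objectives) < 2:
        raise ValueError("normalization needs at least two objectives")
    optima: list[CoreSubset] = []
    upper: dict[str, float] = {}
    for i, obj in enumerate(objectives):
        single = ObjectiveConfig([replace(obj, weight=1.0)])
        result = random_descent(dataset, single, k, stop=stop, seed=seed + i)
        optima.append(result.core)
        upper[obj.measure] = obj.sign_adjusted(raw_value(dataset, result.core, obj))
    bounds: dict[str, tuple[float, float]] = {}
    for obj in objectives:
        cross = [obj.sign_adjusted(raw_value(dataset, c, obj)) for c in optima]
        bounds[obj.measure] = (min(cross), upper[obj.measure])
    return NormalizationRanges(bounds)


def weighted_index(
    raw_values: Mapping[str, float],
    objectives: ObjectiveConfig,
    ranges: NormalizationRanges,
) -> float:
    """Normalized weighted sum of sign-adjusted raw measure values."""
    total = 0.0
    for obj in objectives:
        try:
            raw = raw_values[obj.measure]
        except KeyError:
            raise DataError(f"missing raw value for {obj.measure}") from None
        total += obj.weight * ranges.normalize(obj.measure, obj.sign_adjusted(raw))
    return total


@dataclass
class EvaluationReport:
    """Raw per-measure values plus the (possibly normalized) index."""

    values: dict[str, float]
    index: float


def evaluate(
    dataset: Dataset,
    core: CoreSubset,
    objectives: ObjectiveConfig,
    ranges: NormalizationRanges | None = None,
) -> EvaluationReport:
    """Evaluate a core on every configured measure.

    With a single objective and no ranges the index is the raw value;
    with several objectives, ranges are required and the index is the
    normalized weighted sum. DMIN is always reported when any distance
    matrix is available, whether or not it is an objective.
    """
    values = {obj.measure: raw_value(dataset, core, obj) for obj in objectives}
    if len(objectives) == 1 and ranges is None:
        index = values[objectives.objectives[0].measure]
    else:
        if ranges is None:
            raise DataError("multiple objectives require normalization ranges")
        index = weighted_index(values, objectives, ranges)
    report = dict(values)
    has_distance = (
        dataset.distances is not None
        or dataset.genotypes is not None
        or dataset.phenotypes is not None
    )
    if DMIN not in report and has_distance:
        report[DMIN] = min_distance(resolve_distance(dataset, "auto"), core)
    return EvaluationReport(values=report, index=index)
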