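"""Core evaluation measures, the weighted index, and normalization."""

import itertools

import numpy as np
import pytest

from coreselect import (
    CoreSubset,
    DataError,
    Dataset,
    DistanceMatrix,
    GenotypeMatrix,
    Locus,
    NormalizationRanges,
    Objective,
    ObjectiveConfig,
    StopCondition,
    accession_to_nearest_entry,
    average_entry_to_entry,
    compute_normalization_ranges,
    entry_to_nearest_entry,
    evaluate,
    expected_heterozygosity,
    min_distance,
    weighted_index,
)
from coreselect.objectives import raw_value
from coreselect.synthetic import generate_distance_matrix


class TestDistanceAggregates:
    def test_entry_to_nearest_entry_hand_example(self, toy_distance):
        assert entry_to_nearest_entry(toy_distance, CoreSubset([0, 2, 3])) == pytest.approx(
            0.3, abs=1e-9
        )

    def test_ene_with_duplicates_contributes_zero(self):
        d = np.array(
            [
                [0, 0, 0.5, 0.6],
                [0, 0, 0.5, 0.6],
                [0.5, 0.5, 0, 0.7],
                [0.6, 0.6, 0.7, 0],
            ],
            dtype=float,
        )
        dm = DistanceMatrix(["a", "b", "c", "d"], d)
        # both duplicates have nearest distance 0; third entry is 0.5 away
        assert entry_to_nearest_entry(dm, CoreSubset([0, 1, 2])) == pytest.approx(0.5 / 3)

    def test_ene_k2_equals_pairwise_distance(self, toy_distance):
        assert entry_to_nearest_entry(toy_distance, CoreSubset([1, 3])) == 0.7

    def test_accession_to_nearest_entry_hand_example(self, toy_distance):
        assert accession_to_nearest_entry(toy_distance, CoreSubset([1, 3])) == pytest.approx(
            0.075, abs=1e-9
        )

    def test_ane_zero_when_duplicates_cover(self):
        d = np.array([[0, 0, 0.5], [0, 0, 0.5], [0.5, 0.5, 0]], dtype=float)
        dm = DistanceMatrix(["a", "b", "c"], d)
        # every unselected accession has a zero-distance selected duplicate
        assert accession_to_nearest_entry(dm, CoreSubset([0, 2])) == 0.0

    def test_min_distance_hand_example(self, toy_distance):
        assert min_distance(toy_distance, CoreSubset([0, 2, 3])) == pytest.approx(0.2)

    def test_avg_entry_to_entry_hand_example(self, toy_distance):
        assert average_entry_to_entry(toy_distance, CoreSubset([0, 2, 3])) == pytest.approx(
            (0.5 + 0.6 + 0.2) / 3, abs=1e-9
        )

    def test_dmin_never_exceeds_ene(self):
        rng = np.random.default_rng(5)
        for trial in range(25):
            n = int(rng.integers(5, 15))
            dm = generate_distance_matrix(n, seed=trial, structure="uniform")
            k = int(rng.integers(2, n))
            core = CoreSubset(rng.choice(n, size=k, replace=False).tolist())
            assert min_distance(dm, core) <= entry_to_nearest_entry(dm, core) + 1e-12

    def test_single_entry_core_rejected(self):
        with pytest.raises(DataError):
            CoreSubset([0])


class TestExpectedHeterozygosity:
    def test_single_locus_balanced(self, biallelic_toy):
        # core {x, y}: pooled frequencies (0.5, 0.5) at locus 1, monomorphic locus 2
        assert expected_heterozygosity(biallelic_toy, CoreSubset([0, 1])) == pytest.approx(
            0.25, abs=1e-9
        )

    def test_monomorphic_core_is_zero(self):
        freq = np.tile(np.array([[1.0, 0.0]]), (3, 1))
        geno = GenotypeMatrix(["a", "b", "c"], [Locus("l", ("A", "a"))], freq)
        assert expected_heterozygosity(geno, CoreSubset([0, 1])) == 0.0

    def test_single_balanced_locus(self):
        freq = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        geno = GenotypeMatrix(["a", "b", "c"], [Locus("l", ("A", "a"))], freq)
        assert expected_heterozygosity(geno, CoreSubset([0, 1])) == pytest.approx(0.5)

    def test_bounded_in_unit_interval(self, ssr_panel):
        rng = np.random.default_rng(0)
        for _ in range(20):
            core = CoreSubset(rng.choice(ssr_panel.n, size=8, replace=False).tolist())
            he = expected_heterozygosity(ssr_panel, core)
            assert 0.0 <= he <= 1.0

    def test_locus_missing_in_whole_core_dropped(self):
        freq = np.array(
            [
                [1.0, 0.0, np.nan, np.nan],
                [0.0, 1.0, np.nan, np.nan],
                [1.0, 0.0, 1.0, 0.0],
            ]
        )
        loci = [Locus("l1", ("A", "a")), Locus("l2", ("B", "b"))]
        geno = GenotypeMatrix(["x", "y", "z"], loci, freq)
        assert expected_heterozygosity(geno, CoreSubset([0, 1])) == pytest.approx(0.5)


class TestWeightedIndex:
    def test_arithmetic(self):
        ranges = NormalizationRanges({"E-NE": (0.0, 1.0), "HE": (0.0, 1.0)})
        config = ObjectiveConfig([Objective("E-NE", 0.5), Objective("HE", 0.5)])
        assert weighted_index({"E-NE": 0.4, "HE": 0.6}, config, ranges) == pytest.approx(0.5)

    def test_minimized_objective_at_best_value_contributes_full_weight(self):
        # A-NE is minimized: raw 0.1 is its best; sign-adjusted scale is [-0.5, -0.1]
        ranges = NormalizationRanges({"A-NE": (-0.5, -0.1), "E-NE": (0.0, 1.0)})
        config = ObjectiveConfig([Objective("A-NE", 0.4), Objective("E-NE", 0.6)])
        value = weighted_index({"A-NE": 0.1, "E-NE": 0.0}, config, ranges)
        assert value == pytest.approx(0.4)

    def test_missing_range_rejected(self):
        ranges = NormalizationRanges({"E-NE": (0.0, 1.0)})
        config = ObjectiveConfig([Objective("E-NE", 0.5), Objective("HE", 0.5)])
        with pytest.raises(DataError, match="range"):
            weighted_index({"E-NE": 0.4, "HE": 0.6}, config, ranges)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            ObjectiveConfig([Objective("E-NE", 0.5), Objective("HE", 0.4)])

    def test_degenerate_range_treated_as_constant(self):
        with pytest.warns(UserWarning, match="degenerate"):
            ranges = NormalizationRanges({"E-NE": (0.3, 0.3)})
        assert ranges.normalize("E-NE", 0.123) == 1.0


class TestNormalizationRanges:
    def test_bounds_match_exhaustive_oracle(self):
        dm = generate_distance_matrix(6, seed=4, structure="uniform")
        dataset = Dataset(distances=dm)
        objectives = ObjectiveConfig([Objective("E-NE", 0.5), Objective("A-NE", 0.5)])
        stop = StopCondition(max_evals=4000)
        ranges = compute_normalization_ranges(dataset, objectives, k=3, stop=stop, seed=0)
        # exhaustive single-objective optima over all C(6,3) = 20 subsets
        cores = [CoreSubset(c) for c in itertools.combinations(range(6), 3)]
        best = {}
        for obj in objectives:
            vals = [obj.sign_adjusted(raw_value(dataset, c, obj)) for c in cores]
            best[obj.measure] = cores[int(np.argmax(vals))]
        for obj in objectives:
            upper = obj.sign_adjusted(raw_value(dataset, best[obj.measure], obj))
            lower = min(
                obj.sign_adjusted(raw_value(dataset, best[o.measure], obj)) for o in objectives
            )
            lo, hi = ranges.bounds[obj.measure]
            assert hi == pytest.approx(upper, abs=1e-12)
            assert lo == pytest.approx(lower, abs=1e-12)

    def test_deterministic_given_seed(self, snp_dataset):
        objectives = ObjectiveConfig([Objective("E-NE", 0.5), Objective("HE", 0.5)])
        stop = StopCondition(max_evals=2000)
        r1 = compute_normalization_ranges(snp_dataset, objectives, k=10, stop=stop, seed=3)
        r2 = compute_normalization_ranges(snp_dataset, objectives, k=10, stop=stop, seed=3)
        assert r1.bounds == r2.bounds


class TestEvaluate:
    def test_single_objective_index_is_raw_value(self, toy_dataset):
        config = ObjectiveConfig([Objective("E-NE")])
        report = evaluate(toy_dataset, CoreSubset([0, 2, 3]), config)
        assert report.index == pytest.approx(0.3)

    def test_he_without_genotypes_rejected(self, toy_dataset):
        config = ObjectiveConfig([Objective("HE")])
        with pytest.raises(DataError, match="genotype"):
            evaluate(toy_dataset, CoreSubset([0, 2]), config)

    def test_report_always_includes_dmin(self, snp_dataset):
        config = ObjectiveConfig([Objective("HE")])
        report = evaluate(snp_dataset, CoreSubset([0, 1, 2]), config)
        assert "DMIN" in report.values
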