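"""Search engines: acceptance rules, determinism, and oracle equivalence."""

import math

import numpy as np
import pytest

from coreselect import (
    DataError,
    Dataset,
    Objective,
    ObjectiveConfig,
    StopCondition,
    acceptance_probability,
    brute_force_optimum,
    genetic_algorithm,
    parallel_tempering,
    random_descent,
    swap_probability,
)
from coreselect.search import _crossover
from coreselect.synthetic import generate_distance_matrix

ENE_CONFIG = ObjectiveConfig([Objective("E-NE")])
ALL_ENGINES = [random_descent, parallel_tempering, genetic_algorithm]


class TestAcceptanceFunctions:
    def test_improving_move_always_accepted(self):
        assert acceptance_probability(0.05, 1e-6) == 1.0

    def test_inferior_move_boltzmann(self):
        assert acceptance_probability(-1e-4, 1e-4) == pytest.approx(math.exp(-1.0))

    def test_tie_accepted_with_probability_one(self):
        assert acceptance_probability(0.0, 1.0) == 1.0

    def test_zero_temperature_rejected(self):
        with pytest.raises(ValueError):
            acceptance_probability(0.1, 0.0)

    def test_cold_limit_is_strict_improvement_plus_ties(self):
        # as t -> 0+ any inferior move is rejected while ties stay accepted
        assert acceptance_probability(-1e-6, 1e-300) == 0.0
        assert acceptance_probability(0.0, 1e-300) == 1.0

    def test_swap_better_hotter_always_swapped(self):
        assert swap_probability(0.01, 1e-8, 1e-4) == 1.0

    def test_swap_tie_probability_one(self):
        assert swap_probability(0.0, 1e-8, 1e-4) == 1.0

    def test_swap_exponent(self):
        expected = math.exp((1e8 - 1e4) * -1.0001e-8)
        assert swap_probability(-1.0001e-8, 1e-8, 1e-4) == pytest.approx(expected)
        assert swap_probability(-1.0001e-8, 1e-8, 1e-4) == pytest.approx(math.exp(-1), rel=1e-4)

    def test_non_increasing_temperatures_rejected(self):
        with pytest.raises(ValueError):
            swap_probability(-0.1, 1e-4, 1e-8)
        with pytest.raises(ValueError):
            swap_probability(-0.1, 1e-4, 1e-4)


class TestBruteForce:
    def test_k2_optimum_is_largest_pairwise_distance(self, toy_dataset):
        core, value = brute_force_optimum(toy_dataset, ENE_CONFIG, 2)
        assert sorted(core.selected) == [1, 3]
        assert value == pytest.approx(0.7)

    def test_k3_optimum(self, toy_dataset):
        core, value = brute_force_optimum(toy_dataset, ENE_CONFIG, 3)
        assert sorted(core.selected) == [0, 2, 3]
        assert value == pytest.approx(0.3)

    def test_k_equals_n_minus_one(self, toy_dataset):
        core, _ = brute_force_optimum(toy_dataset, ENE_CONFIG, 3)
        assert core.k == 3

    def test_instance_size_guard(self, toy_dataset):
        with pytest.raises(ValueError, match="enumeration limit"):
            brute_force_optimum(toy_dataset, ENE_CONFIG, 2, max_subsets=3)


class TestRandomDescent:
    def test_finds_tiny_optimum(self, toy_dataset):
        for seed in range(5):
            result = random_descent(
                toy_dataset, ENE_CONFIG, 3, StopCondition(max_evals=300), seed=seed
            )
            assert sorted(result.core.selected) == [0, 2, 3]
            assert result.value == pytest.approx(0.3)

    def test_zero_budget_returns_initial_core(self, toy_dataset):
        result = random_descent(
            toy_dataset, ENE_CONFIG, 3, StopCondition(max_evals=0), seed=9
        )
        assert result.core.k == 3
        assert result.evaluations == 0
        assert len(result.trace) == 1

    def test_infeasible_core_size_rejected(self, toy_dataset):
        with pytest.raises(DataError):
            random_descent(toy_dataset, ENE_CONFIG, 4, StopCondition(max_evals=10), seed=0)


@pytest.mark.parametrize("engine", ALL_ENGINES, ids=["rd", "pt", "ga"])
class TestEngineContracts:
    def test_deterministic_given_seed(self, engine, snp_dataset):
        stop = StopCondition(max_evals=3000)
        r1 = engine(snp_dataset, ENE_CONFIG, 10, stop, seed=42)
        r2 = engine(snp_dataset, ENE_CONFIG, 10, stop, seed=42)
        assert r1.core.selected == r2.core.selected
        assert r1.value == r2.value
        # elapsed times differ between runs; the searched path must not
        assert [(e, v) for _, e, v in r1.trace] == [(e, v) for _, e, v in r2.trace]

    def test_trace_non_decreasing_and_ends_at_best(self, engine, snp_dataset):
        result = engine(snp_dataset, ENE_CONFIG, 10, StopCondition(max_evals=3000), seed=7)
        values = [v for _, _, v in result.trace]
        assert values == sorted(values)
        assert result.value == values[-1]

    def test_result_is_valid_core(self, engine, snp_dataset):
        result = engine(snp_dataset, ENE_CONFIG, 10, StopCondition(max_evals=2000), seed=3)
        assert result.core.k == 10
        result.core.validate_for(snp_dataset.n)

    def test_dmin_objective_rejected(self, engine, snp_dataset):
        config = ObjectiveConfig([Objective("DMIN")])
        with pytest.raises(DataError, match="DMIN"):
            engine(snp_dataset, config, 10, StopCondition(max_evals=10), seed=0)


class TestParallelTempering:
    def test_escapes_local_optima_on_clustered_instances(self):
        hits = 0
        for i in range(6):
            dm = generate_distance_matrix(12, seed=100 + i, structure="clustered")
            dataset = Dataset(distances=dm)
            _, opt = brute_force_optimum(dataset, ENE_CONFIG, 4)
            result = parallel_tempering(
                dataset, ENE_CONFIG, 4, StopCondition(max_evals=50_000), seed=i
            )
            hits += result.value >= opt - 1e-12
        assert hits >= 5

    def test_invalid_temperature_range_rejected(self, toy_dataset):
        with pytest.raises(ValueError):
            parallel_tempering(
                toy_dataset, ENE_CONFIG, 2, StopCondition(max_evals=10), seed=0,
                t_min=1e-4, t_max=1e-8,
            )


class TestGeneticAlgorithm:
    def test_crossover_of_identical_parents_is_parent(self):
        rng = np.random.default_rng(0)
        parent = np.array([2, 5, 7, 9])
        child = _crossover(rng, parent, parent, 4)
        assert sorted(child.tolist()) == sorted(parent.tolist())

    def test_crossover_child_subset_of_union(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p1 = rng.choice(30, size=6, replace=False)
            p2 = rng.choice(30, size=6, replace=False)
            child = _crossover(rng, p1, p2, 6)
            union = set(p1) | set(p2)
            assert len(child) == 6 and len(set(child.tolist())) == 6
            assert set(child.tolist()) <= union

    def test_reaches_optimum_on_small_instance(self, toy_dataset):
        result = genetic_algorithm(
            toy_dataset, ENE_CONFIG, 3, StopCondition(max_evals=3000), seed=1,
            mutation_stall=50,
        )
        assert result.value == pytest.approx(0.3)

    def test_population_must_exceed_tournament(self, toy_dataset):
        with pytest.raises(ValueError):
            genetic_algorithm(
                toy_dataset, ENE_CONFIG, 2, StopCondition(max_evals=10), seed=0,
                population=4, tournament=5,
            )


class TestStopCondition:
    def test_needs_at_least_one_criterion(self):
        with pytest.raises(ValueError):
            StopCondition()

    def test_eval_budget_respected(self, snp_dataset):
        result = random_descent(
            snp_dataset, ENE_CONFIG, 10, StopCondition(max_evals=500), seed=0
        )
        assert result.evaluations == 500

    def test_stall_evals_stop(self, toy_dataset):
        result = random_descent(
            toy_dataset, ENE_CONFIG, 3, StopCondition(max_stall_evals=200), seed=0
        )
        # tiny instance: the optimum is found quickly, then 200 stalled proposals
        assert result.evaluations >= 200
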