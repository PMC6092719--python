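"""Run configuration, the Pareto weight sweep, and comparison harnesses.

These wrap the search engines into the experimental designs used to
study core selection methods: repeated seeded runs per configuration,
weight sweeps approximating the Pareto front of a two-objective
trade-off, and side-by-side engine comparisons with convergence traces.
Sub-seeds of repeated runs are ``base_seed + run_index`` so every run is
individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as csio
from .datamodel import CoreSubset, DataError, Dataset
from .objectives import (
    ENE,
    NormalizationRanges,
    Objective,
    ObjectiveConfig,
    compute_normalization_ranges,
    evaluate,
    raw_value,
)
from .search import ENGINES, StopCondition, brute_force_optimum
from .synthetic import generate_distance_matrix


def resolve_core_size(n: int, k: int | None = None, fraction: float | None = None) -> int:
    """Absolute core size from either ``k`` or a fraction of ``n``.

    Fractions round half up and the result is clamped to [2, n - 1].
    """
    if (k is None) == (fraction is None):
        raise ValueError("specify exactly one of k and fraction")
    if fraction is not None:
        if not 0.0 < fraction < 1.0:
            raise ValueError("fraction must lie in (0, 1)")
        k = int(math.floor(fraction * n + 0.5))
    k = max(2, min(int(k), n - 1))
    if not 2 <= k <= n - 1:
        raise DataError(f"resolved core size {k} infeasible for n={n}")
    return k


@dataclass
class RunConfig:
    """A fully specified sampling run (paths, size, objectives, engine)."""

    genotype_path: str | None = None
    genotype_dialect: str = "dosage"
    phenotype_path: str | None = None
    trait_spec: dict[str, str] | None = None
    distance_path: str | None = None
    k: int | None = None
    fraction: float | None = None
    objectives: list[dict] = field(default_factory=lambda: [{"measure": ENE, "weight": 1.0}])
    method: str = "pt"
    fast: bool = False
    seed: int = 0
    max_time: float | None = None
    max_stall_time: float | None = 10.0
    max_stall_evals: int | None = None
    max_evals: int | None = None
    core_out: str | None = None
    trace_out: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def load_dataset(self) -> Dataset:
        geno = pheno = dist = None
        if self.genotype_path:
            geno = csio.read_genotypes(self.genotype_path, self.genotype_dialect)
        if self.phenotype_path:
            if not self.trait_spec:
                raise ValueError("phenotype data needs a trait_spec")
            pheno = csio.read_phenotypes(self.phenotype_path, self.trait_spec)
        if self.distance_path:
            dist = csio.read_distance_matrix(self.distance_path)
        return Dataset(genotypes=geno, phenotypes=pheno, distances=dist)

    def stop_condition(self) -> StopCondition:
        return StopCondition(
            max_time=self.max_time,
            max_stall_time=self.max_stall_time,
            max_stall_evals=self.max_stall_evals,
            max_evals=self.max_evals,
        )

    def objective_config(self) -> ObjectiveConfig:
        return ObjectiveConfig([Objective(**o) for o in self.objectives])


def run_sampling(config: RunConfig, dataset: Dataset | None = None):
    """Execute one configured sampling run; optionally write outputs.

    Returns ``(SearchResult, EvaluationReport)``. With several
    objectives, normalization ranges are first computed with the same
    stop condition and seed-derived sub-seeds; single objectives are
    optimized unnormalized.
    """
    if dataset is None:
        dataset = config.load_dataset()
    k = resolve_core_size(dataset.n, config.k, config.fraction)
    objectives = config.objective_config()
    stop = config.stop_condition()
    method = "rd" if config.fast else config.method
    try:
        engine = ENGINES[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(ENGINES)}") from None
    ranges = None
    if len(objectives) > 1:
        ranges = compute_normalization_ranges(dataset, objectives, k, stop, config.seed)
    result = engine(dataset, objectives, k, stop=stop, seed=config.seed, ranges=ranges)
    report = evaluate(dataset, result.core, objectives, ranges)
    if config.core_out:
        csio.write_core(result.core, dataset, config.core_out, report.values)
    if config.trace_out:
        pd.DataFrame(
            result.trace, columns=["elapsed_s", "evaluations", "best_value"]
        ).to_csv(config.trace_out, index=False)
    return result, report


@dataclass
class SweepRecord:
    alpha: float
    run: int
    seed: int
    core: CoreSubset
    value_a: float
    value_b: float


@dataclass
class SweepResult:
    """Per-weight summary, per-run records, and the normalization ranges."""

    summary: pd.DataFrame
    records: list[SweepRecord]
    ranges: NormalizationRanges


def pareto_sweep(
    dataset: Dataset,
    objective_a: Objective,
    objective_b: Objective,
    k: int,
    stop: StopCondition,
    base_seed: int,
    step: float = 0.05,
    runs: int = 10,
    method: str = "pt",
    engine_kwargs: Mapping | None = None,
) -> SweepResult:
    """Approximate the Pareto front of two objectives by a weight sweep.

    Weights ``alpha`` for objective A run over 0, step, ..., 1 (21
    settings for step 0.05) with ``1 - alpha`` on objective B; each
    setting is sampled ``runs`` times with sub-seeds
    ``base_seed + run_index``. Endpoint weights drop the zero-weight
    objective and optimize the other unnormalized (its value is still
    reported). Normalization ranges for the interior weights are
    computed once, seeded from ``base_seed``.
    """
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1")
    engine = ENGINES[method]
    kwargs = dict(engine_kwargs or {})
    pair = ObjectiveConfig(
        [replace(objective_a, weight=0.5), replace(objective_b, weight=0.5)]
    )
    ranges = compute_normalization_ranges(dataset, pair, k, stop, base_seed)
    records: list[SweepRecord] = []
    run_index = 0
    for i in range(m + 1):
        alpha = i * step
        if alpha == 0.0:
            config = ObjectiveConfig([replace(objective_b, weight=1.0)])
            use_ranges = None
        elif alpha == 1.0:
            config = ObjectiveConfig([replace(objective_a, weight=1.0)])
            use_ranges = None
        else:
            config = ObjectiveConfig(
                [replace(objective_a, weight=alpha), replace(objective_b, weight=1.0 - alpha)]
            )
            use_ranges = ranges
        for run in range(runs):
            seed = base_seed + run_index
            run_index += 1
            result = engine(dataset, config, k, stop=stop, seed=seed, ranges=use_ranges, **kwargs)
            records.append(
                SweepRecord(
                    alpha=alpha,
                    run=run,
                    seed=seed,
                    core=result.core,
                    value_a=raw_value(dataset, result.core, objective_a),
                    value_b=raw_value(dataset, result.core, objective_b),
                )
            )
    frame = pd.DataFrame(
        [
            {"alpha": r.alpha, "run": r.run, "value_a": r.value_a, "value_b": r.value_b}
            for r in records
        ]
    )
    summary = (
        frame.groupby("alpha")
        .agg(
            mean_a=("value_a", "mean"),
            sd_a=("value_a", "std"),
            mean_b=("value_b", "mean"),
            sd_b=("value_b", "std"),
        )
        .reset_index()
    )
    return SweepResult(summary=summary, records=records, ranges=ranges)


@dataclass
class ComparisonRun:
    method: str
    run: int
    seed: int
    core: CoreSubset
    value: float
    trace: list[tuple[float, int, float]]


@dataclass
class ComparisonResult:
    """Per-method summary statistics plus all individual runs."""

    summary: pd.DataFrame
    runs: list[ComparisonRun]


def compare_algorithms(
    dataset: Dataset,
    objectives: ObjectiveConfig,
    k: int,
    methods: Sequence[str],
    runs: int,
    stop: StopCondition,
    base_seed: int,
    ranges: NormalizationRanges | None = None,
    engine_kwargs: Mapping[str, Mapping] | None = None,
) -> ComparisonResult:
    """Repeated seeded runs of several engines under one stop condition.

    Every method sees the same sub-seeds ``base_seed + run_index`` so
    runs are paired across methods. The summary reports mean and
    standard deviation of the best score per method; traces of best
    value against time and evaluation count are kept per run.
    """
    if not methods:
        raise ValueError("need at least one method")
    all_runs: list[ComparisonRun] = []
    for method in methods:
        engine = ENGINES[method]
        kwargs = dict((engine_kwargs or {}).get(method, {}))
        for run in range(runs):
            seed = base_seed + run
            result = engine(dataset, objectives, k, stop=stop, seed=seed, ranges=ranges, **kwargs)
            all_runs.append(
                ComparisonRun(
                    method=method,
                    run=run,
                    seed=seed,
                    core=result.core,
                    value=result.value,
                    trace=result.trace,
                )
            )
    frame = pd.DataFrame([{"method": r.method, "value": r.value} for r in all_runs])
    summary = (
        frame.groupby("method", sort=False)
        .agg(mean=("value", "mean"), sd=("value", "std"))
        .reset_index()
    )
    return ComparisonResult(summary=summary, runs=all_runs)


def oracle_benchmark(
    base_seed: int,
    n_instances: int = 30,
    n: int = 12,
    k: int = 4,
    budget: int = 50_000,
    methods: Sequence[str] = ("pt", "rd"),
) -> dict[str, dict]:
    """Seeded random instances with a brute-force oracle.

    For each instance a clustered random distance matrix is drawn, the
    exact E-NE optimum enumerated, and each engine run once with an
    evaluation budget. Reports per-method hit counts (optimum found to
    1e-12) and mean best values.
    """
    stop = StopCondition(max_evals=budget)
    objectives = ObjectiveConfig([Objective(ENE)])
    hits = {m: 0 for m in methods}
    values: dict[str, list[float]] = {m: [] for m in methods}
    for i in range(n_instances):
        dist = generate_distance_matrix(n, seed=base_seed + i, structure="clustered")
        dataset = Dataset(distances=dist)
        _, opt_value = brute_force_optimum(dataset, objectives, k)
        for m in methods:
            result = ENGINES[m](dataset, objectives, k, stop=stop, seed=base_seed + 1000 + i)
            values[m].append(result.value)
            if result.value >= opt_value - 1e-12:
                hits[m] += 1
    return {
        m: {
            "hits": hits[m],
            "instances": n_instances,
            "mean_value": float(np.mean(values[m])),
        }
        for m in methods
    }
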