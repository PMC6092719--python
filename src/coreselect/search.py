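"""Stochastic search engines over the single-swap neighbourhood.

All engines maximize the scalar score of a :class:`CompositeEvaluator`
(sign-adjusted raw value for a single objective, normalized weighted
index otherwise) over the space of k-subsets, moving between neighbours
that differ by one selected accession. Three engines are provided:

* random descent — a stochastic hill-climber accepting strictly
  improving swaps only;
* parallel tempering (replica exchange) — ten Metropolis chains at
  fixed temperatures equally spaced in [1e-8, 1e-4] that exchange their
  current selections after every 500 steps per replica;
* a genetic algorithm with tournament selection, union crossover,
  random-descent mutation and inverse-fitness roulette survival.

A brute-force enumerator serves as the exact oracle on small instances.
All engines are deterministic given their seed.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass
from itertools import combinations
import numpy as np

from .datamodel import CoreSubset, DataError, Dataset
from .evaluators import CompositeEvaluator
from .objectives import NormalizationRanges, ObjectiveConfig, raw_value


@dataclass(frozen=True)
class SwapMove:
    """Replace selected accession ``remove`` with unselected ``add``."""

    remove: int
    add: int


@dataclass(frozen=True)
class StopCondition:
    """Search termination criteria; at least one must be set.

    ``max_evals`` and ``max_stall_evals`` count proposed moves (each
    costs one objective evaluation); the initial evaluation of a random
    start is free, so a zero-evaluation budget returns the evaluated
    initial selection. Time limits are wall-clock seconds.
    """

    max_time: float | None = None
    max_stall_time: float | None = None
    max_stall_evals: int | None = None
    max_evals: int | None = None

    def __post_init__(self) -> None:
        if all(
            v is None
            for v in (self.max_time, self.max_stall_time, self.max_stall_evals, self.max_evals)
        ):
            raise ValueError("stop condition needs at least one criterion")


@dataclass
class SearchResult:
    """Best core found, its score, and the improvement trace."""

    core: CoreSubset
    value: float
    trace: list[tuple[float, int, float]]  # (elapsed seconds, evaluations, best value)
    seed: int
    evaluations: int


class _Run:
    """Bookkeeping shared by all engines: budget, stall, best, trace."""

    def __init__(self, stop: StopCondition) -> None:
        self.stop = stop
        self.t0 = time.monotonic()
        self.evals = 0
        self.best = -math.inf
        self.best_sel: np.ndarray | None = None
        self.last_improvement_eval = 0
        self.last_improvement_time = self.t0
        self.trace: list[tuple[float, int, float]] = []

    def offer(self, score: float, sel: np.ndarray) -> bool:
        if score > self.best:
            self.best = score
            self.best_sel = sel.copy()
            self.last_improvement_eval = self.evals
            self.last_improvement_time = time.monotonic()
            self.trace.append((self.last_improvement_time - self.t0, self.evals, score))
            return True
        return False

    def done(self) -> bool:
        s = self.stop
        if s.max_evals is not None and self.evals >= s.max_evals:
            return True
        if s.max_stall_evals is not None and self.evals - self.last_improvement_eval >= s.max_stall_evals:
            return True
        if s.max_time is not None or s.max_stall_time is not None:
            now = time.monotonic()
            if s.max_time is not None and now - self.t0 >= s.max_time:
                return True
            if s.max_stall_time is not None and now - self.last_improvement_time >= s.max_stall_time:
                return True
        return False

    def result(self, seed: int) -> SearchResult:
        return SearchResult(
            core=CoreSubset(self.best_sel.tolist()),
            value=self.best,
            trace=self.trace,
            seed=seed,
            evaluations=self.evals,
        )


class _IntStream:
    """Batched uniform integers from a Generator (cuts per-call overhead)."""

    def __init__(self, rng: np.random.Generator, bound: int, block: int = 2048) -> None:
        self.rng = rng
        self.bound = bound
        self.block = block
        self.buf = rng.integers(0, bound, size=block)
        self.pos = 0

    def next(self) -> int:
        if self.pos == self.block:
            self.buf = self.rng.integers(0, self.bound, size=self.block)
            self.pos = 0
        v = self.buf[self.pos]
        self.pos += 1
        return int(v)


class _UniformStream:
    """Batched uniform floats in [0, 1)."""

    def __init__(self, rng: np.random.Generator, block: int = 2048) -> None:
        self.rng = rng
        self.block = block
        self.buf = rng.random(block)
        self.pos = 0

    def next(self) -> float:
        if self.pos == self.block:
            self.buf = self.rng.random(self.block)
            self.pos = 0
        v = self.buf[self.pos]
        self.pos += 1
        return float(v)


def acceptance_probability(delta: float, t: float) -> float:
    """Metropolis acceptance: 1 if the move improves, else exp(delta / t)."""
    if t <= 0:
        raise ValueError("temperature must be positive")
    if delta > 0:
        return 1.0
    return math.exp(delta / t)


def swap_probability(delta_r: float, t_r: float, t_r1: float) -> float:
    """Replica-exchange probability between temperatures t_r < t_r1.

    ``delta_r`` is the score of the hotter replica minus that of the
    cooler one; a better solution always moves to the cooler replica.
    """
    if not 0 < t_r < t_r1:
        raise ValueError("temperatures must satisfy 0 < t_r < t_r1")
    if delta_r > 0:
        return 1.0
    return math.exp((1.0 / t_r - 1.0 / t_r1) * delta_r)


def _validate_k(n: int, k: int) -> None:
    if not 2 <= k <= n - 1:
        raise DataError(f"core size k={k} must satisfy 2 <= k <= n - 1 = {n - 1}")


def _random_start(ev: CompositeEvaluator, rng: np.random.Generator, k: int) -> float:
    perm = rng.permutation(ev.n)
    return ev.reset(perm[:k], perm[k:])


def random_descent(
    dataset: Dataset,
    objectives: ObjectiveConfig,
    k: int,
    stop: StopCondition,
    seed: int,
    ranges: NormalizationRanges | None = None,
) -> SearchResult:
    """Stochastic hill-climber: random swaps, strict-improvement acceptance."""
    _validate_k(dataset.n, k)
    rng = np.random.default_rng(seed)
    ev = CompositeEvaluator(dataset, objectives, ranges)
    cur = _random_start(ev, rng, k)
    run = _Run(stop)
    run.offer(cur, ev.sel)
    cur = _descent_loop(ev, rng, run, cur)
    return run.result(seed)


def _descent_loop(
    ev: CompositeEvaluator,
    rng: np.random.Generator,
    run: _Run,
    cur: float,
    stall_limit: int | None = None,
) -> float:
    """Shared descent kernel; also the GA mutation operator."""
    k = ev.sel.size
    isel = _IntStream(rng, k)
    iuns = _IntStream(rng, ev.n - k)
    stall = 0
    while not run.done():
        if stall_limit is not None and stall >= stall_limit:
            break
        new = ev.swap(isel.next(), iuns.next())
        run.evals += 1
        if new > cur:
            cur = new
            stall = 0
            run.offer(cur, ev.sel)
        else:
            ev.revert()
            stall += 1
    return cur


def parallel_tempering(
    dataset: Dataset,
    objectives: ObjectiveConfig,
    k: int,
    stop: StopCondition,
    seed: int,
    replicas: int = 10,
    t_min: float = 1e-8,
    t_max: float = 1e-4,
    steps_per_iteration: int = 500,
    ranges: NormalizationRanges | None = None,
) -> SearchResult:
    """Replica-exchange Metropolis search at fixed temperatures.

    ``replicas`` chains at temperatures equally spaced in
    ``[t_min, t_max]`` each take ``steps_per_iteration`` single-swap
    Metropolis steps per round; after every round, adjacent pairs
    (cold to hot) attempt to exchange their current selections. The
    global best is tracked across all replicas.
    """
    _validate_k(dataset.n, k)
    if replicas < 2:
        raise ValueError("parallel tempering needs at least 2 replicas")
    if not 0 < t_min < t_max:
        raise ValueError("need 0 < t_min < t_max")
    temps = np.linspace(t_min, t_max, replicas)
    ss = np.random.SeedSequence(seed)
    child_rngs = [np.random.default_rng(s) for s in ss.spawn(replicas + 1)]
    exchange_rng = child_rngs[-1]
    evs: list[CompositeEvaluator] = []
    cur: list[float] = []
    run = _Run(stop)
    for r in range(replicas):
        ev = CompositeEvaluator(dataset, objectives, ranges)
        score = _random_start(ev, child_rngs[r], k)
        evs.append(ev)
        cur.append(score)
        run.offer(score, ev.sel)
    isel = [_IntStream(child_rngs[r], k) for r in range(replicas)]
    iuns = [_IntStream(child_rngs[r], dataset.n - k) for r in range(replicas)]
    unif = [_UniformStream(child_rngs[r]) for r in range(replicas)]
    stopping = False
    while not stopping:
        for r in range(replicas):
            t = temps[r]
            ev = evs[r]
            for _ in range(steps_per_iteration):
                if run.done():
                    stopping = True
                    break
                new = ev.swap(isel[r].next(), iuns[r].next())
                run.evals += 1
                delta = new - cur[r]
                if delta > 0:
                    cur[r] = new
                    run.offer(new, ev.sel)
                elif unif[r].next() < math.exp(delta / t):
                    cur[r] = new
                else:
                    ev.revert()
            if stopping:
                break
        if stopping:
            break
        # one exchange pass over adjacent pairs, cold to hot
        for r in range(replicas - 1):
            prob = swap_probability(cur[r + 1] - cur[r], temps[r], temps[r + 1])
            if prob >= 1.0 or exchange_rng.random() < prob:
                evs[r], evs[r + 1] = evs[r + 1], evs[r]
                cur[r], cur[r + 1] = cur[r + 1], cur[r]
    return run.result(seed)


def _tournament(
    rng: np.random.Generator, scores: list[float], size: int
) -> int:
    candidates = rng.choice(len(scores), size=size, replace=False)
    return int(max(candidates, key=lambda i: scores[i]))


def _crossover(
    rng: np.random.Generator, p1: np.ndarray, p2: np.ndarray, k: int
) -> np.ndarray:
    union = np.union1d(p1, p2)
    return rng.choice(union, size=k, replace=False)


def genetic_algorithm(
    dataset: Dataset,
    objectives: ObjectiveConfig,
    k: int,
    stop: StopCondition,
    seed: int,
    population: int = 25,
    children: int = 5,
    tournament: int = 5,
    mutation_stall: int = 5000,
    discard: int = 5,
    ranges: NormalizationRanges | None = None,
) -> SearchResult:
    """Genetic algorithm over k-subsets with random-descent mutation.

    Each generation creates ``children`` offspring: two parents are
    picked by tournament, combined by uniformly sampling ``k``
    accessions from the union of their selections, and mutated by random
    descent until ``mutation_stall`` consecutive proposals fail to
    improve. Roulette survival then discards ``discard`` solutions with
    probability inversely proportional to their score, keeping the
    population size fixed.
    """
    _validate_k(dataset.n, k)
    if discard != children:
        raise ValueError("discard count must equal children (fixed population size)")
    if population <= tournament:
        raise ValueError("population must exceed tournament size")
    rng = np.random.default_rng(seed)
    ev = CompositeEvaluator(dataset, objectives, ranges)
    run = _Run(stop)
    pop_sel: list[np.ndarray] = []
    pop_score: list[float] = []
    for _ in range(population):
        score = _random_start(ev, rng, k)
        pop_sel.append(ev.sel.copy())
        pop_score.append(score)
        run.offer(score, ev.sel)
    while not run.done():
        for _ in range(children):
            if run.done():
                break
            i1 = _tournament(rng, pop_score, tournament)
            i2 = _tournament(rng, pop_score, tournament)
            child = _crossover(rng, pop_sel[i1], pop_sel[i2], k)
            score = ev.reset(child)
            run.offer(score, ev.sel)
            score = _descent_loop(ev, rng, run, score, stall_limit=mutation_stall)
            pop_sel.append(ev.sel.copy())
            pop_score.append(score)
        while len(pop_sel) > population:
            scores = np.array(pop_score)
            low = scores.min()
            shifted = scores + (abs(low) + 1e-9 if low <= 0 else 0.0)
            weights = 1.0 / shifted
            probs = weights / weights.sum()
            victim = int(rng.choice(len(pop_sel), p=probs))
            del pop_sel[victim]
            del pop_score[victim]
    return run.result(seed)


def brute_force_optimum(
    dataset: Dataset,
    objectives: ObjectiveConfig,
    k: int,
    ranges: NormalizationRanges | None = None,
    max_subsets: int = 10**6,
) -> tuple[CoreSubset, float]:
    """Exact optimum by exhaustive enumeration (test oracle).

    Ties are broken toward the lexicographically smallest index set
    (strict improvement while enumerating in lexicographic order).
    """
    n = dataset.n
    _validate_k(n, k)
    if math.comb(n, k) > max_subsets:
        raise ValueError(f"C({n}, {k}) exceeds the enumeration limit {max_subsets}")
    best_score = -math.inf
    best: tuple[int, ...] | None = None
    objs = objectives.objectives
    for subset in combinations(range(n), k):
        core = CoreSubset(subset)
        if ranges is None:
            score = objs[0].sign_adjusted(raw_value(dataset, core, objs[0]))
            if len(objs) > 1:
                raise DataError("multiple objectives require normalization ranges")
        else:
            score = 0.0
            for obj in objs:
                adjusted = obj.sign_adjusted(raw_value(dataset, core, obj))
                score += obj.weight * ranges.normalize(obj.measure, adjusted, clamp=False)
        if score > best_score:
            best_score = score
            best = subset
    return CoreSubset(best), float(best_score)


ENGINES = {
    "rd": random_descent,
    "pt": parallel_tempering,
    "ga": genetic_algorithm,
}
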