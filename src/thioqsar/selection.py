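"""Subset-search engines shared by the 2D regression and 3D kNN-MFA models.

Each engine searches over column subsets of a descriptor matrix, scoring a
candidate subset with a caller-supplied fitness function (typically the
leave-one-out q² of the downstream predictor).  Subsets larger than
``max_terms`` (or empty) are infeasible and scored −inf.

Engines:
  * stepwise — deterministic forward/backward moves with enter/remove
    improvement thresholds;
  * genetic algorithm — bitmask chromosomes, tournament selection, uniform
    crossover, bit-flip mutation, elitism of one (best-ever fitness is
    therefore non-decreasing over generations);
  * simulated annealing — single-bit-flip neighborhood with Metropolis
    acceptance exp(Δ/T) and geometric cooling; the initial temperature is
    set from sampled moves so early acceptance is ≈ 0.8.

All engines are reproducible bit-for-bit under a fixed seed, and all share a
fitness cache keyed by the subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = ["SelectionConfig", "SearchResult", "stepwise_search", "ga_search", "sa_search"]

NEG_INF = float("-inf")


@dataclass
class SelectionConfig:
    """Knobs for the subset-search engines; only the ones for the chosen
    method matter.  ``fitness`` names the criterion the caller wires in
    ('loo_q2' by default, 'r2' optional)."""

    method: str = "GA"                 # SW | GA | SA
    max_terms: int = 4
    fitness: str = "loo_q2"
    seed: int = 0
    standardize: bool = False
    # GA
    population: int = 60
    generations: int = 150
    p_crossover: float = 0.8
    p_mutation: float | None = None    # default 2 expected flips per chromosome
    tournament: int = 2
    immigrant_fraction: float = 0.2    # fresh random chromosomes per generation
    polish: bool = True                # hill-climb the best-ever subset at the end
    # SA
    t0: float | None = None            # default: initial acceptance ~0.8
    cooling: float = 0.95
    steps_per_temp: int = 60
    n_temps: int = 80
    # SW
    enter_threshold: float = 1e-4
    remove_threshold: float = 1e-4

    def __post_init__(self):
        if self.method not in ("SW", "GA", "SA"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")
        for name in ("p_crossover", "cooling"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.p_mutation is not None and not 0.0 < self.p_mutation < 1.0:
            raise ValueError("p_mutation must lie in (0, 1)")


@dataclass
class SearchResult:
    subset: tuple[int, ...]
    fitness: float
    trace: list[tuple[int, tuple[int, ...], float]] = field(default_factory=list)
    n_evaluations: int = 0


class _CachedFitness:
    def __init__(self, fn: Callable[[tuple[int, ...]], float], max_terms: int):
        self.fn = fn
        self.max_terms = max_terms
        self.cache: dict[tuple[int, ...], float] = {}
        self.n_evaluations = 0

    def __call__(self, subset) -> float:
        subset = tuple(sorted(subset))
        if not subset or len(subset) > self.max_terms:
            return NEG_INF
        if subset not in self.cache:
            self.n_evaluations += 1
            self.cache[subset] = float(self.fn(subset))
        return self.cache[subset]


def stepwise_search(
    n_columns: int, fitness_fn: Callable, cfg: SelectionConfig
) -> SearchResult:
    """Deterministic forward/backward stepwise subset search.

    Forward: add the column with the largest fitness gain, if the gain
    exceeds ``enter_threshold``.  Backward: drop any column whose removal
    improves fitness by more than ``remove_threshold``.  Ties break on the
    lower column index.  Terminates when no move qualifies or the subset has
    ``max_terms`` columns and no backward move helps.
    """
    fit = _CachedFitness(fitness_fn, cfg.max_terms)
    current: tuple[int, ...] = ()
    current_fit = NEG_INF
    trace = []
    step = 0
    while True:
        moved = False
        # backward pass first so an over-threshold removal frees a slot
        if len(current) > 1:
            best_drop, best_gain = None, cfg.remove_threshold
            for col in current:
                cand = tuple(c for c in current if c != col)
                gain = fit(cand) - current_fit
                if gain > best_gain:
                    best_drop, best_gain = col, gain
            if best_drop is not None:
                current = tuple(c for c in current if c != best_drop)
                current_fit = fit(current)
                moved = True
        if len(current) < cfg.max_terms:
            best_add, best_fit = None, current_fit
            for col in range(n_columns):
                if col in current:
                    continue
                f = fit(current + (col,))
                if f > best_fit + (cfg.enter_threshold if current else 0.0):
                    best_add, best_fit = col, f
            if best_add is not None:
                current = tuple(sorted(current + (best_add,)))
                current_fit = best_fit
                moved = True
        step += 1
        trace.append((step, current, current_fit))
        if not moved:
            break
    return SearchResult(
        subset=current, fitness=current_fit, trace=trace,
        n_evaluations=fit.n_evaluations,
    )


def _hill_climb(mask: np.ndarray, fit: _CachedFitness, max_terms: int):
    """Best-improvement local search over single flips and pair swaps.

    The stochastic engines reliably land within a move or two of the
    optimum but sample any *specific* neighbor only rarely; a deterministic
    polish of the best-ever subset closes that gap.  Monotone by
    construction, so the engines' non-decreasing fitness trace is preserved.
    """
    n = len(mask)
    current = mask.copy()
    current_fit = fit(tuple(np.nonzero(current)[0]))
    while True:
        best_move, best_fit = None, current_fit
        on = np.nonzero(current)[0]
        off = np.nonzero(~current)[0]
        neighbors = [(int(i),) for i in on]
        if len(on) < max_terms:
            neighbors += [(int(j),) for j in off]
        neighbors += [(int(i), int(j)) for i in on for j in off]
        for move in neighbors:
            cand = current.copy()
            for b in move:
                cand[b] ^= True
            f = fit(tuple(np.nonzero(cand)[0]))
            if f > best_fit + 1e-12:
                best_move, best_fit = move, f
        if best_move is None:
            return current, current_fit
        for b in best_move:
            current[b] ^= True
        current_fit = best_fit


def _random_feasible(rng, n_columns: int, max_terms: int) -> np.ndarray:
    size = int(rng.integers(1, max_terms + 1))
    mask = np.zeros(n_columns, dtype=bool)
    mask[rng.choice(n_columns, size=size, replace=False)] = True
    return mask


def ga_search(
    n_columns: int, fitness_fn: Callable, cfg: SelectionConfig
) -> SearchResult:
    """Genetic-algorithm subset search (see module docstring)."""
    if cfg.population < 4:
        raise ValueError("population must be >= 4")
    rng = np.random.default_rng(cfg.seed)
    fit = _CachedFitness(fitness_fn, cfg.max_terms)
    # expected flips per chromosome (default 2, i.e. p = 2/n per bit)
    expected_flips = (
        cfg.p_mutation * n_columns if cfg.p_mutation is not None else 2.0
    )

    def _mutate(child: np.ndarray) -> None:
        # Bit-flip mutation with the expected number of flips split evenly
        # between set and unset bits.  A single rate applied uniformly would
        # almost always grow a near-cap chromosome past max_terms (scored
        # -inf), stalling the search on sparse subsets of many columns.
        k = int(child.sum())
        p_off = min(0.5, expected_flips / (2.0 * max(k, 1)))
        p_on = min(0.5, expected_flips / (2.0 * max(n_columns - k, 1)))
        u = rng.random(n_columns)
        child ^= np.where(child, u < p_off, u < p_on)

    for _attempt in range(2):
        pop = [_random_feasible(rng, n_columns, cfg.max_terms)
               for _ in range(cfg.population)]
        scores = np.array([fit(tuple(np.nonzero(m)[0])) for m in pop])
        if np.any(np.isfinite(scores)):
            break
    else:
        raise RuntimeError("GA could not initialize a feasible population")

    best_idx = int(np.argmax(scores))
    best_mask = pop[best_idx].copy()
    best_fit = float(scores[best_idx])
    trace = [(0, tuple(np.nonzero(best_mask)[0]), best_fit)]

    n_immigrants = int(round(cfg.immigrant_fraction * cfg.population))
    for gen in range(1, cfg.generations + 1):
        new_pop = [best_mask.copy()]  # elitism of 1
        # random immigrants keep novel columns in circulation once the
        # population has converged around the elite
        for _ in range(min(n_immigrants, cfg.population - 1)):
            new_pop.append(_random_feasible(rng, n_columns, cfg.max_terms))
        while len(new_pop) < cfg.population:
            parents = []
            for _ in range(2):  # tournament selection
                idx = rng.integers(0, cfg.population, size=cfg.tournament)
                parents.append(pop[idx[np.argmax(scores[idx])]])
            c1, c2 = parents[0].copy(), parents[1].copy()
            if rng.random() < cfg.p_crossover:  # uniform crossover
                swap = rng.random(n_columns) < 0.5
                c1[swap], c2[swap] = parents[1][swap], parents[0][swap]
            for child in (c1, c2):
                _mutate(child)
                new_pop.append(child)
                if len(new_pop) >= cfg.population:
                    break
        pop = new_pop
        scores = np.array([fit(tuple(np.nonzero(m)[0])) for m in pop])
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_fit:
            best_fit = float(scores[gen_best])
            best_mask = pop[gen_best].copy()
        trace.append((gen, tuple(np.nonzero(best_mask)[0]), best_fit))

    if cfg.polish:
        best_mask, best_fit = _hill_climb(best_mask, fit, cfg.max_terms)
        trace.append((cfg.generations + 1, tuple(np.nonzero(best_mask)[0]), best_fit))
    return SearchResult(
        subset=tuple(int(i) for i in np.nonzero(best_mask)[0]),
        fitness=best_fit, trace=trace, n_evaluations=fit.n_evaluations,
    )


def sa_search(
    n_columns: int, fitness_fn: Callable, cfg: SelectionConfig
) -> SearchResult:
    """Simulated-annealing subset search (see module docstring)."""
    rng = np.random.default_rng(cfg.seed)
    fit = _CachedFitness(fitness_fn, cfg.max_terms)

    for _attempt in range(2):
        mask = _random_feasible(rng, n_columns, cfg.max_terms)
        current_fit = fit(tuple(np.nonzero(mask)[0]))
        if np.isfinite(current_fit):
            break
    else:
        raise RuntimeError("SA could not initialize a feasible state")

    t0 = cfg.t0
    if t0 is None:
        # calibrate: mean downhill |Δ| over sampled flips, accept ~0.8
        deltas = []
        for _ in range(min(30, max(10, n_columns))):
            cand = mask.copy()
            cand[rng.integers(n_columns)] ^= True
            f = fit(tuple(np.nonzero(cand)[0]))
            if np.isfinite(f) and f < current_fit:
                deltas.append(current_fit - f)
        t0 = (float(np.mean(deltas)) / -np.log(0.8)) if deltas else 1.0
        t0 = max(t0, 1e-6)

    best_mask, best_fit = mask.copy(), current_fit
    trace = [(0, tuple(np.nonzero(best_mask)[0]), best_fit)]
    temp = t0
    step = 0
    for _level in range(cfg.n_temps):
        for _ in range(cfg.steps_per_temp):
            step += 1
            # propose a single-bit flip among feasibility-preserving moves
            # (adding when at the size cap, or emptying the subset, would
            # always score -inf and waste the step)
            k = int(mask.sum())
            if k >= cfg.max_terms:
                candidates = np.nonzero(mask)[0]
            elif k <= 1:
                candidates = np.nonzero(~mask)[0]
            else:
                candidates = np.arange(n_columns)
            cand = mask.copy()
            cand[candidates[rng.integers(len(candidates))]] ^= True
            cand_fit = fit(tuple(np.nonzero(cand)[0]))
            delta = cand_fit - current_fit
            if delta >= 0 or (
                np.isfinite(cand_fit)
                and temp > 0
                and rng.random() < np.exp(delta / temp)
            ):
                mask, current_fit = cand, cand_fit
                if current_fit > best_fit:
                    best_mask, best_fit = mask.copy(), current_fit
        trace.append((step, tuple(np.nonzero(best_mask)[0]), best_fit))
        temp *= cfg.cooling
    if cfg.polish:
        best_mask, best_fit = _hill_climb(best_mask, fit, cfg.max_terms)
        trace.append((step + 1, tuple(np.nonzero(best_mask)[0]), best_fit))
    return SearchResult(
        subset=tuple(int(i) for i in np.nonzero(best_mask)[0]),
        fitness=best_fit, trace=trace, n_evaluations=fit.n_evaluations,
    )


def run_search(n_columns: int, fitness_fn: Callable, cfg: SelectionConfig) -> SearchResult:
    engine = {"SW": stepwise_search, "GA": ga_search, "SA": sa_search}[cfg.method]
    return engine(n_columns, fitness_fn, cfg)


def with_method(cfg: SelectionConfig, method: str) -> SelectionConfig:
    return replace(cfg, method=method)
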