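"""Real-coded genetic algorithm: roulette selection, two-point crossover,
uniform mutation, elitism.

The GA minimizes an objective (predicted contamination %, 0-100) over a
bounded box of protocol coordinates.  Roulette-wheel selection needs a
nonnegative bigger-is-better fitness, so minimization uses
fitness = 100 − objective, exploiting the known percentage scale; fitness
is clipped at 0, and if the whole population clips to 0 the selector
falls back to uniform probabilities.

Each generation: evaluate the population, copy the ``elite_count`` best
unchanged, produce a ``crossover_fraction`` share of the remaining
offspring by two-point crossover of roulette-selected parents, clone the
rest from roulette-selected parents, then apply per-gene uniform mutation
to every non-elite offspring.  With at least one elite the best objective
is non-increasing across generations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = ["GAConfig", "GAResult", "run_ga", "roulette_select",
           "two_point_crossover", "uniform_mutation", "DEFAULT_BOUNDS"]

# experimental envelope of the disinfection study:
# NaOCl 0-15 % v/v, H2O2 0-30 %, immersion 0-20 min
DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = ((0.0, 15.0), (0.0, 30.0), (0.0, 20.0))


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 200
    generations: int = 1000
    mutation_rate: float = 0.05  # per gene
    crossover_fraction: float = 0.6  # share of non-elite offspring from crossover
    elite_count: int = 2
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError(f"mutation_rate out of [0,1]: {self.mutation_rate}")
        if not 0 <= self.crossover_fraction <= 1:
            raise ValueError(f"crossover_fraction out of [0,1]: {self.crossover_fraction}")
        if not self.population_size > self.elite_count >= 0:
            raise ValueError("need population_size > elite_count >= 0")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid gene bounds ({lo}, {hi})")


@dataclass
class GAResult:
    best: np.ndarray  # best chromosome's genes
    best_objective: float
    history: list[tuple[float, float]] = field(default_factory=list)  # (best, mean) per generation
    seed: int = 0

    def write_trace_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["generation", "best_objective", "mean_objective"])
            for g, (b, m) in enumerate(self.history):
                w.writerow([g, b, m])

    def to_dict(self) -> dict:
        return {
            "best_genes": self.best.tolist(),
            "best_objective": self.best_objective,
            "generations": len(self.history),
            "seed": self.seed,
        }


def roulette_select(fitness_values, count: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``count`` indices with replacement, P(i) ∝ fitness_i.

    Requires nonnegative fitness with at least one positive value.
    """
    f = np.asarray(fitness_values, dtype=float)
    if (f < 0).any():
        raise ValueError("roulette selection requires nonnegative fitness")
    total = f.sum()
    if total <= 0:
        raise ValueError("roulette selection requires at least one positive fitness")
    return rng.choice(len(f), size=count, replace=True, p=f / total)


def two_point_crossover(
    parent_a: np.ndarray, parent_b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Swap the gene segment between two uniform cut points in {0, ..., L}.

    Cut points may coincide (empty segment, children = parents) or span the
    whole chromosome (full swap); on 3 genes this makes one- and two-gene
    exchanges both reachable.
    """
    a = np.asarray(parent_a, dtype=float)
    b = np.asarray(parent_b, dtype=float)
    L = len(a)
    if L < 2 or len(b) != L:
        raise ValueError("parents must share a gene count of at least 2")
    i, j = np.sort(rng.integers(0, L + 1, size=2))
    child_a, child_b = a.copy(), b.copy()
    child_a[i:j], child_b[i:j] = b[i:j], a[i:j]
    return child_a, child_b


def uniform_mutation(
    chromosome: np.ndarray,
    rate: float,
    bounds: Sequence[tuple[float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Each gene independently, with probability ``rate``, resampled uniformly
    within its bounds; otherwise unchanged."""
    if not 0 <= rate <= 1:
        raise ValueError(f"rate out of [0,1]: {rate}")
    genes = np.asarray(chromosome, dtype=float).copy()
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    mask = rng.random(len(genes)) < rate
    genes[mask] = lo[mask] + rng.random(mask.sum()) * (hi - lo)[mask]
    return genes


def _evaluate(objective: Callable, pop: np.ndarray) -> np.ndarray:
    """Evaluate the objective on a (n, L) population; accepts callables that
    are vectorized over rows or take one chromosome at a time."""
    try:
        vals = np.asarray(objective(pop), dtype=float).ravel()
        if vals.size != len(pop):
            raise TypeError
    except (TypeError, ValueError, IndexError):
        vals = np.array([float(np.asarray(objective(row)).ravel()[0]) for row in pop])
    if not np.isfinite(vals).all():
        bad = pop[np.flatnonzero(~np.isfinite(vals))[0]]
        raise ValueError(f"objective returned a non-finite value at chromosome {bad.tolist()}")
    return vals


def run_ga(objective: Callable, config: GAConfig) -> GAResult:
    """Minimize ``objective`` over the bounded box with the configured GA.

    ``objective`` maps a chromosome (or an (n, L) stack of chromosomes) to
    contamination % on the 0-100 scale.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    L = len(config.bounds)
    n = config.population_size
    pop = lo + rng.random((n, L)) * (hi - lo)
    history: list[tuple[float, float]] = []
    best_genes: np.ndarray | None = None
    best_obj = np.inf

    for _ in range(config.generations):
        vals = _evaluate(objective, pop)
        gen_best = int(vals.argmin())
        if vals[gen_best] < best_obj:
            best_obj = float(vals[gen_best])
            best_genes = pop[gen_best].copy()
        history.append((float(vals.min()), float(vals.mean())))

        fitness = np.clip(100.0 - vals, 0.0, None)
        if fitness.sum() <= 0:  # uniform fallback when every fitness clips to 0
            fitness = np.ones(n)

        elite_idx = np.argsort(vals)[: config.elite_count]
        elites = pop[elite_idx].copy()
        n_rest = n - config.elite_count
        n_cross = int(round(config.crossover_fraction * n_rest))
        offspring: list[np.ndarray] = []
        while len(offspring) < n_cross:
            pa, pb = roulette_select(fitness, 2, rng)
            ca, cb = two_point_crossover(pop[pa], pop[pb], rng)
            offspring.append(ca)
            if len(offspring) < n_cross:
                offspring.append(cb)
        n_clone = n_rest - len(offspring)
        if n_clone > 0:
            clones = roulette_select(fitness, n_clone, rng)
            offspring.extend(pop[i].copy() for i in clones)
        offspring = [
            uniform_mutation(c, config.mutation_rate, config.bounds, rng)
            for c in offspring
        ]
        pop = np.vstack([elites] + offspring) if offspring else elites

    vals = _evaluate(objective, pop)
    gen_best = int(vals.argmin())
    if vals[gen_best] < best_obj:
        best_obj = float(vals[gen_best])
        best_genes = pop[gen_best].copy()
    assert best_genes is not None
    return GAResult(best=best_genes, best_objective=best_obj,
                    history=history, seed=config.seed)
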