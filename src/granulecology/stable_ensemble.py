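"""Stable-ensemble search (ensemble quotient optimisation, uniform mode).

Finds a genus subset whose summed relative abundance is maximally stable —
minimum coefficient of variation (CV) across samples — by a genetic
algorithm over binary membership vectors, with an exhaustive enumerator as
oracle for small pools. The individual members' abundances may fluctuate;
the subset total is what is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .io_model import RelativeAbundanceMatrix


@dataclass
class GaParams:
    population: int = 200
    tournament_k: int = 3
    crossover_p: float = 0.5
    elitism: int = 5
    max_generations: int = 1000
    stall_generations: int = 50


@dataclass
class EnsembleSolution:
    members: list[str]
    cv: float
    trajectory: list[float]     # best CV per generation, non-increasing
    generations: int
    converged: bool
    seed: int | None = None


def ensemble_cv(subset, r: RelativeAbundanceMatrix) -> float:
    """CV of the subset's summed relative abundance across samples.

    Sample standard deviation (n−1 denominator) over the mean.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    idx = {t: i for i, t in enumerate(r.taxon_ids)}
    missing = [g for g in subset if g not in idx]
    if missing:
        raise KeyError(f"genera not in matrix: {missing}")
    totals = r.values[[idx[g] for g in subset]].sum(axis=0)
    mean = totals.mean()
    if mean == 0:
        raise ValueError("subset total abundance is zero in every sample")
    return float(totals.std(ddof=1) / mean)


def _cv_of_population(pop: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Vectorised CV for a population of membership vectors."""
    totals = pop.astype(float) @ values            # pop × samples
    mean = totals.mean(axis=1)
    sd = totals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.inf)
    cv[pop.sum(axis=1) == 0] = np.inf
    return cv


def _repair(pop: np.ndarray, max_size: int, mean_abund: np.ndarray,
            rng: np.random.Generator) -> None:
    """Enforce the size cap: drop lowest-mean-abundance members beyond it."""
    order = np.argsort(mean_abund)  # ascending: drop least abundant first
    for row in pop:
        excess = int(row.sum()) - max_size
        if excess > 0:
            on = [i for i in order if row[i]]
            row[on[:excess]] = 0
        if row.sum() == 0:
            row[rng.integers(len(row))] = 1


def search_stable_ensemble(
    r: RelativeAbundanceMatrix,
    max_size: int,
    ga: GaParams | None = None,
    seed: int = 0,
) -> EnsembleSolution:
    """Genetic-algorithm minimisation of the subset CV under a size cap.

    Tournament selection, uniform crossover, per-gene mutation at rate
    1/n_genera, elitism, and size repair; the lowest-CV singleton is seeded
    into the initial population, which guarantees the returned CV never
    exceeds that of any single genus. Stops after ``stall_generations``
    without improvement or ``max_generations`` total.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    if r.n_samples < 2:
        raise ValueError("need at least 2 samples")
    n = r.n_taxa
    if max_size > n:
        warnings.warn(f"max_size {max_size} exceeds pool size {n}; clamped")
        max_size = n
    ga = ga or GaParams()
    rng = np.random.default_rng(seed)
    values = r.values
    mean_abund = values.mean(axis=1)
    mut_p = 1.0 / n

    # initial population: every singleton, best first, then random members
    singles = np.eye(n, dtype=np.int8)
    single_cv = _cv_of_population(singles, values)
    order = np.argsort(single_cv)
    pop = list(singles[order[: min(n, ga.population)]])
    while len(pop) < ga.population:
        row = (rng.random(n) < min(max_size / n, 0.5)).astype(np.int8)
        pop.append(row)
    pop = np.array(pop)
    _repair(pop, max_size, mean_abund, rng)

    fitness = _cv_of_population(pop, values)
    best_i = int(np.argmin(fitness))
    best, best_cv = pop[best_i].copy(), float(fitness[best_i])
    trajectory = [best_cv]
    stall = 0
    gen = 0
    for gen in range(1, ga.max_generations + 1):
        elite_idx = np.argsort(fitness)[: ga.elitism]
        elite = pop[elite_idx].copy()
        # tournament selection of parents
        n_off = ga.population - ga.elitism
        cand = rng.integers(0, ga.population, (2 * n_off, ga.tournament_k))
        winners = cand[np.arange(2 * n_off), np.argmin(fitness[cand], axis=1)]
        pa, pb = pop[winners[:n_off]], pop[winners[n_off:]]
        # uniform crossover and per-gene mutation
        mask = rng.random((n_off, n)) < ga.crossover_p
        off = np.where(mask, pa, pb).astype(np.int8)
        flip = rng.random((n_off, n)) < mut_p
        off ^= flip.astype(np.int8)
        _repair(off, max_size, mean_abund, rng)
        pop = np.vstack([elite, off])
        # diversity maintenance: duplicates beyond the first occurrence are
        # replaced by fresh random individuals, preventing premature
        # convergence of the population onto one local optimum
        _, first = np.unique(pop, axis=0, return_index=True)
        dup = np.setdiff1d(np.arange(len(pop)), first)
        dup = dup[dup >= ga.elitism]
        if len(dup):
            fresh = (rng.random((len(dup), n)) <
                     min(max_size / n, 0.5)).astype(np.int8)
            _repair(fresh, max_size, mean_abund, rng)
            pop[dup] = fresh
        fitness = _cv_of_population(pop, values)
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_cv - 1e-15:
            best, best_cv = pop[gen_best].copy(), float(fitness[gen_best])
            stall = 0
        else:
            stall += 1
        trajectory.append(best_cv)
        if stall >= ga.stall_generations:
            break
    members = [r.taxon_ids[i] for i in np.flatnonzero(best)]
    return EnsembleSolution(
        members=members, cv=best_cv, trajectory=trajectory,
        generations=gen, converged=stall >= ga.stall_generations, seed=seed,
    )


def exhaustive_stable_ensemble(
    r: RelativeAbundanceMatrix, max_size: int, budget: int = 2_000_000
) -> EnsembleSolution:
    """Global CV minimum over all non-empty subsets of size ≤ max_size."""
    n = r.n_taxa
    max_size = min(max_size, n)
    total = sum(comb(n, k) for k in range(1, max_size + 1))
    if total > budget:
        raise ValueError(
            f"{total} subsets exceed the enumeration budget; use the GA"
        )
    values = r.values
    best_cv, best_members = np.inf, None
    for k in range(1, max_size + 1):
        for idx in combinations(range(n), k):
            totals = values[list(idx)].sum(axis=0)
            mean = totals.mean()
            if mean == 0:
                continue
            cv = totals.std(ddof=1) / mean
            if cv < best_cv - 1e-15:
                best_cv, best_members = float(cv), idx
    if best_members is None:
        raise ValueError("no subset with nonzero abundance")
    return EnsembleSolution(
        members=[r.taxon_ids[i] for i in best_members], cv=best_cv,
        trajectory=[best_cv], generations=0, converged=True,
    )
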