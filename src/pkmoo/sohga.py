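"""Single-objective hybrid genetic algorithm (SOHGA).

A classic generational GA over bit-string genomes — binary tournament
selection on the composite penalized fitness, single-point crossover,
one-bit-per-candidate mutation, elitism spread across Hamming-distance
niches — hybridized with a steepest-descent local search: every
``downhill_period`` generations the best model of each niche seeds a downhill
pass that evaluates all one-bit neighbors (n models for an n-bit genome),
moves to the single best improvement, and on a stall optionally evaluates all
n(n-1)/2 two-bit neighbors before giving up.  The search result is the
lowest-fitness record ever evaluated.

All randomness flows through one seeded generator, and every tie is broken by
(fitness, NEP, lexicographic bit string), so a run is a pure function of its
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigurationError
from .evaluation import EvalRecord, ModelEvaluator, PenaltyConfig
from .pk_engine import PKDataset
from .search_space import (
    Genome,
    GenomeSampler,
    SearchSpace,
    hamming,
    one_bit_neighbors,
    two_bit_neighbors,
    within_effect_limit,
)

__all__ = [
    "GAConfig",
    "tournament_select",
    "crossover",
    "mutate",
    "niche_heads",
    "downhill",
    "sohga_search",
    "SOHGASearch",
    "history_to_frame",
]


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters shared by the single- and multi-objective searches.

    Defaults are the single-objective settings (population 80, 20
    generations); the NSGA-II path overrides population_size/num_generations
    via :meth:`for_nsga2`.  ``num_parallel`` is a worker-count contract for
    concurrent model evaluation only — results are identical for any count.
    """

    population_size: int = 80
    num_generations: int = 20
    crossover_rate: float = 0.95
    mutation_rate: float = 0.95
    elitist_num: int = 4
    num_niches: int = 2
    niche_radius: int = 2
    downhill_period: int = 5
    two_bit_enabled: bool = True
    num_parallel: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ConfigurationError("rates must lie in [0, 1]")
        if self.elitist_num >= self.population_size:
            raise ConfigurationError("elitist_num must be < population_size")
        if self.downhill_period < 1:
            raise ConfigurationError("downhill_period must be >= 1")
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")

    @staticmethod
    def from_dict(d: Mapping[str, Any]) -> "GAConfig":
        known = {f for f in GAConfig.__dataclass_fields__}
        return GAConfig(**{k: v for k, v in d.items() if k in known})

    def for_nsga2(self) -> "GAConfig":
        """Table-default multi-objective sizes (population 100, 30 generations)."""
        from dataclasses import replace

        return replace(self, population_size=100, num_generations=30)


# ---------------------------------------------------------------------------
# GA operators


def tournament_select(
    population: Sequence[EvalRecord], rng: np.random.Generator
) -> EvalRecord:
    """Binary tournament: draw two (with replacement), keep the lower fitness.

    Ties break by lower NEP then lexicographic bit string.
    """
    if not population:
        raise ValueError("population is empty")
    i, j = rng.integers(len(population), size=2)
    a, b = population[i], population[j]
    return a if a.sort_key <= b.sort_key else b


def crossover(
    parent_a: Sequence[int],
    parent_b: Sequence[int],
    rate: float,
    rng: np.random.Generator,
) -> tuple[Genome, Genome]:
    """Single-point crossover with probability ``rate``; cut uniform in [1, n-1]."""
    a, b = tuple(parent_a), tuple(parent_b)
    if len(a) != len(b):
        raise ValueError("parents differ in length")
    n = len(a)
    if n < 2 or rng.random() >= rate:
        return a, b
    cut = int(rng.integers(1, n))
    return a[:cut] + b[cut:], b[:cut] + a[cut:]


def mutate(
    genome: Sequence[int], rate: float, rng: np.random.Generator
) -> Genome:
    """With probability ``rate``, flip exactly one uniformly chosen bit.

    The mutation probability is per candidate, not per bit.
    """
    g = tuple(genome)
    if not g or rng.random() >= rate:
        return g
    i = int(rng.integers(len(g)))
    return g[:i] + (1 - g[i],) + g[i + 1:]


def niche_heads(
    population: Sequence[EvalRecord], num_niches: int, niche_radius: int
) -> list[EvalRecord]:
    """Greedy niche heads: scan by ascending fitness; a record founds a new
    niche iff its Hamming distance to every existing head exceeds the radius."""
    heads: list[EvalRecord] = []
    for rec in sorted(population, key=lambda r: r.sort_key):
        if len(heads) >= num_niches:
            break
        if all(hamming(rec.genome, h.genome) > niche_radius for h in heads):
            heads.append(rec)
    return heads


def _select_elites(
    population: Sequence[EvalRecord],
    heads: Sequence[EvalRecord],
    elitist_num: int,
) -> list[EvalRecord]:
    """Elitist slots: round-robin across niche heads, then global fitness."""
    chosen: list[EvalRecord] = []
    seen: set[Genome] = set()
    for rec in list(heads) + sorted(population, key=lambda r: r.sort_key):
        if len(chosen) >= elitist_num:
            break
        if rec.genome not in seen:
            chosen.append(rec)
            seen.add(rec.genome)
    return chosen


# ---------------------------------------------------------------------------
# Downhill local search


def downhill(
    seed_record: EvalRecord,
    evaluator,
    two_bit_enabled: bool = True,
    stats: dict | None = None,
) -> EvalRecord:
    """Steepest-descent bit-flip search from an evaluated seed.

    Repeats: evaluate all one-bit neighbors; if any improves on the current
    fitness, move to the single best (ties by NEP then bit string) and start
    over.  When the one-bit pass stalls and ``two_bit_enabled``, evaluate all
    two-bit neighbors once; an improvement there resumes the one-bit loop.
    Terminates when neither neighborhood improves, so the returned record is a
    one-bit (and, when enabled, two-bit) local minimum, never worse than the
    seed.

    Neighbors exceeding the space's effect limit are skipped (models over the
    limit are discarded before running, never evaluated).

    ``stats`` (optional dict) receives bookkeeping: one-bit passes, two-bit
    stalls, and total neighbor evaluations requested.
    """
    space = evaluator.space
    current = seed_record
    n_one = n_two = n_evals = 0
    while True:
        n_one += 1
        nbrs = [g for g in one_bit_neighbors(current.genome)
                if within_effect_limit(space, g)]
        n_evals += len(nbrs)
        best = min(
            (evaluator.evaluate(g) for g in nbrs),
            key=lambda r: r.sort_key,
            default=None,
        )
        if best is not None and best.sort_key < current.sort_key:
            current = best
            continue
        if two_bit_enabled:
            n_two += 1
            nbrs2 = [g for g in two_bit_neighbors(current.genome)
                     if within_effect_limit(space, g)]
            n_evals += len(nbrs2)
            best2 = min(
                (evaluator.evaluate(g) for g in nbrs2),
                key=lambda r: r.sort_key,
                default=None,
            )
            if best2 is not None and best2.sort_key < current.sort_key:
                current = best2
                continue
        break
    if stats is not None:
        stats.update(
            one_bit_passes=n_one, two_bit_passes=n_two, neighbor_evaluations=n_evals
        )
    return current


# ---------------------------------------------------------------------------
# Main loop


def sohga_search(
    evaluator,
    config: GAConfig = GAConfig(),
    sampler: GenomeSampler | None = None,
) -> tuple[EvalRecord, list[dict[str, Any]]]:
    """Run the hybrid single-objective search; returns (best record, history).

    ``evaluator`` is any object with ``.space``, ``.evaluate``,
    ``.evaluate_many`` and a writable ``.generation`` (a
    :class:`~pkmoo.evaluation.ModelEvaluator` for real datasets, a
    :class:`~pkmoo.evaluation.FunctionEvaluator` for benchmarks).  The final
    result is the lowest-fitness record ever evaluated, which elitism makes
    non-increasing across generations.
    """
    space: SearchSpace = evaluator.space
    rng = np.random.default_rng(config.rng_seed)
    sampler = sampler or GenomeSampler(space)

    evaluator.generation = 0
    population = evaluator.evaluate_many(
        sampler.sample(config.population_size, rng), n_jobs=config.num_parallel
    )
    best = min(population, key=lambda r: r.sort_key)
    history: list[dict[str, Any]] = []

    def log_generation(gen: int, pop: Sequence[EvalRecord], did_downhill: bool):
        fits = [r.fitness for r in pop if r.feasible]
        history.append(
            {
                "generation": gen,
                "best_fitness": best.fitness,
                "best_bits": best.bits,
                "pop_best": min((r.fitness for r in pop), default=float("inf")),
                "pop_mean": float(np.mean(fits)) if fits else float("inf"),
                "n_unique": len({r.genome for r in pop}),
                "downhill": did_downhill,
            }
        )

    log_generation(0, population, False)

    for gen in range(1, config.num_generations + 1):
        evaluator.generation = gen
        heads = niche_heads(population, config.num_niches, config.niche_radius)
        elites = _select_elites(population, heads, config.elitist_num)

        n_children = config.population_size - len(elites)
        children: list[Genome] = []
        while len(children) < n_children:
            pa = tournament_select(population, rng)
            pb = tournament_select(population, rng)
            ca, cb = crossover(pa.genome, pb.genome, config.crossover_rate, rng)
            for child in (ca, cb):
                child = mutate(child, config.mutation_rate, rng)
                child = sampler.replace_if_over_limit(child, rng)
                children.append(child)
        children = children[:n_children]
        offspring = evaluator.evaluate_many(children, n_jobs=config.num_parallel)
        population = elites + offspring

        did_downhill = gen % config.downhill_period == 0
        if did_downhill:
            heads = niche_heads(population, config.num_niches, config.niche_radius)
            for head in heads:
                improved = downhill(head, evaluator, config.two_bit_enabled)
                if improved.sort_key < head.sort_key:
                    idx = population.index(head)
                    population[idx] = improved

        gen_best = min(population, key=lambda r: r.sort_key)
        if gen_best.sort_key < best.sort_key:
            best = gen_best
        log_generation(gen, population, did_downhill)

    return best, history


def history_to_frame(history: list[dict[str, Any]]) -> pd.DataFrame:
    return pd.DataFrame(history)


class SOHGASearch(BaseEstimator):
    """scikit-learn-style front end for the hybrid single-objective search.

    ``fit`` takes a :class:`PKDataset` (or NONMEM-style DataFrame) and runs
    the GA over ``space``; afterwards ``best_record_`` holds the
    lowest-fitness evaluated model, ``history_`` the per-generation log and
    ``evaluator_`` the cache of every model fitted.
    """

    def __init__(
        self,
        space: SearchSpace,
        config: GAConfig = GAConfig(),
        penalties: PenaltyConfig = PenaltyConfig(),
        method: str = "foce_i",
        route: str = "iv_bolus",
    ):
        self.space = space
        self.config = config
        self.penalties = penalties
        self.method = method
        self.route = route

    def fit(self, X, y: Any = None) -> "SOHGASearch":
        ds = X if isinstance(X, PKDataset) else PKDataset(X)
        self.evaluator_ = ModelEvaluator(
            self.space, ds, self.penalties, method=self.method, route=self.route
        )
        self.best_record_, self.history_ = sohga_search(self.evaluator_, self.config)
        return self
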