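"""Multi-objective model search with NSGA-II over (OFV, NEP).

Both objectives are minimized: the -2 log-likelihood (OFV) measures fit, the
number of estimated parameters (NEP) measures complexity.  One model
dominates another when it is not worse on both objectives and strictly better
on at least one; the search output is the Pareto front — the mutually
non-dominated set, along which OFV strictly decreases as NEP increases.

The generational loop is canonical NSGA-II: fast non-dominated sorting
(domination counts n_p and dominated-sets S_p, peeled front by front),
crowding-distance diversity with infinite distance at front boundaries,
crowded binary tournament selection, and environmental selection truncating
the combined parent+offspring pool by rank then descending crowding.
Diagnostic flags (convergence, covariance step, correlation, condition
number) ride along on every record but never enter the objective comparison.

The local downhill step is driven by the same two objectives: neighbors of
archive members are merged whenever the current archive does not dominate
them, so a downhill pass can only improve the front.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .evaluation import EvalRecord, ModelEvaluator, PenaltyConfig
from .pk_engine import PKDataset
from .search_space import (
    Genome,
    GenomeSampler,
    SearchSpace,
    one_bit_neighbors,
    two_bit_neighbors,
    within_effect_limit,
)
from .sohga import GAConfig, crossover, mutate

logger = logging.getLogger(__name__)

__all__ = [
    "dominates",
    "non_dominated_sort",
    "crowding_distance",
    "environmental_selection",
    "FrontAssignment",
    "ParetoArchive",
    "moo_downhill",
    "nsga2_search",
    "NSGA2Search",
]

ObjectiveVector = tuple[float, float]


def _objectives(items: Sequence[Any]) -> list[ObjectiveVector]:
    return [
        tuple(map(float, getattr(x, "objectives", x)))  # records or raw tuples
        for x in items
    ]


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """True iff ``a`` is not worse on every objective and better on one."""
    a = getattr(a, "objectives", a)
    b = getattr(b, "objectives", b)
    not_worse = all(x <= y for x, y in zip(a, b))
    strictly_better = any(x < y for x, y in zip(a, b))
    return not_worse and strictly_better


def non_dominated_sort(population: Sequence[Any]) -> list[list[int]]:
    """Fast non-dominated sorting; returns fronts as index lists.

    Computes, for every member p, the domination count n_p (how many members
    dominate p) and the dominated set S_p; front 1 is {n_p == 0}, and fronts
    peel off by decrementing n_q for q in S_p of the current front.  Accepts
    records with an ``objectives`` attribute or raw objective tuples.
    """
    objs = _objectives(population)
    n = len(objs)
    if n == 0:
        raise ValueError("population is empty")
    n_p = np.zeros(n, dtype=int)
    S: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(objs[i], objs[j]):
                S[i].append(j)
                n_p[j] += 1
            elif dominates(objs[j], objs[i]):
                S[j].append(i)
                n_p[i] += 1
    fronts: list[list[int]] = []
    current = [i for i in range(n) if n_p[i] == 0]
    while current:
        fronts.append(current)
        nxt = []
        for p in current:
            for q in S[p]:
                n_p[q] -= 1
                if n_p[q] == 0:
                    nxt.append(q)
        current = sorted(nxt)
    return fronts


def crowding_distance(front: Sequence[Any]) -> np.ndarray:
    """Crowding distances for one mutually non-dominated front.

    Distances start at 0; per objective the front is sorted, the two boundary
    members get +inf, and each interior member accumulates the gap between
    its neighbors normalized by the objective's range (a fully degenerate
    objective, max == min, contributes nothing).  Fronts of size 1 or 2 are
    all boundaries, hence all infinite.  Input order is irrelevant: distances
    are returned aligned with the input.
    """
    objs = _objectives(front)
    n = len(objs)
    if n == 0:
        return np.zeros(0)
    d = np.zeros(n)
    if n <= 2:
        d[:] = np.inf
        return d
    m = len(objs[0])
    for k in range(m):
        vals = np.array([o[k] for o in objs])
        order = np.argsort(vals, kind="stable")
        d[order[0]] = d[order[-1]] = np.inf
        rng = vals[order[-1]] - vals[order[0]]
        if rng <= 0:
            continue
        for pos in range(1, n - 1):
            i = order[pos]
            if np.isinf(d[i]):
                continue
            d[i] += (vals[order[pos + 1]] - vals[order[pos - 1]]) / rng
    return d


def environmental_selection(
    pool: Sequence[EvalRecord], population_size: int
) -> list[EvalRecord]:
    """Next generation from the combined parent+offspring pool.

    Whole fronts are admitted in rank order; the first front that does not
    fit is truncated by descending crowding distance (ties: lower NEP, then
    lexicographic bit string).
    """
    if len(pool) < population_size:
        raise ValueError("pool smaller than the population size")
    fronts = non_dominated_sort(pool)
    out: list[EvalRecord] = []
    for front_idx in fronts:
        if len(out) + len(front_idx) <= population_size:
            out.extend(pool[i] for i in front_idx)
            continue
        crowd = crowding_distance([pool[i] for i in front_idx])
        ranked = sorted(
            zip(front_idx, crowd),
            key=lambda t: (-t[1], pool[t[0]].nep, pool[t[0]].genome),
        )
        out.extend(pool[i] for i, _ in ranked[: population_size - len(out)])
        break
    return out


@dataclass(frozen=True)
class FrontAssignment:
    """Rank (1 = non-dominated) and crowding distance of one record."""

    rank: int
    crowding: float


def rank_and_crowd(population: Sequence[EvalRecord]) -> list[FrontAssignment]:
    """Front rank and within-front crowding distance for every member."""
    fronts = non_dominated_sort(population)
    out: list[FrontAssignment | None] = [None] * len(population)
    for rank, front_idx in enumerate(fronts, start=1):
        crowd = crowding_distance([population[i] for i in front_idx])
        for i, c in zip(front_idx, crowd):
            out[i] = FrontAssignment(rank=rank, crowding=float(c))
    return out  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Pareto archive


class ParetoArchive:
    """Running non-dominated set over everything evaluated so far.

    Infeasible records (non-finite objectives) are excluded.  Duplicate
    objective vectors are deduplicated, keeping the lexicographically
    smallest bit string.  ``provenance`` maps each member's genome to the
    generation it entered and whether a downhill pass found it.
    """

    def __init__(self) -> None:
        self.records: list[EvalRecord] = []
        self.provenance: dict[Genome, dict[str, Any]] = {}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.sorted())

    def sorted(self) -> list[EvalRecord]:
        """Members along the front: ascending NEP, then OFV, then bits."""
        return sorted(self.records, key=lambda r: (r.nep, r.ofv, r.genome))

    def add(
        self, rec: EvalRecord, generation: int | None = None, downhill: bool = False
    ) -> bool:
        """Merge one record; returns True when the archive changed."""
        if not rec.feasible or not np.isfinite(rec.ofv):
            return False
        for member in self.records:
            if dominates(member.objectives, rec.objectives):
                return False
            if member.objectives == rec.objectives:
                if rec.genome < member.genome:  # dedup: keep smaller bit string
                    self._replace(member, rec, generation, downhill)
                    return True
                return False
        survivors = [
            m for m in self.records if not dominates(rec.objectives, m.objectives)
        ]
        for m in self.records:
            if m not in survivors:
                self.provenance.pop(m.genome, None)
        survivors.append(rec)
        self.records = survivors
        self.provenance[rec.genome] = {"generation": generation, "downhill": downhill}
        return True

    def _replace(self, old: EvalRecord, new: EvalRecord, generation, downhill) -> None:
        self.records = [m for m in self.records if m is not old] + [new]
        self.provenance.pop(old.genome, None)
        self.provenance[new.genome] = {"generation": generation, "downhill": downhill}

    def update(
        self,
        records: Iterable[EvalRecord],
        generation: int | None = None,
        downhill: bool = False,
    ) -> int:
        changed = 0
        for rec in sorted(records, key=lambda r: r.sort_key):
            changed += self.add(rec, generation, downhill)
        return changed

    def copy(self) -> "ParetoArchive":
        out = ParetoArchive()
        out.records = list(self.records)
        out.provenance = {k: dict(v) for k, v in self.provenance.items()}
        return out

    def hypervolume(self, reference: ObjectiveVector | None = None) -> float:
        """Dominated 2-D hypervolume w.r.t. a reference point (defaults to the
        worst observed objective values + 1)."""
        if not self.records:
            return 0.0
        pts = sorted(r.objectives for r in self.records)
        if reference is None:
            reference = (
                max(p[0] for p in pts) + 1.0,
                max(p[1] for p in pts) + 1.0,
            )
        hv, prev_nep = 0.0, reference[1]
        for ofv, nep in sorted(pts, key=lambda p: p[0]):  # ascending OFV
            width = reference[0] - ofv
            height = prev_nep - nep
            if width > 0 and height > 0:
                hv += width * height
                prev_nep = nep
        return hv


def moo_downhill(
    front: ParetoArchive,
    evaluator,
    two_bit_enabled: bool = True,
    generation: int | None = None,
) -> ParetoArchive:
    """Objective-driven local search around the archive.

    Each pass evaluates the one-bit neighbors of every archive member and
    merges any candidate the current archive does not dominate; when a full
    one-bit pass changes nothing and two-bit flips are enabled, a two-bit
    pass runs once, resuming one-bit passes if it helps.  Merge-only
    acceptance guarantees the output archive is never dominated by the input.
    Neighbors exceeding the effect limit are never evaluated.
    """
    if len(front) == 0:
        raise ValueError("archive is empty")
    space: SearchSpace = evaluator.space
    archive = front.copy()

    def pass_once(neighbor_fn) -> bool:
        changed = False
        for member in list(archive.sorted()):
            if member not in archive.records:
                continue  # pruned by an earlier merge in this pass
            for g in neighbor_fn(member.genome):
                if not within_effect_limit(space, g):
                    continue
                rec = evaluator.evaluate(g)
                if rec.feasible:
                    changed |= archive.add(rec, generation, downhill=True)
        return changed

    while True:
        if pass_once(one_bit_neighbors):
            continue
        if two_bit_enabled and pass_once(two_bit_neighbors):
            continue
        break
    return archive


# ---------------------------------------------------------------------------
# Main loop


def _crowded_tournament(
    population: Sequence[EvalRecord],
    assign: Sequence[FrontAssignment],
    rng: np.random.Generator,
) -> EvalRecord:
    """Binary tournament on (rank, crowding): lower rank wins, then larger
    crowding, then the deterministic (NEP, bits) tie-break."""
    i, j = rng.integers(len(population), size=2)
    key_i = (assign[i].rank, -assign[i].crowding, population[i].nep, population[i].genome)
    key_j = (assign[j].rank, -assign[j].crowding, population[j].nep, population[j].genome)
    return population[i] if key_i <= key_j else population[j]


def nsga2_search(
    evaluator,
    config: GAConfig | None = None,
    sampler: GenomeSampler | None = None,
) -> tuple[ParetoArchive, list[dict[str, Any]]]:
    """Run the NSGA-II search; returns (archive, history).

    The initial population comes from the effect-limit sampler; offspring
    exceeding the limit are discarded and replaced before evaluation, so
    every model run satisfies the limit.  Every ``downhill_period``
    generations the current archive front seeds :func:`moo_downhill` and the
    discoveries are folded back into the population.  The returned archive is
    the non-dominated set over *all* evaluated models; history rows tag each
    generation (the final row describes the last generation's rank-1 front).

    ``elitist_num`` in the config is accepted but ignored: canonical NSGA-II
    environmental selection over the combined parent+offspring pool already
    preserves every rank-1 member that fits, subsuming elitism.  Likewise
    ``num_niches``/``niche_radius`` play no role in the multi-objective path.
    """
    config = config or GAConfig().for_nsga2()
    space: SearchSpace = evaluator.space
    rng = np.random.default_rng(config.rng_seed)
    sampler = sampler or GenomeSampler(space)
    logger.info(
        "NSGA-II: elitist_num=%d and niche settings are ignored by the "
        "multi-objective path (environmental selection subsumes elitism)",
        config.elitist_num,
    )

    evaluator.generation = 0
    population = evaluator.evaluate_many(
        sampler.sample(config.population_size, rng), n_jobs=config.num_parallel
    )
    archive = ParetoArchive()
    archive.update(population, generation=0)
    history: list[dict[str, Any]] = []

    def log_generation(gen: int, pop: Sequence[EvalRecord], did_downhill: bool):
        feas = [r for r in pop if r.feasible]
        front = (
            [feas[i] for i in non_dominated_sort(feas)[0]] if feas else []
        )
        history.append(
            {
                "generation": gen,
                "archive_size": len(archive),
                "archive_min_ofv": min((r.ofv for r in archive.records), default=np.nan),
                "archive_min_nep": min((r.nep for r in archive.records), default=np.nan),
                "pop_front_size": len(front),
                "downhill": did_downhill,
                "hypervolume": archive.hypervolume(),
            }
        )

    log_generation(0, population, False)

    for gen in range(1, config.num_generations + 1):
        evaluator.generation = gen
        assign = rank_and_crowd(population)
        children: list[Genome] = []
        while len(children) < config.population_size:
            pa = _crowded_tournament(population, assign, rng)
            pb = _crowded_tournament(population, assign, rng)
            ca, cb = crossover(pa.genome, pb.genome, config.crossover_rate, rng)
            for child in (ca, cb):
                child = mutate(child, config.mutation_rate, rng)
                child = sampler.replace_if_over_limit(child, rng)
                children.append(child)
        children = children[: config.population_size]
        offspring = evaluator.evaluate_many(children, n_jobs=config.num_parallel)
        archive.update(offspring, generation=gen)
        population = environmental_selection(
            list(population) + list(offspring), config.population_size
        )

        did_downhill = gen % config.downhill_period == 0
        if did_downhill and len(archive):
            improved = moo_downhill(
                archive, evaluator, config.two_bit_enabled, generation=gen
            )
            new_members = [r for r in improved.records if r not in population]
            archive = improved
            if new_members:
                population = environmental_selection(
                    list(population) + new_members, config.population_size
                )
        log_generation(gen, population, did_downhill)

    return archive, history


class NSGA2Search(BaseEstimator):
    """scikit-learn-style front end for the multi-objective search.

    After ``fit``, ``pareto_front_`` lists the non-dominated evaluated models
    in ascending NEP order, ``archive_`` is the :class:`ParetoArchive` with
    provenance, and ``evaluator_`` caches every fitted model.
    """

    def __init__(
        self,
        space: SearchSpace,
        config: GAConfig | None = None,
        penalties: PenaltyConfig = PenaltyConfig(),
        method: str = "foce_i",
        route: str = "iv_bolus",
    ):
        self.space = space
        self.config = config
        self.penalties = penalties
        self.method = method
        self.route = route

    def fit(self, X, y: Any = None) -> "NSGA2Search":
        ds = X if isinstance(X, PKDataset) else PKDataset(X)
        self.evaluator_ = ModelEvaluator(
            self.space, ds, self.penalties, method=self.method, route=self.route
        )
        self.archive_, self.history_ = nsga2_search(
            self.evaluator_, self.config or GAConfig().for_nsga2()
        )
        self.pareto_front_ = self.archive_.sorted()
        return self
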