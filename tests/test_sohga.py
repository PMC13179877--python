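"""GA operators, downhill local search, and the hybrid single-objective loop."""

import numpy as np
import pytest

import pkmoo
from pkmoo.evaluation import FunctionEvaluator
from pkmoo.search_space import hamming, one_bit_neighbors, two_bit_neighbors
from pkmoo.sohga import (
    GAConfig,
    crossover,
    downhill,
    mutate,
    niche_heads,
    sohga_search,
    tournament_select,
)


def make_records(fitnesses, n_bits=6):
    recs = []
    for i, f in enumerate(fitnesses):
        bits = tuple(int(b) for b in np.binary_repr(i, n_bits))
        recs.append(
            pkmoo.EvalRecord(
                genome=bits, spec=None, fit=None, nep=3, ofv=f, fitness=f,
                flags={},
            )
        )
    return recs


class TestTournament:
    def test_lower_fitness_wins(self):
        recs = make_records([1060.0, 1200.0])
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert tournament_select(recs, rng).fitness in (1060.0, 1200.0)
        # force the pair (0, 1) repeatedly: winner must be the 1060 record
        class PairRng:
            def integers(self, n, size):
                return np.array([0, 1])
            def random(self):
                return 0.0
        assert tournament_select(recs, PairRng()).fitness == 1060.0

    def test_identical_pair_returns_that_record(self):
        recs = make_records([5.0])
        class SameRng:
            def integers(self, n, size):
                return np.array([0, 0])
        assert tournament_select(recs, SameRng()) is recs[0]

    def test_selection_frequency_decreases_with_fitness_rank(self):
        recs = make_records([10.0, 20.0, 30.0, 40.0, 50.0])
        rng = np.random.default_rng(42)
        counts = {r.fitness: 0 for r in recs}
        for _ in range(10_000):
            counts[tournament_select(recs, rng).fitness] += 1
        freqs = [counts[f] for f in sorted(counts)]
        assert all(a > b for a, b in zip(freqs, freqs[1:]))
        # closed form for binary tournaments: P(rank r of N) = (2(N-r)-1)/N^2
        n = len(recs)
        for r, f in enumerate(freqs):
            p = (2 * (n - r) - 1) / n**2
            sd = np.sqrt(10_000 * p * (1 - p))
            assert abs(f - 10_000 * p) < 4 * sd


class TestCrossoverMutation:
    def test_zero_rates_are_identity(self):
        rng = np.random.default_rng(0)
        a, b = (1, 1, 1, 0, 0, 0), (0, 0, 0, 1, 1, 1)
        assert crossover(a, b, 0.0, rng) == (a, b)
        assert mutate(a, 0.0, rng) == a

    def test_single_point_cut_swaps_tails(self):
        a, b = (1, 1, 1, 0, 0, 0), (0, 0, 0, 1, 1, 1)

        class CutRng:
            def random(self):
                return 0.0  # always cross over
            def integers(self, lo, hi=None):
                return 3
        ca, cb = crossover(a, b, 1.0, CutRng())
        assert ca == (1, 1, 1, 1, 1, 1)
        assert cb == (0, 0, 0, 0, 0, 0)

    def test_locus_wise_bit_conservation(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = tuple(int(x) for x in rng.integers(0, 2, 8))
            b = tuple(int(x) for x in rng.integers(0, 2, 8))
            ca, cb = crossover(a, b, 1.0, rng)
            for i in range(8):
                assert sorted((ca[i], cb[i])) == sorted((a[i], b[i]))

    def test_mutation_flips_exactly_one_bit_at_rate_one(self):
        rng = np.random.default_rng(2)
        g = (0,) * 12
        for _ in range(100):
            assert hamming(g, mutate(g, 1.0, rng)) == 1

    def test_mutated_locus_is_uniform(self):
        rng = np.random.default_rng(3)
        g = (0,) * 12
        counts = np.zeros(12)
        for _ in range(12_000):
            m = mutate(g, 1.0, rng)
            counts[[i for i in range(12) if m[i] != g[i]][0]] += 1
        p = 1 / 12
        sd = np.sqrt(12_000 * p * (1 - p))
        assert np.all(np.abs(counts - 1000) < 4 * sd)


def greedy_oracle(bits, key_of, two_bit):
    """Independently coded steepest-descent reference."""
    cur = bits
    while True:
        nb = one_bit_neighbors(cur)
        best = min(nb, key=key_of)
        if key_of(best) < key_of(cur):
            cur = best
            continue
        if two_bit:
            nb2 = two_bit_neighbors(cur)
            best2 = min(nb2, key=key_of)
            if key_of(best2) < key_of(cur):
                cur = best2
                continue
        break
    return cur


@pytest.fixture(scope="module")
def lookup(tiny_space):
    rng = np.random.default_rng(99)
    return {g: float(rng.uniform(0, 1000)) for g in tiny_space.enumerate_genomes()}


class TestDownhill:
    def _evaluator(self, tiny_space, table):
        return FunctionEvaluator(tiny_space, lambda g: (table[g], 3))

    def test_matches_greedy_oracle_from_50_random_seeds(self, tiny_space, lookup):
        rng = np.random.default_rng(7)
        pen = 30.0  # nep fixed: fitness = ofv + 10*3

        def key_of(g):
            return (lookup[g] + pen, 3, g)

        for two_bit in (False, True):
            for _ in range(25):
                g = tuple(int(b) for b in rng.integers(0, 2, tiny_space.n_total_bits))
                ev = self._evaluator(tiny_space, lookup)
                got = downhill(ev.evaluate(g), ev, two_bit_enabled=two_bit)
                assert got.genome == greedy_oracle(g, key_of, two_bit)

    def test_result_is_local_minimum_and_never_worse_than_seed(
        self, tiny_space, lookup
    ):
        rng = np.random.default_rng(13)
        for _ in range(10):
            g = tuple(int(b) for b in rng.integers(0, 2, tiny_space.n_total_bits))
            ev = self._evaluator(tiny_space, lookup)
            seed = ev.evaluate(g)
            got = downhill(seed, ev, two_bit_enabled=True)
            assert got.fitness <= seed.fitness
            for nb in one_bit_neighbors(got.genome) + two_bit_neighbors(got.genome):
                assert ev.evaluate(nb).sort_key >= got.sort_key

    def test_local_minimum_seed_returns_unchanged_after_n_evaluations(
        self, tiny_space, lookup
    ):
        # locate a strict 1+2-bit local minimum first
        ev = self._evaluator(tiny_space, lookup)
        rec = downhill(ev.evaluate((0,) * 10), ev, two_bit_enabled=True)
        ev2 = self._evaluator(tiny_space, lookup)
        seeded = ev2.evaluate(rec.genome)
        before = ev2.n_objective_calls
        stats = {}
        again = downhill(seeded, ev2, two_bit_enabled=False, stats=stats)
        assert again is seeded
        assert ev2.n_objective_calls - before == tiny_space.n_total_bits
        assert stats["neighbor_evaluations"] == tiny_space.n_total_bits

    def test_evaluation_budget_bookkeeping(self, tiny_space, lookup):
        n = tiny_space.n_total_bits
        ev = self._evaluator(tiny_space, lookup)
        stats = {}
        downhill(ev.evaluate((1,) * n), ev, two_bit_enabled=True, stats=stats)
        bound = stats["one_bit_passes"] * n + stats["two_bit_passes"] * n * (n - 1) // 2
        assert stats["neighbor_evaluations"] <= bound


class TestSearchLoop:
    def test_recovers_exhaustive_minimum(self, tiny_space, bench_objective):
        ev_all = FunctionEvaluator(tiny_space, bench_objective)
        true_best = min(
            (ev_all.evaluate(g) for g in tiny_space.enumerate_genomes()),
            key=lambda r: r.sort_key,
        )
        hits = 0
        for seed in range(3):
            ev = FunctionEvaluator(tiny_space, bench_objective)
            best, _ = sohga_search(ev, GAConfig(rng_seed=seed))
            hits += best.fitness == true_best.fitness
        assert hits == 3

    def test_best_so_far_is_non_increasing(self, tiny_space, bench_objective):
        ev = FunctionEvaluator(tiny_space, bench_objective)
        _, history = sohga_search(ev, GAConfig(rng_seed=5))
        best = [h["best_fitness"] for h in history]
        assert all(a >= b for a, b in zip(best, best[1:]))

    def test_same_seed_reproduces_identical_history(self, tiny_space, bench_objective):
        run = lambda: sohga_search(
            FunctionEvaluator(tiny_space, bench_objective), GAConfig(rng_seed=11)
        )
        (b1, h1), (b2, h2) = run(), run()
        assert b1.genome == b2.genome and b1.fitness == b2.fitness
        assert h1 == h2

    def test_niche_heads_respect_radius(self, tiny_space, bench_objective):
        ev = FunctionEvaluator(tiny_space, bench_objective)
        rng = np.random.default_rng(0)
        recs = [
            ev.evaluate(tuple(int(b) for b in rng.integers(0, 2, 10)))
            for _ in range(60)
        ]
        heads = niche_heads(recs, num_niches=3, niche_radius=2)
        for i, a in enumerate(heads):
            for b in heads[i + 1:]:
                assert hamming(a.genome, b.genome) > 2

    def test_selection_only_never_increases_diversity(
        self, tiny_space, bench_objective
    ):
        cfg = GAConfig(
            rng_seed=3, crossover_rate=0.0, mutation_rate=0.0,
            num_generations=6, downhill_period=100, population_size=30,
            elitist_num=2,
        )
        ev = FunctionEvaluator(tiny_space, bench_objective)
        _, history = sohga_search(ev, cfg)
        uniques = [h["n_unique"] for h in history]
        assert all(a >= b for a, b in zip(uniques, uniques[1:]))

    def test_worker_count_does_not_change_results(self, mini_space, mini_dataset):
        def run(workers):
            ev = pkmoo.ModelEvaluator(
                mini_space, mini_dataset, method="fo", route="oral_first_order"
            )
            cfg = GAConfig(
                population_size=6, num_generations=2, elitist_num=1,
                downhill_period=100, rng_seed=4, num_parallel=workers,
            )
            best, history = sohga_search(ev, cfg)
            return best.genome, best.fitness, [row["bits"] for row in ev.log]

        g1, f1, log1 = run(1)
        g2, f2, log2 = run(2)
        assert (g1, f1) == (g2, f2)
        assert log1 == log2
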