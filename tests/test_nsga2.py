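"""Non-dominated sorting, crowding, environmental selection, MOO downhill."""

import numpy as np
import pytest

import pkmoo
from pkmoo.evaluation import FunctionEvaluator
from pkmoo.nsga2 import (
    ParetoArchive,
    crowding_distance,
    dominates,
    environmental_selection,
    moo_downhill,
    non_dominated_sort,
    nsga2_search,
)
from pkmoo.sohga import GAConfig, sohga_search


def recs_from_objectives(objs, n_bits=8):
    out = []
    for i, (ofv, nep) in enumerate(objs):
        bits = tuple(int(b) for b in np.binary_repr(i, n_bits))
        out.append(
            pkmoo.EvalRecord(
                genome=bits, spec=None, fit=None, nep=int(nep), ofv=float(ofv),
                fitness=float(ofv), flags={},
            )
        )
    return out


def brute_force_fronts(objs):
    """O(N^2) peel-by-scan oracle, coded independently of the S_p machinery."""
    remaining = list(range(len(objs)))
    fronts = []
    while remaining:
        front = [
            i
            for i in remaining
            if not any(dominates(objs[j], objs[i]) for j in remaining if j != i)
        ]
        fronts.append(sorted(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


class TestDomination:
    def test_strictly_better_on_both(self):
        assert dominates((8034.5, 5), (8040.0, 6))

    def test_identical_vectors_do_not_dominate(self):
        assert not dominates((1.0, 2), (1.0, 2))

    def test_trade_off_is_incomparable(self):
        assert not dominates((8024.6, 23), (9813.4, 5))
        assert not dominates((9813.4, 5), (8024.6, 23))

    def test_weak_domination_needs_one_strict(self):
        assert dominates((1.0, 2), (1.0, 3))


class TestSorting:
    def test_mutually_non_dominated_is_single_front(self):
        objs = [(1.0, 5), (2.0, 4), (3.0, 3)]
        assert non_dominated_sort(objs) == [[0, 1, 2]]

    def test_strict_chain_gives_singleton_fronts(self):
        objs = [(1.0, 1), (2.0, 2), (3.0, 3)]
        assert non_dominated_sort(objs) == [[0], [1], [2]]

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            objs = [
                (float(o), int(n))
                for o, n in zip(rng.uniform(0, 100, 200), rng.integers(1, 12, 200))
            ]
            assert non_dominated_sort(objs) == brute_force_fronts(objs)

    def test_no_record_dominated_within_or_by_later_fronts(self):
        rng = np.random.default_rng(3)
        objs = [
            (float(o), int(n))
            for o, n in zip(rng.uniform(0, 50, 100), rng.integers(1, 8, 100))
        ]
        fronts = non_dominated_sort(objs)
        for k, front in enumerate(fronts):
            later = [i for f in fronts[k:] for i in f]
            for i in front:
                assert not any(dominates(objs[j], objs[i]) for j in later)


class TestCrowding:
    def test_small_fronts_are_all_infinite(self):
        assert np.all(np.isinf(crowding_distance([(1.0, 2)])))
        assert np.all(np.isinf(crowding_distance([(1.0, 2), (2.0, 1)])))

    def test_three_point_worked_example(self):
        d = crowding_distance([(0.0, 2.0), (1.0, 1.0), (2.0, 0.0)])
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)

    def test_input_order_invariance(self):
        pts = [(0.0, 5.0), (1.0, 4.0), (3.0, 2.0), (6.0, 0.0)]
        d = crowding_distance(pts)
        perm = [2, 0, 3, 1]
        dp = crowding_distance([pts[i] for i in perm])
        for j, i in enumerate(perm):
            assert dp[j] == pytest.approx(d[i]) or (np.isinf(dp[j]) and np.isinf(d[i]))

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        ofv = np.sort(rng.uniform(0, 100, 12))
        nep = np.sort(rng.uniform(1, 20, 12))[::-1]
        pts = list(zip(ofv, nep))
        scaled = [(o * 1000.0, n) for o, n in pts]
        d1, d2 = crowding_distance(pts), crowding_distance(scaled)
        finite = ~np.isinf(d1)
        np.testing.assert_allclose(d1[finite], d2[finite], rtol=1e-12)

    def test_degenerate_objective_contributes_nothing(self):
        pts = [(0.0, 7.0), (1.0, 7.0), (2.0, 7.0)]
        d = crowding_distance(pts)
        assert d[1] == pytest.approx(1.0)  # only the varying objective counts


class TestEnvironmentalSelection:
    def test_truncates_overfull_front_by_crowding(self):
        # one front of 5, capacity 3: boundaries kept, then largest interior gap
        objs = [(0.0, 10.0), (1.0, 6.0), (2.0, 5.0), (3.0, 4.0), (10.0, 0.0)]
        pool = recs_from_objectives(objs)
        kept = environmental_selection(pool, 3)
        crowd = crowding_distance(objs)
        expected = sorted(
            range(5), key=lambda i: (-crowd[i], pool[i].nep, pool[i].genome)
        )[:3]
        assert {r.genome for r in kept} == {pool[i].genome for i in expected}

    def test_identical_objectives_resolved_deterministically(self):
        pool = recs_from_objectives([(5.0, 3)] * 6)
        kept1 = environmental_selection(pool, 4)
        kept2 = environmental_selection(list(pool), 4)
        assert [r.genome for r in kept1] == [r.genome for r in kept2]

    def test_matches_reference_selector_on_random_pools(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            objs = [
                (float(o), int(n))
                for o, n in zip(rng.uniform(0, 30, 40), rng.integers(1, 9, 40))
            ]
            pool = recs_from_objectives(objs)
            kept = environmental_selection(pool, 15)
            # reference: fill whole oracle fronts, truncate last by crowding
            fronts = brute_force_fronts(objs)
            ref = []
            for fr in fronts:
                if len(ref) + len(fr) <= 15:
                    ref.extend(fr)
                else:
                    crowd = crowding_distance([objs[i] for i in fr])
                    order = sorted(
                        zip(fr, crowd),
                        key=lambda t: (-t[1], pool[t[0]].nep, pool[t[0]].genome),
                    )
                    ref.extend(i for i, _ in order[: 15 - len(ref)])
                    break
            assert {r.genome for r in kept} == {pool[i].genome for i in ref}

    def test_rank_one_members_survive_when_they_fit(self):
        rng = np.random.default_rng(31)
        objs = [
            (float(o), int(n))
            for o, n in zip(rng.uniform(0, 30, 40), rng.integers(1, 9, 40))
        ]
        pool = recs_from_objectives(objs)
        front1 = {pool[i].genome for i in non_dominated_sort(pool)[0]}
        kept = {r.genome for r in environmental_selection(pool, 20)}
        assert front1 <= kept


class TestArchiveAndDownhill:
    def test_archive_is_pareto_staircase(self, tiny_space, bench_objective):
        ev = FunctionEvaluator(tiny_space, bench_objective)
        arch = ParetoArchive()
        rng = np.random.default_rng(2)
        for _ in range(300):
            g = tuple(int(b) for b in rng.integers(0, 2, 10))
            arch.add(ev.evaluate(g))
        members = arch.sorted()
        for a, b in zip(members, members[1:]):
            assert b.nep > a.nep and b.ofv < a.ofv

    def test_locally_optimal_archive_unchanged(self, tiny_space, bench_objective):
        ev = FunctionEvaluator(tiny_space, bench_objective)
        full = ParetoArchive()
        for g in tiny_space.enumerate_genomes():
            full.add(ev.evaluate(g))
        out = moo_downhill(full, ev, two_bit_enabled=True)
        assert {r.genome for r in out.records} == {r.genome for r in full.records}

    def test_downhill_result_within_true_front(self, tiny_space, bench_objective):
        ev = FunctionEvaluator(tiny_space, bench_objective)
        true_front = {
            ev.evaluate(g).objectives
            for g in tiny_space.enumerate_genomes()
        }
        fronts = non_dominated_sort(sorted(true_front))
        truth = {sorted(true_front)[i] for i in fronts[0]}
        seed_arch = ParetoArchive()
        rng = np.random.default_rng(8)
        for _ in range(50):
            g = tuple(int(b) for b in rng.integers(0, 2, 10))
            seed_arch.add(ev.evaluate(g))
        out = moo_downhill(seed_arch, ev, two_bit_enabled=True)
        found = {r.objectives for r in out.records}
        assert found <= truth

    def test_hypervolume_never_decreases_across_passes(
        self, tiny_space, bench_objective
    ):
        ev = FunctionEvaluator(tiny_space, bench_objective)
        arch = ParetoArchive()
        rng = np.random.default_rng(4)
        for _ in range(20):
            arch.add(ev.evaluate(tuple(int(b) for b in rng.integers(0, 2, 10))))
        ref = (1e4, 50.0)
        hv0 = arch.hypervolume(ref)
        out = moo_downhill(arch, ev, two_bit_enabled=False)
        assert out.hypervolume(ref) >= hv0 - 1e-12


class TestSearchLoop:
    def _true_front(self, space, objective):
        ev = FunctionEvaluator(space, objective)
        objs = sorted({ev.evaluate(g).objectives for g in space.enumerate_genomes()})
        fronts = non_dominated_sort(objs)
        return {objs[i] for i in fronts[0]}

    def test_recovers_exhaustive_pareto_front(self, tiny_space, bench_objective):
        truth = self._true_front(tiny_space, bench_objective)
        hits = 0
        for seed in range(3):
            ev = FunctionEvaluator(tiny_space, bench_objective)
            arch, _ = nsga2_search(ev, GAConfig(rng_seed=seed).for_nsga2())
            hits += {r.objectives for r in arch.records} == truth
        assert hits == 3

    def test_equal_nep_space_collapses_to_single_objective_optimum(
        self, tiny_space, bench_objective
    ):
        flat = lambda g: (bench_objective(g)[0], 4)  # constant NEP everywhere
        ev = FunctionEvaluator(tiny_space, flat)
        arch, _ = nsga2_search(ev, GAConfig(rng_seed=1).for_nsga2())
        assert len(arch) == 1
        ev2 = FunctionEvaluator(tiny_space, flat)
        best, _ = sohga_search(ev2, GAConfig(rng_seed=1))
        assert arch.records[0].ofv == pytest.approx(best.ofv)

    def test_same_seed_reproduces_identical_archive_and_history(
        self, tiny_space, bench_objective
    ):
        def run():
            ev = FunctionEvaluator(tiny_space, bench_objective)
            cfg = GAConfig(rng_seed=21, population_size=40, num_generations=8)
            return nsga2_search(ev, cfg)

        (a1, h1), (a2, h2) = run(), run()
        assert [r.genome for r in a1.sorted()] == [r.genome for r in a2.sorted()]
        assert h1 == h2

    def test_every_evaluated_model_satisfies_effect_limit(self, six_set_space):
        objective = lambda g: (
            1000.0 - 7.0 * sum(g), 3 + pkmoo.decode(six_set_space, g).total_effects
        )
        ev = FunctionEvaluator(six_set_space, objective)
        cfg = GAConfig(rng_seed=2, population_size=20, num_generations=6)
        nsga2_search(ev, cfg)
        for genome in ev.cache:
            assert pkmoo.decode(six_set_space, genome).total_effects <= 4

    def test_history_tags_downhill_generations(self, tiny_space, bench_objective):
        ev = FunctionEvaluator(tiny_space, bench_objective)
        cfg = GAConfig(rng_seed=0, population_size=30, num_generations=6,
                       downhill_period=3)
        _, history = nsga2_search(ev, cfg)
        assert [h["downhill"] for h in history] == [
            False, False, False, True, False, False, True
        ]
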