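"""Evolutionary engine: operators, selection, the generational loop."""

import numpy as np
import pandas as pd
import pytest

from cage_evolve.ea import (
    Candidate,
    EAConfig,
    combine_and_rerank,
    crossover,
    evolve,
    initialize,
    mutate,
    roulette_select,
)
from cage_evolve.fitness import FitnessRecord


def candidate(node, linker, ff):
    rec = FitnessRecord(cage_id=f"{node}+{linker}", E_binding=-1.0, A_complex=0.1, A_cage=0.1)
    rec.ff = ff
    return Candidate(node, linker, rec)


class TestInitialize:
    def test_seeded_determinism_and_size(self, toy_library):
        cfg = EAConfig(population_size=20, seed=11)
        p1 = initialize(toy_library, cfg, np.random.default_rng(11))
        p2 = initialize(toy_library, cfg, np.random.default_rng(11))
        assert [c.key for c in p1] == [c.key for c in p2]
        assert len(p1) == 20

    def test_different_seeds_differ(self, toy_library):
        cfg = EAConfig(population_size=20)
        pops = [
            {c.key for c in initialize(toy_library, cfg, np.random.default_rng(s))}
            for s in range(5)
        ]
        assert len({frozenset(p) for p in pops}) == 5

    def test_initial_population_is_diverse(self, toy_library):
        cfg = EAConfig(population_size=20, seed=0)
        pop = initialize(toy_library, cfg, np.random.default_rng(0))
        assert len({c.key for c in pop}) == 20

    def test_small_library_warns(self, toy_library):
        cfg = EAConfig(population_size=20)
        tiny = type(toy_library)(toy_library.nodes[:2], toy_library.linkers[:2])
        with pytest.warns(UserWarning):
            initialize(tiny, cfg, np.random.default_rng(0))


class TestCrossover:
    def test_exchanges_building_blocks(self):
        o1, o2 = crossover(candidate("N1", "L1", 1.0), candidate("N2", "L2", 1.0))
        assert (o1.node_id, o1.linker_id) == ("N1", "L2")
        assert (o2.node_id, o2.linker_id) == ("N2", "L1")

    def test_self_crossover_reproduces_parent(self):
        o1, o2 = crossover(candidate("N1", "L1", 1.0), candidate("N1", "L1", 1.0))
        assert o1.key == o2.key == ("N1", "L1")

    def test_seven_crossovers_give_fourteen_offspring(self, toy_library, landscape):
        res = evolve(toy_library, landscape, EAConfig(population_size=20, generations=1, seed=0))
        assert set(res.pool_sizes) == {44}  # 20 + 14 + 10


class TestMutate:
    def test_fittest_member_always_mutated(self, toy_library):
        pop = [candidate("node01", "link01", 0.1), candidate("node02", "link02", 9.0)]
        cfg = EAConfig(population_size=2, mutations_per_gen=1)
        mutants = mutate(pop, toy_library, cfg, np.random.default_rng(0))
        assert len(mutants) == 1
        # derived from the fittest parent: shares its node or its linker
        assert mutants[0].node_id == "node02" or mutants[0].linker_id == "link02"
        assert mutants[0].key != ("node02", "link02")

    def test_similar_linker_matches_brute_force_neighbour(self, toy_library):
        from cage_evolve.precursors import dice_similarity, most_similar

        linker = toy_library.linkers[4]
        pool = [p for p in toy_library.linkers if p.id != linker.id]
        expected = max(pool, key=lambda p: (dice_similarity(linker, p), tuple(-ord(ch) for ch in p.id)))
        assert most_similar(linker, pool).id == expected.id

    def test_operator_draws_are_equiprobable(self, toy_library):
        """Across many seeded mutations the four operators appear ~25% each."""
        from cage_evolve import ea as ea_module

        counts = {op: 0 for op in ea_module.MUTATION_OPERATORS}
        orig = ea_module._apply_operator

        def counting(candidate, operator, library, rng):
            counts[operator] += 1
            return orig(candidate, operator, library, rng)

        pop = [candidate("node03", "link05", 1.0), candidate("node04", "link06", 2.0)]
        cfg = EAConfig(population_size=2, mutations_per_gen=10)
        ea_module._apply_operator = counting
        try:
            rng = np.random.default_rng(123)
            for _ in range(1000):
                mutate(pop, toy_library, cfg, rng)
        finally:
            ea_module._apply_operator = orig
        total = sum(counts.values())
        assert total == 10_000
        # 3-sigma binomial band around p = 1/4
        sigma = np.sqrt(total * 0.25 * 0.75)
        for op, n in counts.items():
            assert abs(n - total * 0.25) < 3 * sigma, (op, n)


class TestRouletteSelect:
    def test_zero_fitness_member_unreachable(self):
        pool = [candidate("N1", "L1", 1.0), candidate("N2", "L2", 0.0)]
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert roulette_select(pool, 1, rng)[0].key == ("N1", "L1")

    def test_single_draw_frequencies_match_probabilities(self):
        pool = [candidate("N1", "L1", 3.0), candidate("N2", "L2", 1.0)]
        rng = np.random.default_rng(42)
        wins = sum(
            roulette_select(pool, 1, rng, elitism=False)[0].key == ("N1", "L1")
            for _ in range(10_000)
        )
        sigma = np.sqrt(10_000 * 0.75 * 0.25)
        assert abs(wins - 7500) < 3 * sigma

    def test_elite_always_survives(self):
        pool = [candidate(f"N{i}", f"L{i}", float(i)) for i in range(10)]
        rng = np.random.default_rng(5)
        for _ in range(30):
            keys = {c.key for c in roulette_select(pool, 3, rng)}
            assert ("N9", "L9") in keys

    def test_all_zero_fitness_falls_back_to_uniform(self):
        pool = [candidate(f"N{i}", f"L{i}", 0.0) for i in range(6)]
        with pytest.warns(UserWarning):
            out = roulette_select(pool, 4, np.random.default_rng(0))
        assert len(out) == 4

    def test_selection_prefers_distinct_compositions(self):
        pool = [candidate("N1", "L1", 5.0) for _ in range(5)] + [
            candidate(f"N{i}", f"L{i}", 1.0) for i in range(2, 6)
        ]
        out = roulette_select(pool, 5, np.random.default_rng(3))
        assert len({c.key for c in out}) == 5

    def test_oversubscription_rejected(self):
        with pytest.raises(ValueError):
            roulette_select([candidate("N", "L", 1.0)], 2, np.random.default_rng(0))


class TestEvolve:
    def test_deterministic_runs(self, toy_library, landscape):
        cfg = EAConfig(population_size=10, generations=5, seed=21)
        r1 = evolve(toy_library, landscape, cfg)
        r2 = evolve(toy_library, landscape, cfg)
        pd.testing.assert_frame_equal(r1.generations, r2.generations)

    def test_elite_best_ff_never_decreases(self, toy_library, landscape):
        for seed in range(5):
            res = evolve(toy_library, landscape, EAConfig(population_size=10, generations=15, seed=seed))
            assert (np.diff(res.generations["max_ff"].to_numpy()) >= -1e-9).all()

    def test_generation_record_invariants(self, toy_library, landscape):
        res = evolve(toy_library, landscape, EAConfig(population_size=10, generations=5, seed=2))
        g = res.generations
        assert (g["max_ff"] >= g["mean_ff"]).all()
        assert (g["mean_ff"] >= g["min_ff"]).all()
        assert list(g["generation"]) == list(range(len(g)))


class TestCombine:
    def _evolved(self, toy_library, landscape, seed):
        return evolve(
            toy_library, landscape, EAConfig(population_size=10, generations=8, seed=seed)
        ).population

    def test_identical_populations_dedup_to_population_size(self, toy_library, landscape):
        pop = self._evolved(toy_library, landscape, 3)
        combined = combine_and_rerank([pop] * 5)
        assert len(combined) == len({c.key for c in pop})

    def test_upper_bound_and_order_invariance(self, toy_library, landscape):
        pops = [self._evolved(toy_library, landscape, s) for s in range(3)]
        combined = combine_and_rerank(pops)
        assert len(combined) <= 30
        reversed_combined = combine_and_rerank(list(reversed(pops)))
        pd.testing.assert_frame_equal(
            combined.reset_index(drop=True), reversed_combined.reset_index(drop=True)
        )

    def test_code_names_follow_descending_ff(self, toy_library, landscape):
        combined = combine_and_rerank([self._evolved(toy_library, landscape, 7)])
        assert combined["code_name"].iloc[0] == "C1"
        assert (combined["FF"].to_numpy()[:-1] >= combined["FF"].to_numpy()[1:]).all()
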