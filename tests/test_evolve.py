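"""Evolutionary engine: operators, selection, generation loop, aggregation."""

import numpy as np
import pytest

from evoscreen import chemlib
from evoscreen.errors import InputError
from evoscreen.evolve import (
    EvolutionConfig,
    Individual,
    aggregate_runs,
    crossover,
    init_population,
    mutate,
    rank_select,
    run_evolution,
)
from evoscreen.scoring import OracleConfig, SyntheticOracle


def _individual(library, index=0, fitness=None):
    mols = list(chemlib.enumerate_products(library))
    return Individual(molecule=mols[index % len(mols)], fitness=fitness)


@pytest.fixture(scope="module")
def oracle(planted):
    _, config = planted
    return SyntheticOracle(config)


@pytest.fixture()
def small_config():
    return EvolutionConfig(
        seed_size=60, survivors=15, generations=10,
        offspring_per_generation=30, elitism_count=3, rng_seed=42,
    )


class TestInitPopulation:
    def test_random_mode_returns_seed_size_molecules(self, search_library, oracle):
        config = EvolutionConfig(seed_size=200, survivors=50, rng_seed=1)
        pop = init_population(search_library, config, oracle)
        assert len(pop) == 200
        assert all(ind.fitness is not None for ind in pop)

    def test_seeded_mode_picks_from_pool_plus_random_extras(self, search_library, oracle):
        pool = list(chemlib.enumerate_products(search_library))[:304]
        config = EvolutionConfig(
            seed_size=200, survivors=50, seeded_pool=pool,
            seeded_pick=200, seeded_random_extra=50, rng_seed=1)
        pop = init_population(search_library, config, oracle)
        assert len(pop) == 250
        pool_keys = {m.key for m in pool}
        seeds = [ind for ind in pop if ind.operator == "seed"]
        assert len(seeds) == 200
        assert all(ind.key in pool_keys for ind in seeds)

    def test_small_pool_is_taken_whole(self, search_library, oracle):
        pool = list(chemlib.enumerate_products(search_library))[:20]
        config = EvolutionConfig(
            seed_size=200, survivors=50, seeded_pool=pool,
            seeded_pick=200, seeded_random_extra=5, rng_seed=1)
        pop = init_population(search_library, config, oracle)
        assert len(pop) == 25

    def test_fixed_seed_reproduces_population(self, search_library, oracle):
        config = EvolutionConfig(seed_size=30, survivors=10, rng_seed=9)
        a = init_population(search_library, config, oracle)
        b = init_population(search_library, config, oracle)
        assert [i.key for i in a] == [i.key for i in b]


class TestMutate:
    def test_substrate_mutation_changes_exactly_one_slot(self, search_library):
        rng = np.random.default_rng(0)
        parent = _individual(search_library, 10)
        child = mutate(parent, search_library, rng, kind="substrate")
        diffs = sum(
            a != b
            for a, b in zip(parent.molecule.substrate_ids, child.molecule.substrate_ids)
        )
        assert diffs == 1 and child.operator == "mutation_substrate"

    def test_reaction_mutation_keeps_substrates_allowed_in_new_slots(self, mixed_library):
        rng = np.random.default_rng(1)
        parent = _individual(mixed_library, 0)
        child = mutate(parent, mixed_library, rng, kind="reaction")
        assert child.molecule.reaction_id != parent.molecule.reaction_id
        for pos, sid in enumerate(child.molecule.substrate_ids):
            assert sid in mixed_library.slots[(child.molecule.reaction_id, pos)]

    def test_singleton_library_returns_parent_flagged_unchanged(self, search_library):
        rng = np.random.default_rng(2)
        parent = _individual(search_library, 0)
        child = mutate(parent, search_library, rng, kind="reaction")
        assert child.unchanged and child.key == parent.key

    def test_validity_sweep_of_1000_mutations(self, mixed_library):
        """Every mutated child validates against the library (operator closure)."""
        rng = np.random.default_rng(3)
        mols = list(chemlib.enumerate_products(mixed_library))
        for i in range(1000):
            parent = Individual(molecule=mols[i % len(mols)])
            kind = "substrate" if i % 2 else "reaction"
            child = mutate(parent, mixed_library, rng, kind=kind)
            again = chemlib.assemble_product(
                mixed_library, child.molecule.reaction_id, child.molecule.substrate_ids
            )
            assert again.product_smiles == child.molecule.product_smiles


class TestCrossover:
    def test_same_reaction_parents_swap_one_slot(self, search_library):
        mols = list(chemlib.enumerate_products(search_library))
        a = Individual(molecule=mols[0])
        b = Individual(molecule=mols[45])  # differs in both slots
        assert a.molecule.substrate_ids[0] != b.molecule.substrate_ids[0]
        assert a.molecule.substrate_ids[1] != b.molecule.substrate_ids[1]
        rng = np.random.default_rng(4)
        ca, cb = crossover(a, b, search_library, rng)
        # children are the two recombinants of the swapped slot
        swapped = [
            pos for pos in range(2)
            if ca.molecule.substrate_ids[pos] == b.molecule.substrate_ids[pos]
        ]
        assert len(swapped) == 1
        pos = swapped[0]
        assert cb.molecule.substrate_ids[pos] == a.molecule.substrate_ids[pos]

    def test_identical_parents_flagged_unchanged(self, search_library):
        mols = list(chemlib.enumerate_products(search_library))
        a = Individual(molecule=mols[7])
        b = Individual(molecule=mols[7])
        ca, cb = crossover(a, b, search_library, np.random.default_rng(5))
        assert ca.unchanged and cb.unchanged
        assert ca.key == cb.key == a.key

    def test_different_reaction_parents_fall_back_to_mutation(self, mixed_library):
        mols = list(chemlib.enumerate_products(mixed_library))
        two = next(m for m in mols if len(m.substrate_ids) == 2)
        three = next(m for m in mols if len(m.substrate_ids) == 3)
        ca, cb = crossover(Individual(molecule=two), Individual(molecule=three),
                           mixed_library, np.random.default_rng(6))
        for child, parent in ((ca, two), (cb, three)):
            assert child.molecule.reaction_id == parent.reaction_id
            diffs = sum(a != b for a, b in
                        zip(parent.substrate_ids, child.molecule.substrate_ids))
            assert diffs == 1


class TestRankSelect:
    def _population(self, n):
        return [
            Individual(
                molecule=chemlib.LibraryMolecule("r", (f"s{i}",), f"key-{i:03d}"),
                fitness=-5.0 + 0.1 * i,
            )
            for i in range(n)
        ]

    def test_selects_exactly_k(self):
        pop = self._population(300)
        out = rank_select(pop, 50, 5, np.random.default_rng(0))
        assert len(out) == 50

    def test_best_always_survives_with_elitism(self):
        pop = self._population(20)
        best = min(pop, key=lambda i: i.fitness)
        for seed in range(20):
            out = rank_select(pop, 5, 1, np.random.default_rng(seed))
            assert best in out

    def test_k_larger_than_population_is_error(self):
        with pytest.raises(InputError):
            rank_select(self._population(3), 5, 1, np.random.default_rng(0))

    def test_selection_frequency_monotone_in_rank(self):
        """10 000 seeded trials: better ranks are selected at least as often."""
        pop = self._population(10)
        counts = {ind.key: 0 for ind in pop}
        rng = np.random.default_rng(17)
        for _ in range(10_000):
            for ind in rank_select(pop, 5, 0, rng):
                counts[ind.key] += 1
        freqs = [counts[f"key-{i:03d}"] / 10_000 for i in range(10)]
        for a, b in zip(freqs, freqs[1:]):
            assert a >= b - 0.02


class TestRunEvolution:
    def test_generation_summaries_match_config(self, search_library, oracle, small_config):
        log = run_evolution(search_library, oracle, small_config)
        assert len(log.generations) == small_config.generations

    def test_same_seed_gives_identical_run_logs(self, search_library, oracle,
                                                small_config, tmp_path):
        a = run_evolution(search_library, oracle, small_config)
        b = run_evolution(search_library, oracle, small_config)
        pa, pb = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        a.to_jsonl(pa)
        b.to_jsonl(pb)
        assert pa.read_bytes() == pb.read_bytes()
        assert a.summary_table().equals(b.summary_table())

    def test_best_fitness_monotone_with_elitism(self, search_library, oracle, small_config):
        log = run_evolution(search_library, oracle, small_config)
        best = [g.best_fitness for g in log.generations]
        assert all(b1 >= b2 for b2, b1 in zip(best[1:], best[:-1])) or \
            all(b2 <= b1 for b1, b2 in zip(best, best[1:]))
        assert best == sorted(best, reverse=True)

    def test_finds_top_percentile_with_partial_evaluation(
        self, search_library, oracle, small_config, planted
    ):
        """On the noiseless planted landscape the search reaches the
        brute-force top 1% while evaluating under 30% of the library."""
        landscape, _ = planted
        library_size = search_library.product_count()
        for seed in range(5):
            config = EvolutionConfig(
                seed_size=60, survivors=15, generations=10,
                offspring_per_generation=30, elitism_count=3, rng_seed=seed)
            log = run_evolution(search_library, oracle, config)
            assert len(log.individuals) <= 0.30 * library_size
            rank = landscape.rank_of(log.best().key)
            assert rank < 0.01 * library_size

    def test_cache_bounds_oracle_calls(self, search_library, oracle, small_config):
        log = run_evolution(search_library, oracle, small_config)
        assert log.oracle_calls == len(log.individuals)
        assert log.cache_hits > 0

    def test_final_fitness_converges_across_seeds(self, search_library, oracle, planted):
        """Independent runs land within 10% of the brute-force optimum of
        each other, mirroring converging score trajectories."""
        landscape, _ = planted
        optimum = landscape.ranking["lid_root2"].iloc[0]
        finals = []
        for seed in (101, 202, 303, 404, 505):
            config = EvolutionConfig(
                seed_size=60, survivors=15, generations=20,
                offspring_per_generation=60, elitism_count=3, rng_seed=seed)
            finals.append(run_evolution(search_library, oracle, config).best().fitness)
        assert max(finals) - min(finals) <= 0.10 * abs(optimum)


class TestAggregateRuns:
    def test_best_fitness_kept_with_both_run_ids(self, search_library, oracle):
        base = EvolutionConfig(seed_size=20, survivors=8, generations=2,
                               offspring_per_generation=10, elitism_count=2)
        logs = []
        for seed in (1, 2):
            config = EvolutionConfig(**{**base.__dict__, "rng_seed": seed,
                                        "seeded_pool": None})
            logs.append(run_evolution(search_library, oracle, config,
                                      run_id=f"run-{seed}"))
        merged = aggregate_runs(logs)
        shared = set(logs[0].individuals) & set(logs[1].individuals)
        assert shared, "runs on a small library should overlap"
        for key in shared:
            row = merged[merged["molecule_key"] == key].iloc[0]
            expected = min(logs[0].individuals[key].fitness,
                           logs[1].individuals[key].fitness)
            assert row["best_fitness"] == expected
            assert set(row["runs"].split(";")) == {"run-1", "run-2"}

    def test_merged_size_equals_distinct_key_count(self, search_library, oracle):
        config = EvolutionConfig(seed_size=20, survivors=8, generations=2,
                                 offspring_per_generation=10, elitism_count=2,
                                 rng_seed=3)
        log = run_evolution(search_library, oracle, config)
        merged = aggregate_runs([log, log])
        assert len(merged) == len(log.individuals)

    def test_sorted_best_first_and_idempotent(self, search_library, oracle):
        config = EvolutionConfig(seed_size=20, survivors=8, generations=2,
                                 offspring_per_generation=10, elitism_count=2,
                                 rng_seed=4)
        merged = aggregate_runs([run_evolution(search_library, oracle, config)])
        fitness = merged["best_fitness"].to_list()
        assert fitness == sorted(fitness)
        resorted = merged.sort_values(["best_fitness", "molecule_key"],
                                      ignore_index=True)
        assert resorted.equals(merged)
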