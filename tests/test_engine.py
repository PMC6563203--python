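"""Mutation, replication, selection, and full-run behavior."""

import random

import numpy as np
import pytest

from mevolve import (
    Population,
    SimulationConfig,
    genetic_distance,
    mutate_population,
    replicate_population,
    run_to_target,
    select_population,
)

ALL_ONES = "111111111111"
ALL_ZEROS = "000000000000"


def random_population(rng, size=10, L=12):
    return Population(rng.integers(0, 2, size=(size, L)))


class TestMutation:
    def test_every_member_moves_exactly_one_locus(self):
        rng = np.random.default_rng(101)
        for _ in range(50):
            pop = random_population(rng)
            mutated = mutate_population(pop, rng)
            assert mutated.size == pop.size
            flips = (pop.array != mutated.array).sum(axis=1)
            assert (flips == 1).all()

    def test_same_seed_gives_identical_mutations(self):
        pop = Population.homogeneous(ALL_ONES, 10)
        a = mutate_population(pop, np.random.default_rng(7))
        b = mutate_population(pop, np.random.default_rng(7))
        assert a == b

    def test_all_ones_member_loses_exactly_one_positive_allele(self):
        pop = Population.homogeneous(ALL_ONES, 10)
        mutated = mutate_population(pop, np.random.default_rng(0))
        assert (mutated.fitness_indices() == 11).all()


class TestReplication:
    def test_expands_to_requested_size(self):
        pop = Population.homogeneous(ALL_ONES, 10)
        out = replicate_population(pop, np.random.default_rng(0), expanded_size=100)
        assert out.size == 100

    def test_homogeneous_input_yields_exact_copies(self):
        pop = Population.homogeneous("110", 5)
        out = replicate_population(pop, np.random.default_rng(1), expanded_size=40)
        assert (out.array == [1, 1, 0]).all()

    def test_zero_fitness_members_leave_no_offspring(self):
        pop = Population.from_genotypes([ALL_ONES] * 5 + [ALL_ZEROS] * 5)
        rng = np.random.default_rng(2)
        for _ in range(20):
            out = replicate_population(pop, rng, expanded_size=100)
            assert (out.fitness_indices() == 12).all()

    def test_offspring_shares_match_fitness_weights(self):
        """Empirical offspring fractions vs the multinomial expectation f / sum(f)."""
        members = ["111111111111", "111111000000", "110000000000", "111100000000"]
        pop = Population.from_genotypes(members)
        fitness = np.array([12, 6, 2, 4], dtype=float)
        expected = fitness / fitness.sum()
        rng = np.random.default_rng(3)
        trials, size = 100, 100
        counts = np.zeros(len(members))
        for _ in range(trials):
            out = replicate_population(pop, rng, expanded_size=size)
            for k, m in enumerate(members):
                counts[k] += (out.array == np.array([int(c) for c in m])).all(axis=1).sum()
        observed = counts / (trials * size)
        se = np.sqrt(expected * (1 - expected) / (trials * size))
        assert (np.abs(observed - expected) < 5 * se).all()

    def test_all_zero_population_falls_back_to_uniform(self):
        pop = Population.homogeneous(ALL_ZEROS, 10)
        out = replicate_population(pop, np.random.default_rng(4), expanded_size=100)
        assert out.size == 100
        assert (out.array == 0).all()


class TestSelection:
    def test_bottlenecks_to_requested_size(self):
        pop = Population.homogeneous(ALL_ONES, 100)
        out = select_population(pop, np.random.default_rng(0), selected_size=10)
        assert out.size == 10

    def test_homogeneous_input_survives_unchanged(self):
        pop = Population.homogeneous("0101", 100)
        out = select_population(pop, np.random.default_rng(1), selected_size=10)
        assert (out.array == [0, 1, 0, 1]).all()

    def test_every_survivor_existed_before_selection(self):
        rng = np.random.default_rng(2)
        pop = random_population(rng, size=100)
        out = select_population(pop, rng, selected_size=10)
        pre = {tuple(row) for row in pop.array}
        assert all(tuple(row) in pre for row in out.array)

    def test_fit_survivor_fraction_matches_pair_enumeration(self):
        """50 fit + 50 unfit members: P(tournament keeps a fit one) = 0.75.

        Oracle: enumerate the four equally likely pair types — the fit member
        wins unless both draws are unfit, so 1 - 0.5 * 0.5 = 0.75.
        """
        p_fit = 0.5
        expected = 1.0 - (1.0 - p_fit) ** 2
        pop = Population.from_genotypes([ALL_ONES] * 50 + [ALL_ZEROS] * 50)
        rng = np.random.default_rng(5)
        n_tournaments = 0
        n_fit = 0
        for _ in range(1000):
            out = select_population(pop, rng, selected_size=10)
            n_tournaments += 10
            n_fit += int((out.fitness_indices() == 12).sum())
        observed = n_fit / n_tournaments
        se = np.sqrt(expected * (1 - expected) / n_tournaments)
        assert abs(observed - expected) < 5 * se

    def test_stage_sizes_follow_the_10_100_10_cycle(self):
        config = SimulationConfig()
        rng = np.random.default_rng(6)
        pop = Population.homogeneous("000011111111", config.seed_population_size)
        for _ in range(5):
            pop = mutate_population(pop, rng)
            assert pop.size == config.seed_population_size
            pop = replicate_population(pop, rng, config.expanded_population_size)
            assert pop.size == config.expanded_population_size
            pop = select_population(pop, rng, config.seed_population_size)
            assert pop.size == config.seed_population_size


class TestRunToTarget:
    def test_seed_equal_to_target_reports_zero_cycles(self):
        result = run_to_target(ALL_ONES, ALL_ONES, SimulationConfig(rng_seed=0))
        assert result.cycles == 0
        assert result.terminated

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="lengths differ"):
            run_to_target("111", "1111", SimulationConfig(locus_count=3))
        with pytest.raises(ValueError, match="locus_count"):
            run_to_target("111", "111", SimulationConfig(locus_count=12))

    def test_unreachable_target_is_censored_not_an_error(self):
        # selection actively removes low-fitness strings, so the all-zeros
        # target is effectively unreachable within a small cap
        config = SimulationConfig(max_cycles=20, rng_seed=11)
        result = run_to_target(ALL_ONES, ALL_ZEROS, config)
        assert not result.terminated
        assert result.cycles == config.max_cycles

    def test_identical_config_reproduces_identical_result(self):
        config = SimulationConfig(rng_seed=42)
        a = run_to_target("000000111111", ALL_ONES, config, record_trajectory=True)
        b = run_to_target("000000111111", ALL_ONES, config, record_trajectory=True)
        assert a == b

    def test_trajectory_has_one_record_per_cycle(self):
        config = SimulationConfig(rng_seed=9)
        result = run_to_target("001111111111", ALL_ONES, config, record_trajectory=True)
        assert result.terminated
        assert len(result.trajectory) == result.cycles
        assert [p.cycle for p in result.trajectory] == list(range(1, result.cycles + 1))
        for point in result.trajectory:
            assert point.best_fitness >= point.mean_fitness
            assert 0 <= point.best_fitness <= 12

    def test_farther_seeds_need_more_cycles(self):
        """Mean cycles at genetic distance 6 exceed those at distance 2."""
        def mean_cycles(seed, base):
            cycles = []
            for r in range(150):
                cfg = SimulationConfig(rng_seed=base + r)
                cycles.append(run_to_target(seed, ALL_ONES, cfg).cycles)
            return np.mean(cycles)

        near = mean_cycles("001111111111", base=10_000)
        far = mean_cycles("000000111111", base=20_000)
        assert far > near
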