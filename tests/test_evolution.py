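"""Simulation loop: mutation, proliferation, full runs and splitting."""

import numpy as np
import pytest

from desim import (
    NKConfig,
    NKLandscape,
    SelectionFunction,
    SimulationConfig,
    find_global_optimum,
    initialize_population,
    mutate_population,
    proliferate,
    run_groups,
    run_simulation,
    run_split,
)
from desim._prng import stable_seed


def _config(**kwargs):
    defaults = dict(
        population_size=100,
        generations=20,
        mutations_per_cell=0.1,
        selection=SelectionFunction(0.0, 0.2),
        trajectory_seed=0,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestInitialisation:
    def test_nk_population_is_one_random_genome_cloned(self, small_nk, rng):
        pop = initialize_population(small_nk, 50, rng)
        assert pop.shape == (50, small_nk.n)
        assert (pop == pop[0]).all()

    def test_empirical_population_starts_at_wildtype(self, toy_landscape, rng):
        pop = initialize_population(toy_landscape, 30, rng)
        wt = toy_landscape.seq_to_coords(toy_landscape.wildtype)
        assert (pop == wt).all()

    def test_same_seed_same_founder(self, small_nk):
        a = initialize_population(small_nk, 5, np.random.default_rng(9))
        b = initialize_population(small_nk, 5, np.random.default_rng(9))
        assert np.array_equal(a, b)


class TestMutation:
    def test_zero_rate_is_identity(self, rng):
        pop = rng.integers(0, 2, (40, 10))
        assert np.array_equal(mutate_population(pop, 0.0, 2, rng), pop)

    def test_input_is_not_modified(self, rng):
        pop = rng.integers(0, 4, (40, 10))
        copy = pop.copy()
        mutate_population(pop, 2.0, 4, rng)
        assert np.array_equal(pop, copy)

    def test_change_counts_are_binomial(self, rng):
        """mu = N * p_I: per-genome change counts follow Binomial(N, mu/N)."""
        n, mu, p = 25, 0.1, 20_000
        pop = np.zeros((p, n), dtype=np.int64)
        out = mutate_population(pop, mu, 2, rng)
        changes = (out != pop).sum(axis=1)
        se = np.sqrt(mu * (1 - mu / n) / p)
        assert changes.mean() == pytest.approx(mu, abs=4 * se)
        # second moment: variance of Binomial(25, 0.004)
        var = n * (mu / n) * (1 - mu / n)
        assert changes.var() == pytest.approx(var, rel=0.15)

    def test_binary_mutation_always_flips(self, rng):
        pop = rng.integers(0, 2, (30, 8))
        out = mutate_population(pop, 8.0, 2, rng)  # p_site = 1: all sites
        assert (out == 1 - pop).all()

    def test_mutated_sites_take_uniform_alternatives(self, rng):
        pop = np.zeros((5000, 4), dtype=np.int64)
        out = mutate_population(pop, 4.0, 4, rng)  # p_site = 1
        counts = np.bincount(out.ravel(), minlength=4)
        assert counts[0] == 0  # never stays the same
        assert np.allclose(counts[1:] / out.size, 1 / 3, atol=0.02)

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            mutate_population(np.zeros((2, 4), dtype=int), 8.0, 2, rng)


class TestProliferation:
    def test_output_size_is_exact(self, rng):
        sel = rng.integers(0, 2, (7, 5))
        assert proliferate(sel, 123, rng).shape == (123, 5)

    def test_single_survivor_is_cloned(self, rng):
        sel = np.array([[1, 0, 1]])
        out = proliferate(sel, 50, rng)
        assert (out == sel[0]).all()

    def test_two_survivors_drawn_evenly(self, rng):
        sel = np.array([[0] * 4, [1] * 4])
        out = proliferate(sel, 10_000, rng)
        frac = (out[:, 0] == 1).mean()
        assert frac == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 10_000))

    def test_empty_input_rejected(self, rng):
        with pytest.raises(ValueError):
            proliferate(np.empty((0, 4), dtype=int), 10, rng)


class TestRunSimulation:
    def test_identical_seeds_identical_trajectories(self, small_nk):
        cfg = _config(trajectory_seed=42)
        a = run_simulation(cfg, small_nk)
        b = run_simulation(cfg, small_nk)
        assert np.array_equal(a.final_genomes, b.final_genomes)
        assert np.array_equal(a.max_fitness, b.max_fitness)

    def test_closed_dynamics_without_mutation_or_base_chance(self, small_nk):
        """No mutation and no base chance: no variation ever enters, so the
        final maximum equals the founder's fitness."""
        cfg = _config(mutations_per_cell=0.0, generations=30)
        traj = run_simulation(cfg, small_nk)
        assert traj.final_max_fitness == traj.max_fitness[0]
        assert (traj.final_genomes == traj.final_genomes[0]).all()

    def test_population_size_conserved_every_generation(self, small_nk):
        cfg = _config(population_size=37, generations=10)
        traj = run_simulation(cfg, small_nk, keep_populations=True)
        for pop in traj.populations:
            assert pop.shape == (37, small_nk.n)

    def test_additive_landscape_reaches_global_optimum(self, smooth_nk):
        """Greedy selection on a K=0 landscape climbs the single peak."""
        opt = find_global_optimum(smooth_nk)
        cfg = _config(
            population_size=200, generations=100, mutations_per_cell=0.1,
            trajectory_seed=1,
        )
        traj = run_simulation(cfg, smooth_nk, global_max=opt.fitness)
        assert traj.normalised_final == pytest.approx(1.0, abs=1e-9)

    def test_recording_honours_record_every(self, small_nk):
        cfg = _config(generations=10, record_every=4)
        traj = run_simulation(cfg, small_nk)
        assert traj.recorded_generations.tolist() == [0, 4, 8, 10]


class TestRunSplit:
    def test_single_subpopulation_equals_plain_run(self, small_nk):
        cfg = _config(trajectory_seed=5, n_subpopulations=1)
        split = run_split(cfg, small_nk)
        plain = run_simulation(cfg, small_nk)
        assert np.array_equal(
            split.trajectories[0].final_genomes, plain.final_genomes
        )

    def test_even_split_sizes(self):
        cfg = _config(population_size=500, n_subpopulations=5)
        assert cfg.subpopulation_sizes().tolist() == [100] * 5

    def test_remainder_spread_one_per_subpopulation(self):
        cfg = _config(population_size=7, n_subpopulations=3)
        assert cfg.subpopulation_sizes().tolist() == [3, 2, 2]

    def test_best_of_final_dominates_all_subpopulations(self, small_nk):
        cfg = _config(population_size=60, n_subpopulations=3, trajectory_seed=2)
        res = run_split(cfg, small_nk)
        assert len(res.trajectories) == 3
        for traj in res.trajectories:
            assert res.best_final_fitness >= traj.final_max_fitness

    def test_subpopulations_evolve_without_cross_talk(self, small_nk):
        """A sub-population's trajectory depends only on its own substream:
        the same sub-population index gives the identical trajectory
        regardless of how many siblings run alongside it."""
        two = run_split(
            _config(population_size=40, n_subpopulations=2, trajectory_seed=3),
            small_nk,
        )
        three = run_split(
            _config(population_size=60, n_subpopulations=3, trajectory_seed=3),
            small_nk,
        )
        assert np.array_equal(
            two.trajectories[0].final_genomes,
            three.trajectories[0].final_genomes,
        )

    def test_oversplit_rejected(self):
        with pytest.raises(ValueError):
            _config(population_size=3, n_subpopulations=5)


class TestMultiProperty:
    def test_unit_weights_reduce_to_single_objective(self, small_nk):
        other = NKLandscape(NKConfig(n=6, k=2, a=2, landscape_seed=77))
        cfg = _config(trajectory_seed=8, weights=(1.0, 0.0))
        multi = run_simulation(cfg, [small_nk, other])
        single = run_simulation(_config(trajectory_seed=8), small_nk)
        assert np.array_equal(multi.final_genomes, single.final_genomes)

    def test_double_round_mode_runs(self, small_nk):
        other = NKLandscape(NKConfig(n=6, k=2, a=2, landscape_seed=78))
        cfg = _config(trajectory_seed=9, selection_mode="double_round")
        traj = run_simulation(cfg, [small_nk, other])
        assert traj.final_genomes.shape == (100, 6)


class TestRunGroups:
    def test_deterministic_and_sizes_conserved(self, small_nk):
        sizes = np.array([10, 20, 5, 1])
        fn = SelectionFunction(0.1, 0.2)
        a = run_groups(small_nk, sizes, 15, fn, 0.2, np.random.default_rng(4))
        b = run_groups(small_nk, sizes, 15, fn, 0.2, np.random.default_rng(4))
        assert np.array_equal(a.final_genomes, b.final_genomes)
        assert np.bincount(a.group_ids).tolist() == sizes.tolist()

    def test_group_max_consistent_with_cells(self, small_nk):
        sizes = np.array([8, 12])
        res = run_groups(
            small_nk, sizes, 10, SelectionFunction(0.0, 0.2), 0.3,
            np.random.default_rng(1),
        )
        for g in range(2):
            cells = res.group_ids == g
            assert res.group_max_fitness[g] == res.final_fitness[cells].max()
            assert small_nk.fitness(res.group_best_genomes[g]) == pytest.approx(
                res.group_max_fitness[g]
            )

    def test_no_mutation_keeps_founder_genome(self, small_nk):
        founders = np.array([[0, 1, 0, 1, 0, 1], [1, 1, 1, 0, 0, 0]])
        res = run_groups(
            small_nk, np.array([6, 6]), 10, SelectionFunction(0.0, 0.2), 0.0,
            np.random.default_rng(2), founders=founders,
        )
        assert (res.final_genomes[:6] == founders[0]).all()
        assert (res.final_genomes[6:] == founders[1]).all()

    def test_statistics_agree_with_reference_loop(self, smooth_nk):
        """The batched engine and the reference loop sample the same
        process: their mean final maxima agree within sampling error."""
        reps = 30
        fn = SelectionFunction(0.0, 0.2)
        batched = run_groups(
            smooth_nk, np.full(reps, 50), 40, fn, 0.2,
            np.random.default_rng(10),
        ).group_max_fitness
        reference = np.array(
            [
                run_simulation(
                    _config(
                        population_size=50, generations=40,
                        mutations_per_cell=0.2, trajectory_seed=stable_seed(11, r),
                    ),
                    smooth_nk,
                ).final_max_fitness
                for r in range(reps)
            ]
        )
        pooled_se = np.sqrt(
            batched.var() / reps + reference.var() / reps
        )
        assert abs(batched.mean() - reference.mean()) < 4 * pooled_se


class TestErgodicity:
    def test_long_runs_visit_most_of_a_small_landscape(self):
        """With mutation and base chance every genome is reachable: a long
        run on a 64-genome landscape visits nearly all of it."""
        ls = NKLandscape(NKConfig(n=6, k=3, a=2, landscape_seed=21))
        cfg = _config(
            population_size=50, generations=400, mutations_per_cell=0.5,
            selection=SelectionFunction(0.15, 0.2), trajectory_seed=6,
            record_every=1,
        )
        traj = run_simulation(cfg, ls, keep_populations=True)
        weights = 2 ** np.arange(6)
        seen = {
            int(code)
            for pop in traj.populations
            for code in pop @ weights
        }
        assert len(seen) > 0.9 * 64
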