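"""Selection functions, percentiles and multi-property selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from desim import (
    ObjectiveWeights,
    SelectionFunction,
    combine_properties,
    double_round_select,
    fitness_percentiles,
    select_population,
    selection_probability,
    single_round_select,
    threshold_from_base_chance,
)


class TestThreshold:
    def test_zero_base_chance(self):
        assert threshold_from_base_chance(0.0, 0.2) == pytest.approx(0.8)

    def test_nonzero_base_chance(self):
        assert threshold_from_base_chance(0.1, 0.2) == pytest.approx(0.8 / 0.9)
        assert threshold_from_base_chance(0.19, 0.2) == pytest.approx(0.8 / 0.81)

    def test_select_everyone(self):
        assert threshold_from_base_chance(0.0, 1.0) == 0.0

    def test_base_chance_above_selected_fraction_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            threshold_from_base_chance(0.3, 0.2)

    @pytest.mark.parametrize("bad", [(-0.1, 0.2), (1.0, 0.2), (0.0, 0.0), (0.0, 1.5)])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            threshold_from_base_chance(*bad)

    @given(
        b=st.floats(0.0, 0.19),
        s=st.floats(0.2, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_expected_fraction_is_conserved(self, b, s):
        """The integral of the step function equals the selected fraction."""
        t = threshold_from_base_chance(b, s)
        assert 0.0 <= t <= 1.0
        assert (1 - t) * 1.0 + t * b == pytest.approx(s, abs=1e-12)


class TestPercentiles:
    def test_all_tied_cells_share_percentile_zero(self):
        assert np.array_equal(fitness_percentiles([2.0, 2.0, 2.0]), [0, 0, 0])

    def test_distinct_values_give_even_grid(self, rng):
        p = 11
        f = rng.permutation(p).astype(float)
        pct = fitness_percentiles(f)
        assert np.allclose(np.sort(pct), np.arange(p) / (p - 1))
        assert pct[np.argmax(f)] == 1.0

    def test_single_cell_is_top_percentile(self):
        assert fitness_percentiles([3.0])[0] == 1.0

    @given(st.lists(st.integers(0, 5), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_counting_definition(self, values):
        """percentile(i) = (# cells strictly below i) / (P - 1)."""
        f = np.array(values, dtype=float)
        pct = fitness_percentiles(f)
        for i in range(len(f)):
            assert pct[i] == pytest.approx(
                (f < f[i]).sum() / (len(f) - 1), abs=1e-12
            )


class TestSelectionProbability:
    def test_step_branches(self):
        fn = SelectionFunction(base_chance=0.05, selected_fraction=0.2)
        thr = fn.fitness_threshold
        assert selection_probability(thr + 0.05, fn) == 1.0
        assert selection_probability(thr, fn) == 1.0  # boundary inclusive
        assert selection_probability(thr - 0.05, fn) == 0.05

    def test_greedy_is_zero_below_threshold(self):
        fn = SelectionFunction(base_chance=0.0, selected_fraction=0.2)
        assert selection_probability(0.5, fn) == 0.0

    def test_probability_monotone_in_percentile(self):
        fn = SelectionFunction(base_chance=0.1, selected_fraction=0.3)
        probs = selection_probability(np.linspace(0, 1, 101), fn)
        assert (np.diff(probs) >= 0).all()


class TestSelectPopulation:
    def test_greedy_selects_exactly_the_top_tier(self, rng):
        fn = SelectionFunction(base_chance=0.0, selected_fraction=0.2)
        f = rng.permutation(50).astype(float)
        expected = set(np.argsort(f)[-int(np.ceil(0.2 * 50)):].tolist())
        for _ in range(5):
            assert set(select_population(f, fn, rng).tolist()) == expected

    def test_realised_fraction_matches_target(self, rng):
        """Monte-Carlo conservation of the 20% selected fraction at
        base chance 0.1 on distinct fitnesses."""
        fn = SelectionFunction(base_chance=0.1, selected_fraction=0.2)
        p, rounds = 10_000, 50
        fracs = [
            select_population(rng.permutation(p).astype(float), fn, rng).size / p
            for _ in range(rounds)
        ]
        se = np.sqrt(0.2 * 0.8 / p / rounds)
        assert np.mean(fracs) == pytest.approx(0.2, abs=4 * se)

    def test_population_of_one_is_always_selected(self, rng):
        fn = SelectionFunction(base_chance=0.0, selected_fraction=0.2)
        assert select_population(np.array([1.5]), fn, rng).tolist() == [0]

    def test_zero_survivors_fall_back_to_fittest(self, rng):
        """All-tied fitness under greedy selection keeps the single best."""
        fn = SelectionFunction(base_chance=0.0, selected_fraction=0.2)
        out = select_population(np.full(10, 3.0), fn, rng)
        assert out.size == 1

    def test_exact_fraction_mode_fills_quota(self, rng):
        fn = SelectionFunction(base_chance=0.1, selected_fraction=0.2)
        f = rng.permutation(100).astype(float)
        out = select_population(f, fn, rng, exact_fraction=True)
        assert out.size == 20
        assert set(out.tolist()) == set(np.argsort(f)[-20:].tolist())

    def test_noise_does_not_modify_input(self, rng):
        fn = SelectionFunction(base_chance=0.0, selected_fraction=0.2,
                               noise_sigma=2.0)
        f = rng.normal(size=100)
        f_copy = f.copy()
        select_population(f, fn, rng)
        assert np.array_equal(f, f_copy)


class TestCombineProperties:
    def test_unit_weight_recovers_single_objective(self):
        f = np.array([1.0, 2.0, 3.0])
        assert combine_properties(f, (1, 0, 0)) == 1.0

    def test_equal_and_skewed_weights(self):
        f = np.array([1.0, 2.0, 3.0])
        assert combine_properties(f, (1, 1, 1)) == 6.0
        assert combine_properties(f, (3, 1, 1)) == 8.0

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_linearity_in_weights(self, alpha):
        f = np.array([0.5, -1.0, 2.0])
        w = np.array([1.0, 2.0, 0.5])
        assert combine_properties(f, alpha * w) == pytest.approx(
            alpha * combine_properties(f, w)
        )

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            ObjectiveWeights((0.0, 0.0))
        with pytest.raises(ValueError):
            ObjectiveWeights((-1.0, 2.0))
        with pytest.raises(ValueError):
            combine_properties(np.ones((3, 5)), (1, 1))


class TestMultiRoundSelection:
    def test_single_property_double_round_is_plain_cut(self, rng):
        f = rng.permutation(40).astype(float)[None, :]
        out = double_round_select(f, selected_fraction=0.2)
        assert set(out.tolist()) == set(np.argsort(f[0])[-8:].tolist())

    def test_correlated_properties_collapse_to_one_ranking(self, rng):
        """With perfectly correlated properties the sequential cuts keep a
        top slice of the single shared ranking."""
        f1 = rng.permutation(100).astype(float)
        out = double_round_select(np.stack([f1, f1]), selected_fraction=0.2)
        k = out.size
        assert set(out.tolist()) == set(np.argsort(f1)[-k:].tolist())

    def test_single_round_beats_double_round_on_independent_properties(
        self, rng
    ):
        """Sequential per-property cuts discard cells that are poor in one
        property but excellent overall, so the survivors' mean combined
        fitness is lower than under one cut on the combination."""
        fn = SelectionFunction(base_chance=0.0, selected_fraction=0.05)
        diffs = []
        for _ in range(20):
            props = rng.normal(size=(2, 10_000))
            combined = props.sum(axis=0)
            single = single_round_select(props, (1.0, 1.0), fn, rng)
            double = double_round_select(props, selected_fraction=0.05)
            diffs.append(combined[single].mean() - combined[double].mean())
        assert np.mean(diffs) > 0
        assert np.mean(np.array(diffs) > 0) >= 0.9

    def test_double_round_expected_yield_under_independence(self, rng):
        props = rng.normal(size=(2, 20_000))
        out = double_round_select(props, selected_fraction=0.2)
        assert out.size / 20_000 == pytest.approx(0.2, abs=0.02)
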