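"""Cluster distributions, the interaction model, and classical mixing rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compactmix import (
    CompactibilityProfile,
    Composition,
    cluster_distribution,
    interaction_predict,
    linear_rule,
    mixture_true_density,
    power_law,
    predict_mixture_profile,
    rd_combination_predict,
    volume_fractions,
)
from compactmix.exceptions import CompositionError, ConfigurationError

from conftest import enumerate_sequences_predict, power_mean_predict


def comp(*fracs, ids=None):
    ids = ids or [chr(ord("A") + i) for i in range(len(fracs))]
    return Composition(components=tuple(zip(ids, fracs)))


# strategies for random mixture inputs
volume_pairs = st.floats(0.01, 0.99).map(lambda v: (v, 1.0 - v))
strength_pairs = st.tuples(st.floats(0.1, 20.0), st.floats(0.1, 20.0)).filter(
    lambda s: abs(s[0] - s[1]) > 1e-6
)


class TestComposition:
    def test_normalized_on_construction(self):
        c = comp(0.5000000001, 0.4999999999)
        assert c.volume_fractions.sum() == pytest.approx(1.0, abs=1e-15)

    def test_off_by_more_than_tolerance_rejected(self):
        with pytest.raises(CompositionError):
            comp(0.6, 0.5)

    def test_negative_fraction_rejected(self):
        with pytest.raises(CompositionError):
            comp(1.2, -0.2)


class TestVolumeFractions:
    def test_equal_weights_equal_densities_symmetric(self):
        c = volume_fractions([0.5, 0.5], [1.4, 1.4])
        assert c.volume_fractions == pytest.approx([0.5, 0.5])

    def test_hand_computed_value(self):
        c = volume_fractions([0.5, 0.5], [1.0, 2.0])
        assert c.volume_fractions == pytest.approx([2 / 3, 1 / 3])

    def test_single_component(self):
        c = volume_fractions([1.0], [1.6])
        assert c.volume_fractions == pytest.approx([1.0])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(CompositionError):
            volume_fractions([0.5, 0.5], [1.0])

    def test_nonpositive_density_rejected(self):
        with pytest.raises(CompositionError):
            volume_fractions([0.5, 0.5], [1.0, 0.0])


class TestMixtureTrueDensity:
    def test_equal_densities_identity(self):
        assert mixture_true_density([0.3, 0.7], [1.5, 1.5]) == pytest.approx(1.5)

    def test_hand_computed_harmonic_mean(self):
        assert mixture_true_density([0.5, 0.5], [1.0, 2.0]) == pytest.approx(4 / 3)

    @settings(max_examples=50, deadline=None)
    @given(w=st.floats(0.01, 0.99), rho1=st.floats(0.5, 3.0), rho2=st.floats(0.5, 3.0))
    def test_bounded_by_component_densities(self, w, rho1, rho2):
        rho = mixture_true_density([w, 1 - w], [rho1, rho2])
        assert min(rho1, rho2) - 1e-12 <= rho <= max(rho1, rho2) + 1e-12


class TestClusterDistribution:
    def test_pairwise_cohesive_fraction_is_half(self, binary_50_50):
        d = cluster_distribution(2, binary_50_50, [10.0, 1.0])
        assert d.cohesive_fraction() == pytest.approx(0.5, abs=1e-12)

    def test_sixth_order_cohesive_fraction_is_three_percent(self, binary_50_50):
        d = cluster_distribution(6, binary_50_50, [10.0, 1.0])
        assert d.cohesive_fraction() == pytest.approx(2 * 0.5**6, abs=1e-12)
        assert round(100 * d.cohesive_fraction()) == 3

    def test_fourth_order_binary_has_binomial_coefficients(self, binary_50_50):
        d = cluster_distribution(4, binary_50_50, [10.0, 1.0])
        assert len(d.entries) == 5
        coeffs = sorted(p / (0.5**4) for _, p, _ in d.entries)
        assert coeffs == pytest.approx([1, 1, 4, 4, 6])

    def test_entry_count_is_stars_and_bars(self):
        c = comp(0.2, 0.3, 0.5)
        d = cluster_distribution(5, c, [1.0, 2.0, 3.0])
        assert len(d.entries) == math.comb(5 + 2, 2)

    @settings(max_examples=40, deadline=None)
    @given(
        n=st.integers(1, 50),
        raw=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=4),
    )
    def test_probabilities_sum_to_one(self, n, raw):
        total = sum(raw)
        c = comp(*[r / total for r in raw])
        d = cluster_distribution(n, c, [1.0] * len(raw))
        assert sum(p for _, p, _ in d.entries) == pytest.approx(1.0, abs=1e-12)

    def test_zero_strength_component_gives_zero_cluster_strength(self, binary_50_50):
        d = cluster_distribution(3, binary_50_50, [10.0, 0.0])
        for ct, _, s in d.entries:
            if ct.counts[1] > 0:
                assert s == 0.0
            else:
                assert s == pytest.approx(10.0)

    def test_invalid_order_rejected(self, binary_50_50):
        with pytest.raises(CompositionError):
            cluster_distribution(0, binary_50_50, [1.0, 1.0])


class TestInteractionPredict:
    def test_fourth_order_reference_value(self, binary_50_50):
        assert interaction_predict(4, binary_50_50, [10.0, 1.0]) == pytest.approx(
            3.7238, abs=1e-4
        )

    def test_pure_component_recovers_its_strength(self):
        c = comp(1.0, 0.0)
        for n in (2, 4, 7):
            assert interaction_predict(n, c, [6.5, 1.0]) == pytest.approx(6.5)

    def test_equal_strengths_recovered_exactly(self, binary_50_50):
        assert interaction_predict(5, binary_50_50, [3.3, 3.3]) == pytest.approx(3.3)

    @settings(max_examples=30, deadline=None)
    @given(
        n=st.integers(1, 8),
        v=st.lists(st.floats(0.05, 1.0), min_size=2, max_size=3),
        s=st.lists(st.floats(0.1, 20.0), min_size=3, max_size=3),
    )
    def test_matches_ordered_sequence_enumeration(self, n, v, s):
        """Closed form equals brute force over all m^n ordered sequences."""
        total = sum(v)
        fracs = [x / total for x in v]
        strengths = s[: len(fracs)]
        c = comp(*fracs)
        expected = enumerate_sequences_predict(n, fracs, strengths)
        got = interaction_predict(n, c, strengths)
        assert got == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(n=st.integers(2, 30), v=volume_pairs, s=strength_pairs)
    def test_power_mean_identity(self, n, v, s):
        """The order-n prediction is the power mean of order 1/n."""
        c = comp(*v)
        assert interaction_predict(n, c, list(s)) == pytest.approx(
            power_mean_predict(n, v, s), rel=1e-10
        )

    @settings(max_examples=50, deadline=None)
    @given(n=st.integers(1, 20), v=volume_pairs, s=strength_pairs)
    def test_bounded_by_component_strengths(self, n, v, s):
        c = comp(*v)
        pred = interaction_predict(n, c, list(s))
        assert min(s) - 1e-12 <= pred <= max(s) + 1e-12

    @settings(max_examples=40, deadline=None)
    @given(v=volume_pairs, s=strength_pairs)
    def test_strictly_decreasing_in_order(self, v, s):
        """Higher cluster order shifts weight to adhesive contacts: the
        prediction falls monotonically from pairwise toward the power law."""
        c = comp(*v)
        preds = [interaction_predict(n, c, list(s)) for n in range(2, 11)]
        assert all(a > b for a, b in zip(preds, preds[1:]))

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(2, 12), v=volume_pairs, s=strength_pairs)
    def test_sandwiched_between_power_law_and_linear_rule(self, n, v, s):
        c = comp(*v)
        pred = interaction_predict(n, c, list(s))
        assert power_law(c, list(s)) - 1e-12 <= pred <= linear_rule(c, list(s)) + 1e-12

    @settings(max_examples=30, deadline=None)
    @given(v=volume_pairs, s=st.tuples(st.floats(1.0, 3.0), st.floats(1.0, 3.0)))
    def test_large_order_asymptote_is_power_law(self, v, s):
        """n=200 sits within 0.1% of the all-adhesive geometric-mean limit.

        The convergence constant grows with (log strength ratio)^2, so this
        asymptote is checked on moderate ratios (<= 3).
        """
        c = comp(*v)
        pl = power_law(c, list(s))
        assert abs(interaction_predict(200, c, list(s)) - pl) / pl < 1e-3

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(1, 10), v=volume_pairs, s=strength_pairs)
    def test_ternary_with_vanishing_component_reduces_to_binary(self, n, v, s):
        binary = interaction_predict(n, comp(*v), list(s))
        ternary = interaction_predict(
            n, comp(v[0], v[1], 0.0), [s[0], s[1], 123.0]
        )
        assert ternary == pytest.approx(binary, rel=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(1, 10), v=volume_pairs, s=strength_pairs)
    def test_permutation_symmetry(self, n, v, s):
        a = interaction_predict(n, comp(*v), list(s))
        b = interaction_predict(n, comp(v[1], v[0], ids=["B", "A"]), [s[1], s[0]])
        assert a == pytest.approx(b, rel=1e-12)


class TestClassicalRules:
    def test_linear_rule_arithmetic_mean(self, binary_50_50):
        assert linear_rule(binary_50_50, [10.0, 1.0]) == pytest.approx(5.5)

    def test_power_law_geometric_mean(self, binary_50_50):
        assert power_law(binary_50_50, [10.0, 1.0]) == pytest.approx(math.sqrt(10))

    def test_power_law_zero_strength_component(self, binary_50_50):
        assert power_law(binary_50_50, [10.0, 0.0]) == 0.0
        # absent component with zero strength must not zero the mixture
        assert power_law(comp(1.0, 0.0), [10.0, 0.0]) == pytest.approx(10.0)

    @settings(max_examples=50, deadline=None)
    @given(v=volume_pairs, s=strength_pairs)
    def test_linear_dominates_power_law(self, v, s):
        c = comp(*v)
        assert linear_rule(c, list(s)) > power_law(c, list(s))

    @settings(max_examples=50, deadline=None)
    @given(v=volume_pairs, s=strength_pairs)
    def test_pairwise_with_arithmetic_adhesive_equals_linear_rule(self, v, s):
        """V_A^2 s_A + V_B^2 s_B + 2 V_A V_B (s_A+s_B)/2 == V_A s_A + V_B s_B."""
        va, vb = v
        sa, sb = s
        second_order_arithmetic = (
            va**2 * sa + vb**2 * sb + 2 * va * vb * 0.5 * (sa + sb)
        )
        assert second_order_arithmetic == pytest.approx(
            linear_rule(comp(*v), list(s)), rel=1e-14
        )


class TestRDCombination:
    profiles = [
        CompactibilityProfile(material_id="A", sigma0=10.0, k=8.0),
        CompactibilityProfile(material_id="B", sigma0=2.0, k=5.0),
    ]

    def test_pp_hand_computed(self, binary_50_50):
        got = rd_combination_predict(self.profiles, binary_50_50, "PP", 0.2)
        expected = math.sqrt(20) * math.exp(-0.2 * math.sqrt(40))
        assert got == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("variant", ["LL", "LP", "PL", "PP"])
    def test_identical_components_reduce_to_pure_profile(self, variant, binary_50_50):
        twins = [
            CompactibilityProfile(material_id="A", sigma0=7.0, k=6.0),
            CompactibilityProfile(material_id="B", sigma0=7.0, k=6.0),
        ]
        got = rd_combination_predict(twins, binary_50_50, variant, 0.15)
        assert got == pytest.approx(7.0 * math.exp(-6.0 * 0.15), rel=1e-12)

    def test_ll_with_equal_k_equals_pointwise_linear_rule(self, binary_50_50):
        profs = [
            CompactibilityProfile(material_id="A", sigma0=10.0, k=6.0),
            CompactibilityProfile(material_id="B", sigma0=2.0, k=6.0),
        ]
        eps = 0.18
        got = rd_combination_predict(profs, binary_50_50, "LL", eps)
        sigma = [p.sigma0 * math.exp(-6.0 * eps) for p in profs]
        assert got == pytest.approx(linear_rule(binary_50_50, sigma), rel=1e-12)

    def test_unknown_variant_rejected(self, binary_50_50):
        with pytest.raises(ConfigurationError):
            rd_combination_predict(self.profiles, binary_50_50, "XY", 0.1)


class TestPredictMixtureProfile:
    def test_porosity_matching_with_equal_strength_crossing(self):
        """Where the two pure R-D curves cross, every model returns the
        common value — the porosity-matching contract."""
        profiles = [
            CompactibilityProfile(material_id="A", sigma0=10.0, k=8.0),
            CompactibilityProfile(material_id="B", sigma0=5.0, k=8.0 - math.log(2) / 0.2),
        ]
        # curves cross at eps = 0.2 by construction
        eps_cross = 0.2
        common = 10.0 * math.exp(-8.0 * eps_cross)
        c = Composition(components=(("A", 0.5), ("B", 0.5)))
        for model in ("interaction-4", "linear", "power"):
            pred = predict_mixture_profile(profiles, c, model, [eps_cross])
            assert pred.strengths[0] == pytest.approx(common, rel=1e-10)

    def test_rank_order_at_single_porosity(self, strong_weak_profiles):
        c = Composition(components=(("strong", 0.5), ("weak", 0.5)))
        grid = [0.15]

        def at(model, order=None):
            return predict_mixture_profile(
                strong_weak_profiles, c, model, grid, order=order
            ).strengths[0]

        lin = at("linear")
        o2 = at("interaction", 2)
        o4 = at("interaction", 4)
        pl = at("power")
        assert lin > o2 > o4 > pl

    def test_output_length_matches_grid(self, strong_weak_profiles):
        c = Composition(components=(("strong", 0.3), ("weak", 0.7)))
        grid = np.linspace(0.1, 0.3, 7)
        pred = predict_mixture_profile(strong_weak_profiles, c, "interaction-4", grid)
        assert len(pred.strengths) == 7
        assert pred.model_id == "interaction-4"

    def test_missing_profile_raises_configuration_error(self, strong_weak_profiles):
        c = Composition(components=(("strong", 0.5), ("unknown", 0.5)))
        with pytest.raises(ConfigurationError, match="unknown"):
            predict_mixture_profile(strong_weak_profiles, c, "linear", [0.15])
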