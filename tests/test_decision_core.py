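"""Individual choice probabilities: worked examples, the Bayes oracle, and
the invariants every two-option variant must satisfy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shoalbayes import (
    InfiniteReliabilityError,
    InvalidInputError,
    InvalidParameterError,
    SchemaError,
    choice_prob_asymmetric,
    choice_prob_asymmetric_full,
    choice_prob_fish_replica,
    choice_prob_multi,
    choice_prob_two_replicas,
    follow_prob_symmetric,
    posterior_best,
    reliability_from_rates,
)
from shoalbayes.decision_core import DecisionModel, ReliabilitySet, SocialState


def bayes_posterior_oracle(p_correct, p_incorrect, n_x, n_y, n_u=0, prior_x=0.5):
    """Explicit Bayes computation from behaviour-probability tables.

    Independent of the package's log-odds path: forms the full likelihoods
    P(observed behaviours | hypothesis) as products of per-individual
    behaviour probabilities and applies Bayes' rule directly.
    """
    p_u = 1.0 - p_correct - p_incorrect
    like_x = p_correct ** n_x * p_incorrect ** n_y * p_u ** n_u
    like_y = p_incorrect ** n_x * p_correct ** n_y * p_u ** n_u
    return like_x * prior_x / (like_x * prior_x + like_y * (1 - prior_x))


class TestWorkedExamples:
    def test_no_information_is_even_odds(self):
        assert posterior_best(1.0, {"go-x": 2.5, "go-y": 0.4},
                              {"go-x": 0, "go-y": 0}) == 0.5

    def test_single_conspecific_at_x(self):
        p = posterior_best(1.0, {"go-x": 2.5, "go-y": 1 / 2.5},
                           {"go-x": 1, "go-y": 0})
        assert p == pytest.approx(1 / (1 + 1 / 2.5), abs=1e-12)

    def test_nonsocial_evidence_alone(self):
        assert posterior_best(4.0, {"go-x": 2.5}, {"go-x": 0}) == \
            pytest.approx(0.8, abs=1e-12)

    @pytest.mark.parametrize("s, dn, expected", [
        (7.3, 0, 0.5),
        (1.0, 5, 0.5),
        (1.0, -3, 0.5),
        (2.5, -2, 1 / (1 + 2.5 ** 2)),
        (2.5, 2, 2.5 ** 2 / (1 + 2.5 ** 2)),
    ])
    def test_symmetric_sigmoid(self, s, dn, expected):
        assert follow_prob_symmetric(s, dn) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("s, rho, dn, expected", [
        (2.5, 1.0, 0, 0.5),
        (2.5, 0.35, 0, 1 / 1.35),  # first fitted attractiveness ratio
        (2.5, 0.5, -1, 1 / (1 + 0.5 * 2.5)),
    ])
    def test_two_replica_rule(self, s, rho, dn, expected):
        assert choice_prob_two_replicas(s, rho, dn) == \
            pytest.approx(expected, abs=1e-12)

    def test_two_replica_mirrored_side(self):
        p_x_side = choice_prob_two_replicas(2.5, 0.35, 2, "x")
        p_y_side = choice_prob_two_replicas(2.5, 0.35, -2, "y")
        assert p_x_side + p_y_side == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("a, s, dn, expected", [
        (3.0, 2.5, 0, 0.75),
        (0.2, 2.5, 2, 1 / (1 + 5 * 2.5 ** -2)),
    ])
    def test_asymmetric_rule(self, a, s, dn, expected):
        assert choice_prob_asymmetric(a, s, dn) == pytest.approx(expected, abs=1e-12)

    def test_asymmetric_full_balanced_with_undecided(self):
        assert choice_prob_asymmetric_full(1, 2.5, 2.5, 1, 1, 1, 3) == \
            pytest.approx(0.5, abs=1e-12)

    def test_asymmetric_full_unequal_side_reliabilities(self):
        assert choice_prob_asymmetric_full(1, 4, 2, 1, 1, 1, 0) == \
            pytest.approx(1 / (1 + 2 / 4), abs=1e-12)

    def test_fish_replica_uninformative_replicas(self):
        assert choice_prob_fish_replica(1, 2.5, 1, 0, 3) == \
            pytest.approx(0.5, abs=1e-12)

    def test_fish_replica_mixed_counts(self):
        assert choice_prob_fish_replica(1, 2, 3, 1, -1) == \
            pytest.approx(0.4, abs=1e-12)

    def test_multi_option_uniform(self):
        np.testing.assert_allclose(
            choice_prob_multi(2.5, [0, 0, 0]), [1 / 3] * 3, atol=1e-12)

    def test_multi_option_reduces_to_sigmoid(self):
        p = choice_prob_multi(2.5, [2, 0])
        assert p[0] == pytest.approx(follow_prob_symmetric(2.5, 2), abs=1e-12)

    def test_multi_option_three_way(self):
        np.testing.assert_allclose(
            choice_prob_multi(2.5, [1, 0, 0]),
            [2.5 / 4.5, 1 / 4.5, 1 / 4.5], atol=1e-12)

    @pytest.mark.parametrize("pc, pi, expected", [
        (0.5, 0.5, 1.0), (0.625, 0.25, 2.5), (0.8, 0.2, 4.0)])
    def test_reliability_from_rates(self, pc, pi, expected):
        assert reliability_from_rates(pc, pi) == pytest.approx(expected, abs=1e-12)


class TestOracle:
    def test_symmetric_sigmoid_matches_explicit_bayes(self, rng):
        """100 random reliability/count draws agree with the brute-force
        Bayes computation from behaviour-probability tables to 1e-12."""
        for _ in range(100):
            p_inc = rng.uniform(0.01, 0.3)
            p_cor = rng.uniform(p_inc, min(1 - p_inc - 0.01, 0.69))
            n_x, n_y, n_u = rng.integers(0, 8, size=3)
            s = p_cor / p_inc
            expected = bayes_posterior_oracle(p_cor, p_inc, n_x, n_y, n_u)
            assert follow_prob_symmetric(s, int(n_x - n_y)) == \
                pytest.approx(expected, abs=1e-12)

    def test_posterior_best_matches_explicit_bayes_with_undecided(self, rng):
        for _ in range(50):
            p_inc = rng.uniform(0.05, 0.3)
            p_cor = rng.uniform(p_inc, 0.6)
            n_x, n_y, n_u = (int(v) for v in rng.integers(0, 5, size=3))
            s = p_cor / p_inc
            rel = {"go-x": s, "go-y": 1 / s, "undecided": 1.0}
            got = posterior_best(1.0, rel,
                                 {"go-x": n_x, "go-y": n_y, "undecided": n_u})
            assert got == pytest.approx(
                bayes_posterior_oracle(p_cor, p_inc, n_x, n_y, n_u), abs=1e-12)


@st.composite
def s_and_dn(draw):
    s = draw(st.floats(0.05, 50.0))
    dn = draw(st.integers(-40, 40))
    return s, dn


class TestInvariants:
    @settings(max_examples=200, derandomize=True)
    @given(s_and_dn())
    def test_point_symmetry(self, sdn):
        s, dn = sdn
        assert follow_prob_symmetric(s, dn) + follow_prob_symmetric(s, -dn) == \
            pytest.approx(1.0, abs=1e-12)

    # strictness is checked away from double-precision saturation (|logit| < 20)
    @settings(max_examples=100, derandomize=True)
    @given(st.floats(1.0 + 1e-6, 10.0), st.integers(-8, 7))
    def test_monotone_in_delta_n_when_informative(self, s, dn):
        assert follow_prob_symmetric(s, dn + 1) > follow_prob_symmetric(s, dn)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0.15, 1.0 - 1e-6), st.integers(-8, 7))
    def test_antitone_when_reliability_below_one(self, s, dn):
        assert follow_prob_symmetric(s, dn + 1) < follow_prob_symmetric(s, dn)

    def test_large_counts_stay_finite_and_ordered(self):
        # log-odds form must survive counts that would overflow s**dn
        p = follow_prob_symmetric(2.5, 2000)
        q = follow_prob_symmetric(2.5, -2000)
        assert p == 1.0 and q == 0.0  # saturated, not NaN

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0.1, 10), st.floats(0.1, 10), st.integers(-10, 10))
    def test_asymmetric_complementarity(self, a, s, dn):
        p_x = choice_prob_asymmetric(a, s, dn)
        p_y = choice_prob_asymmetric(1 / a, s, -dn)
        assert p_x + p_y == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0.2, 5), st.integers(-6, 6), st.integers(-6, 6))
    def test_fish_replica_reduces_to_pooled(self, s, dnf, dnr):
        pooled = choice_prob_asymmetric(1.0, s, dnf + dnr)
        assert choice_prob_fish_replica(1.0, s, s, dnf, dnr) == \
            pytest.approx(pooled, abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.2, 5), st.integers(-8, 8))
    def test_two_replica_reduces_at_unit_ratio(self, s, dn):
        assert choice_prob_two_replicas(s, 1.0, dn) == \
            pytest.approx(follow_prob_symmetric(s, dn), abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.2, 5), st.integers(0, 6), st.integers(0, 6))
    def test_full_asymmetric_reduces_with_unit_extras(self, s, n_x, n_y):
        assert choice_prob_asymmetric_full(1.0, s, s, 1.0, n_x, n_y, 3) == \
            pytest.approx(choice_prob_asymmetric(1.0, s, n_x - n_y), abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.2, 5), st.lists(st.integers(0, 10), min_size=2, max_size=6))
    def test_multi_option_normalizes(self, s, counts):
        assert choice_prob_multi(s, counts).sum() == pytest.approx(1.0, abs=1e-12)


class TestValidation:
    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_nonpositive_reliability_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            follow_prob_symmetric(bad, 1)

    def test_unknown_behavior_label_is_schema_error(self):
        with pytest.raises(SchemaError):
            posterior_best(1.0, {"go-x": 2.5}, {"swim-in-circles": 1})

    def test_zero_error_rate_reports_infinite_reliability(self):
        with pytest.raises(InfiniteReliabilityError):
            reliability_from_rates(0.8, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            choice_prob_multi(2.5, [1, -1])

    def test_reliability_set_enforces_reciprocal_pairs(self):
        with pytest.raises(InvalidParameterError):
            ReliabilitySet({"go-x": 2.5, "go-y": 0.5}, mirror={"go-x": "go-y"})
        ReliabilitySet({"go-x": 2.5, "go-y": 0.4}, mirror={"go-x": "go-y"})

    def test_social_state_respects_group_size(self):
        with pytest.raises(InvalidInputError):
            SocialState({"go-x": 5, "go-y": 4}, group_size=8)

    def test_model_requires_variant_parameters(self):
        with pytest.raises(InvalidParameterError):
            DecisionModel("two-replica", {"s": 2.5})
        with pytest.raises(InvalidParameterError):
            DecisionModel("quorum", {"s": 2.5})
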