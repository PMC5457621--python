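"""Closed-form calculus: agreement map, d-interpolation, amplitudes, fixed points."""

import itertools
import math

import pytest
from hypothesis import given, strategies as st

from placebosim import (
    AmplitudePair,
    agreement_prob,
    agreement_prob_d,
    assessment_prediction,
    classical_path_probs,
    coherent_path_probs,
    fixed_points,
    joint_outcome_table,
    total_prob_unstructured,
)

GRID = [i / 100 for i in range(1, 100)]  # 99 interior probabilities


def agreement_enum(p: float, n: int) -> float:
    """Brute-force oracle: enumerate all 2^n observer-outcome configurations,
    keep the all-agree ones, renormalize the all-direct weight."""
    num = den = 0.0
    for cfg in itertools.product((0, 1), repeat=n):
        w = 1.0
        for o in cfg:
            w *= p if o == 0 else 1.0 - p
        if all(o == 0 for o in cfg):
            num += w
            den += w
        elif all(o == 1 for o in cfg):
            den += w
    return num / den


class TestAgreementProb:
    @pytest.mark.parametrize("p", [0.1, 0.25, 0.5, 0.9])
    def test_no_observers_pins_half(self, p):
        assert agreement_prob(p, 0) == 0.5

    @pytest.mark.parametrize(
        "p, n, expected",
        [
            (0.5, 2, 0.5),  # symmetry fixed point
            (2 / 3, 2, 0.8),  # frozen from the enumeration oracle
            (0.0, 3, 0.0),  # absorbing boundary, continuity limit
            (1.0, 3, 1.0),
        ],
    )
    def test_examples(self, p, n, expected):
        assert agreement_prob(p, n) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        for n in range(1, 7):
            for p in GRID:
                assert abs(agreement_prob(p, n) - agreement_enum(p, n)) < 1e-12

    @pytest.mark.parametrize("n", [1, 2, 4])
    def test_strictly_increasing(self, n):
        vals = [agreement_prob(p, n) for p in GRID]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("bad", [-0.1, 1.1, 2.0])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            agreement_prob(bad, 2)

    def test_negative_observers_rejected(self):
        with pytest.raises(ValueError):
            agreement_prob(0.5, -1)


class TestIndependenceParameter:
    @pytest.mark.parametrize(
        "p, d, expected",
        [
            (0.3, 0.21, 0.3),  # d = pq recovers classical probability p
            (0.5, 0.1, 0.5),  # p = q: numerator is half the denominator
            (2 / 3, 0.0, 0.8),  # d = 0 recovers the two-observer agreement map
        ],
    )
    def test_examples(self, p, d, expected):
        assert agreement_prob_d(p, d) == pytest.approx(expected, abs=1e-12)

    def test_interpolation_endpoints_on_grid(self):
        for p in GRID:
            pq = p * (1.0 - p)
            assert abs(agreement_prob_d(p, 0.0) - agreement_prob(p, 2)) < 1e-12
            assert abs(agreement_prob_d(p, pq) - p) < 1e-12

    def test_d_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            agreement_prob_d(0.3, 0.22)  # pq = 0.21
        with pytest.raises(ValueError):
            agreement_prob_d(0.3, -0.01)

    def test_joint_table_examples(self):
        t = joint_outcome_table(0.5, 0.0)
        assert all(v == pytest.approx(0.25) for v in t.values())
        t = joint_outcome_table(0.5, 0.25)  # d = pq: perfectly correlated
        assert t[("direct", "direct")] == pytest.approx(0.5)
        assert t[("direct", "reverse")] == pytest.approx(0.0)

    def test_joint_table_is_oracle_for_d_interpolation(self):
        # renormalizing the agreement diagonal must reproduce agreement_prob_d
        for p in GRID[::7]:
            pq = p * (1.0 - p)
            for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
                d = frac * pq
                t = joint_outcome_table(p, d)
                assert sum(t.values()) == pytest.approx(1.0, abs=1e-12)
                diag = t[("direct", "direct")] + t[("reverse", "reverse")]
                renorm = t[("direct", "direct")] / diag
                assert abs(renorm - agreement_prob_d(p, d)) < 1e-12


class TestPathAmplitudes:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (1 / math.sqrt(2), 1 / math.sqrt(2), (1.0, 0.0)),
            (1.0, 0.0, (1.0, 0.0)),
            (0.6, 0.8, (1.0, 0.0)),  # (0.36 + 0.64)^2, cross term cancels
        ],
    )
    def test_coherent(self, a, b, expected):
        direct, reverse = coherent_path_probs(AmplitudePair(a, b))
        assert direct == pytest.approx(expected[0], abs=1e-12)
        assert reverse == pytest.approx(expected[1], abs=1e-12)

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (1 / math.sqrt(2), 1 / math.sqrt(2), (0.5, 0.5)),
            (1.0, 0.0, (1.0, 0.0)),
            (0.6, 0.8, (0.5392, 0.4608)),  # 0.36^2 + 0.64^2 and 2*0.36*0.64
        ],
    )
    def test_classical(self, a, b, expected):
        direct, reverse = classical_path_probs(AmplitudePair(a, b))
        assert direct == pytest.approx(expected[0], abs=1e-12)
        assert reverse == pytest.approx(expected[1], abs=1e-12)

    @given(st.floats(0.0, math.pi / 2))
    def test_interference_term_for_normalized_amplitudes(self, theta):
        # classical direct minus coherent direct equals -2(ab)^2 when a^2+b^2=1
        a, b = math.cos(theta), math.sin(theta)
        amps = AmplitudePair(a, b)
        coh_d, coh_r = coherent_path_probs(amps)
        cla_d, cla_r = classical_path_probs(amps)
        assert abs((cla_d - coh_d) + 2 * (a * b) ** 2) < 1e-12
        # conservation under a common normalization
        assert coh_d >= 0 and coh_r >= 0 and cla_d >= 0 and cla_r >= 0
        assert coh_d + coh_r == pytest.approx(1.0, abs=1e-12)
        assert cla_d + cla_r == pytest.approx(1.0, abs=1e-12)

    def test_non_finite_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            AmplitudePair(float("nan"), 0.0)


class TestAssessmentPrediction:
    def test_local_vs_remote(self):
        assert assessment_prediction("local") == pytest.approx(1.0, abs=1e-12)
        assert assessment_prediction("remote") == pytest.approx(0.5, abs=1e-12)

    def test_reverse_components_conserve_per_mode(self):
        amps = AmplitudePair.symmetric()
        for probs in (coherent_path_probs(amps), classical_path_probs(amps)):
            assert sum(probs) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            assessment_prediction("telepathic")


class TestTotalProbUnstructured:
    @pytest.mark.parametrize(
        "prior, c0, c1, expected",
        [
            (0.5, 1.0, 0.0, 0.5),  # stable sub-events, equal priors: no transition
            (1.0, 1.0, 0.3, 1.0),  # degenerate prior
            (0.3, 1.0, 0.0, 0.3),
        ],
    )
    def test_examples(self, prior, c0, c1, expected):
        assert total_prob_unstructured(prior, c0, c1) == pytest.approx(expected)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            total_prob_unstructured(1.5, 1.0, 0.0)


class TestFixedPoints:
    def test_three_points_for_two_observers(self):
        result = fixed_points(2)
        assert not result.identity_map
        assert [fp.p_star for fp in result.points] == pytest.approx([0.0, 0.5, 1.0], abs=1e-9)

    @pytest.mark.parametrize("n", range(2, 7))
    def test_derivative_at_half_equals_observer_count(self, n):
        result = fixed_points(n)
        mid = next(fp for fp in result.points if abs(fp.p_star - 0.5) < 1e-9)
        assert mid.derivative_magnitude == pytest.approx(n, abs=1e-6)
        assert mid.stability == "repelling"

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_boundaries_attracting(self, n):
        result = fixed_points(n)
        for fp in result.points:
            if fp.p_star in (0.0, 1.0):
                assert fp.stability == "attracting"
                assert fp.derivative_magnitude < 1.0

    def test_single_observer_is_identity_map(self):
        result = fixed_points(1)
        assert result.identity_map
        assert all(fp.stability == "neutral" for fp in result.points)

    def test_fixed_points_satisfy_map(self):
        for n in (2, 3, 4):
            for fp in fixed_points(n).points:
                assert abs(agreement_prob(fp.p_star, n) - fp.p_star) < 1e-9

    def test_zero_observers_rejected(self):
        with pytest.raises(ValueError):
            fixed_points(0)
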