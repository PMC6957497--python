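import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedanc import (
    ErrorModelParams,
    MendelianRateModel,
    diploid_transition,
    double_crossover_prob,
    estimate_epsilon,
    estimate_lambda,
    exact_mendelian_rate,
    expected_dosage_error,
    expected_mendelian_rate,
    haploid_transition,
    inference_matrix,
    inference_prob,
    mendelian_rate_mc,
)
from pedanc.pedigree import FamilyType
from pedanc.prob_models import dosage_stationary

params_strategy = st.tuples(
    st.floats(0.0, 0.5),  # d in Morgans
    st.floats(0.5, 20.0),  # tau
    st.floats(0.05, 0.95),  # lamb
)


class TestTransitions:
    def test_zero_distance_is_identity(self):
        assert np.allclose(haploid_transition(0.0, 8, 0.8), np.eye(2))
        assert np.allclose(diploid_transition(0.0, 8, 0.8), np.eye(3))

    def test_large_distance_reaches_stationarity(self):
        H = haploid_transition(1e3, 8, 0.8)
        assert np.allclose(H, [[0.2, 0.8], [0.2, 0.8]], atol=1e-12)
        D = diploid_transition(1e3, 8, 0.8)
        assert np.allclose(D, np.tile(dosage_stationary(0.8), (3, 1)), atol=1e-12)

    def test_haploid_stay_probability_closed_form(self):
        # d=0.02 M, tau=8, lamb=0.8: exp(-0.16) + 0.8*(1-exp(-0.16))
        H = haploid_transition(0.02, 8, 0.8)
        assert H[1, 1] == pytest.approx(
            math.exp(-0.16) + 0.8 * (1 - math.exp(-0.16)), abs=1e-12
        )
        assert H[1, 1] == pytest.approx(0.970429, abs=5e-7)

    def test_diploid_double_switch_is_squared_single_switch(self):
        d, tau, lamb = 0.03, 8, 0.7
        D = diploid_transition(d, tau, lamb)
        p_switch = (1 - math.exp(-d * tau)) * lamb
        assert D[0, 2] == pytest.approx(p_switch**2, abs=1e-15)

    def test_diploid_matches_ordered_pair_enumeration(self):
        d, tau, lamb = 0.015, 8, 0.8
        H = haploid_transition(d, tau, lamb)
        D = diploid_transition(d, tau, lamb)
        pair_of = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
        for x in range(3):
            a, b = pair_of[x]
            dist = np.zeros(3)
            for a2 in (0, 1):
                for b2 in (0, 1):
                    dist[a2 + b2] += H[a, a2] * H[b, b2]
            assert np.allclose(D[x], dist, atol=1e-15)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            haploid_transition(-0.01, 8, 0.8)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(params_strategy)
    def test_rows_stochastic_and_stationary(self, p):
        d, tau, lamb = p
        H = haploid_transition(d, tau, lamb)
        D = diploid_transition(d, tau, lamb)
        assert np.allclose(H.sum(axis=1), 1, atol=1e-12)
        assert np.allclose(D.sum(axis=1), 1, atol=1e-12)
        assert (H >= 0).all() and (D >= 0).all()
        assert np.allclose([1 - lamb, lamb] @ H, [1 - lamb, lamb], atol=1e-10)
        pi = dosage_stationary(lamb)
        assert np.allclose(pi @ D, pi, atol=1e-10)


class TestInferenceModel:
    def test_zero_error_is_identity(self):
        assert np.allclose(inference_matrix(0.0), np.eye(3))

    @pytest.mark.parametrize(
        "y,x,expected",
        [
            (2, 0, lambda e: e**2),  # both alleles flip
            (1, 1, lambda e: (1 - e) ** 2 + e**2),  # neither or both flip
            (0, 2, lambda e: e**2),
            (1, 0, lambda e: 2 * e * (1 - e)),
        ],
    )
    def test_flip_pattern_enumeration(self, y, x, expected):
        e = 0.03
        assert inference_prob(y, x, e) == pytest.approx(expected(e), abs=1e-15)

    def test_rows_sum_to_one(self):
        for e in (0.0, 0.01, 0.3):
            assert np.allclose(inference_matrix(e).sum(axis=1), 1, atol=1e-15)

    def test_out_of_domain_dosage_rejected(self):
        with pytest.raises(ValueError):
            inference_prob(3, 0, 0.01)


def nine_cell_enumeration(e, lamb):
    """E|Y-X| by explicit enumeration over the 9 (x, y) cells."""
    px = [(1 - lamb) ** 2, 2 * lamb * (1 - lamb), lamb**2]
    P = inference_matrix(e)
    return sum(
        px[x] * P[x, y] * abs(y - x) for x in range(3) for y in range(3)
    )


class TestDosageError:
    def test_zero_epsilon_gives_zero(self):
        assert expected_dosage_error(0.0, 0.8, "literal") == 0
        assert expected_dosage_error(0.0, 0.8, "flip_model") == 0

    def test_literal_variant_value(self):
        # 2(0.01)(0.99) + 0.0001*(0.64 + 0.04)
        assert expected_dosage_error(0.01, 0.8, "literal") == pytest.approx(
            0.019868, abs=1e-12
        )

    def test_flip_model_equals_nine_cell_enumeration(self):
        for e in (0.005, 0.01, 0.05, 0.2):
            for lamb in (0.3, 0.5, 0.8):
                assert expected_dosage_error(e, lamb, "flip_model") == pytest.approx(
                    nine_cell_enumeration(e, lamb), abs=1e-12
                )

    def test_variants_differ_by_epsilon_squared_term(self):
        e, lamb = 0.03, 0.8
        gap = expected_dosage_error(e, lamb, "flip_model") - expected_dosage_error(
            e, lamb, "literal"
        )
        assert gap == pytest.approx(e**2 * (lamb**2 + (1 - lamb) ** 2), abs=1e-15)


class TestMendelianRate:
    def test_zero_epsilon_gives_zero(self):
        for ft in FamilyType:
            model = MendelianRateModel(ft, 2)
            assert expected_mendelian_rate(model, 0.0, 0.8) == 0

    def test_two_parent_single_child_simplification(self):
        # m=1 reduces to eps*(2 - 2*l(1-l)) + eps^2*(1 - 6*l(1-l) + 2*l^2(1-l)^2)
        model = MendelianRateModel(FamilyType.TWO_PARENT, 1)
        assert expected_mendelian_rate(model, 0.01, 0.5) == pytest.approx(
            0.0149625, abs=1e-12
        )

    def test_one_parent_limit_of_pure_ancestry(self):
        # as lamb -> 0 only a doubly-flipped member can break consistency
        model = MendelianRateModel(FamilyType.ONE_PARENT, 1)
        e = 0.01
        assert expected_mendelian_rate(model, e, 1e-9) == pytest.approx(
            2 * e**2, rel=1e-4
        )

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            MendelianRateModel(FamilyType.TWO_PARENT, 0)

    def test_two_parent_formula_matches_exact_enumeration(self):
        # the two-parent closed form is exact for the
        # single-error-per-locus mechanism
        for m in (1, 2):
            for lamb in (0.5, 0.8):
                model = MendelianRateModel(FamilyType.TWO_PARENT, m)
                assert expected_mendelian_rate(model, 0.02, lamb) == pytest.approx(
                    exact_mendelian_rate(model, 0.02, lamb), abs=1e-12
                )

    def test_mc_oracle_agrees_with_exact_enumeration(self):
        rng = np.random.default_rng(7)
        model = MendelianRateModel(FamilyType.TWO_PARENT, 2)
        mean, se = mendelian_rate_mc(model, 0.05, 0.8, 40_000, rng)
        assert abs(mean - exact_mendelian_rate(model, 0.05, 0.8)) < 3 * se


class TestEstimateEpsilon:
    def test_all_zero_counts_give_zero(self):
        fams = [MendelianRateModel(FamilyType.TWO_PARENT, 2)] * 5
        assert estimate_epsilon([0] * 5, fams, 1000, 0.8) == 0.0

    def test_exact_inversion_of_forward_formula(self):
        fams = [
            MendelianRateModel(FamilyType.TWO_PARENT, 1),
            MendelianRateModel(FamilyType.TWO_PARENT, 3),
            MendelianRateModel(FamilyType.ONE_PARENT, 2),
        ]
        L, lamb, eps = 5000, 0.8, 0.02
        counts = [L * expected_mendelian_rate(f, eps, lamb) for f in fams]
        assert estimate_epsilon(counts, fams, L, lamb) == pytest.approx(
            eps, abs=1e-10
        )

    @pytest.mark.parametrize("eps", [0.0, 0.05, 0.1, 0.25])
    def test_inversion_identity_across_range(self, eps):
        fams = [MendelianRateModel(FamilyType.TWO_PARENT, 2)] * 10
        counts = [1000 * expected_mendelian_rate(f, eps, 0.5) for f in fams]
        assert estimate_epsilon(counts, fams, 1000, 0.5) == pytest.approx(
            eps, abs=1e-10
        )

    def test_unattainable_rate_reports_model_maximum(self):
        fams = [MendelianRateModel(FamilyType.TWO_PARENT, 1)]
        with pytest.raises(ValueError, match="model maximum"):
            estimate_epsilon([999], fams, 1000, 0.8)


class TestDoubleCrossoverProb:
    def test_zero_window_gives_zero(self):
        assert double_crossover_prob(0.0, 8) == 0

    def test_two_cm_window_at_tau_eight(self):
        # rate 0.16: 1 - 1.16*exp(-0.16)
        assert double_crossover_prob(0.02, 8) == pytest.approx(0.011513, abs=5e-7)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(0.0, 0.5), st.floats(0.001, 0.5))
    def test_monotone_in_window(self, w, dw):
        assert double_crossover_prob(w + dw, 8) >= double_crossover_prob(w, 8)

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            double_crossover_prob(-0.1, 8)


class TestParams:
    def test_domain_validation(self):
        with pytest.raises(ValueError):
            ErrorModelParams(epsilon=0.6, lamb=0.8)
        with pytest.raises(ValueError):
            ErrorModelParams(epsilon=0.01, lamb=1.0)
        with pytest.raises(ValueError):
            ErrorModelParams(epsilon=0.01, lamb=0.8, tau=0)

    def test_estimate_lambda_ignores_missing(self):
        d = np.array([[2, -1], [2, 0]])
        assert estimate_lambda(d) == pytest.approx((2 + 2 + 0) / 6)
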