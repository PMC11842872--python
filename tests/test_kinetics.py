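"""Equilibrium binding model: on-rates, search times, and error propagation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromokin.kinetics import (
    KineticSummary,
    NuclearContext,
    bound_fraction_from_fractions,
    effective_search_time,
    fractions_from_rates,
    nuclear_volume_from_cross_section,
    predict_bound_fraction,
    propagate_gaussian,
    pseudo_on_rate,
    search_time_direct,
    search_time_facilitated,
)

rates = st.floats(min_value=1e-4, max_value=1e3)


class TestPseudoOnRate:
    def test_algebra(self):
        assert pseudo_on_rate(0.01, 0.1, 0.5) == pytest.approx(0.002)

    def test_zero_bound_fraction(self):
        assert pseudo_on_rate(0.01, 0.0, 0.5) == 0.0

    def test_zero_free_fraction_raises(self):
        with pytest.raises(ZeroDivisionError):
            pseudo_on_rate(0.01, 0.1, 0.0)


class TestSearchTimes:
    def test_facilitated_example(self):
        # A^e_s = 0.5 -> 2 trials; k*_on,u = 1.0 * 0.05 / 0.5 = 0.1 ->
        # tau = 2/0.1 + 1/1 = 21 s
        summary = KineticSummary(
            p_f=0.5, p_b_u=0.05, p_b_s=0.45,
            k_off_u=1.0, k_off_s=0.01, event_fraction_s=0.5,
        )
        assert summary.k_on_u_star == pytest.approx(0.1)
        assert search_time_facilitated(summary) == pytest.approx(2 / 0.1 + 1 / 1.0)

    def test_facilitated_no_detours_when_all_events_specific(self):
        summary = KineticSummary(
            p_f=0.5, p_b_u=0.05, p_b_s=0.45,
            k_off_u=1.0, k_off_s=0.01, event_fraction_s=1.0,
        )
        assert search_time_facilitated(summary) == pytest.approx(1.0 / summary.k_on_u_star)

    def test_direct_example(self):
        assert search_time_direct(0.01, 0.1, 0.5) == pytest.approx(500.0)

    def test_direct_halves_when_bound_fraction_doubles(self):
        assert search_time_direct(0.01, 0.2, 0.5) == pytest.approx(
            search_time_direct(0.01, 0.1, 0.5) / 2
        )

    def test_direct_is_inverse_specific_on_rate(self):
        tau = search_time_direct(0.02, 0.3, 0.6)
        assert tau == pytest.approx(1.0 / pseudo_on_rate(0.02, 0.3, 0.6))

    def test_monotone_in_event_fraction_and_unspecific_on_rate(self):
        taus = []
        for a in np.linspace(0.05, 1.0, 10):
            s = KineticSummary(
                p_f=0.5, p_b_u=0.05, p_b_s=0.45,
                k_off_u=1.0, k_off_s=0.01, event_fraction_s=a,
            )
            taus.append(search_time_facilitated(s))
        assert np.all(np.diff(taus) < 0)
        taus = []
        for p_b_u in np.linspace(0.01, 0.4, 10):  # raises k*_on,u at fixed p_f
            s = KineticSummary(
                p_f=0.5, p_b_u=p_b_u, p_b_s=0.5 - p_b_u,
                k_off_u=1.0, k_off_s=0.01, event_fraction_s=0.3,
            )
            taus.append(search_time_facilitated(s))
        assert np.all(np.diff(taus) < 0)


class TestEffectiveSearchTime:
    def test_identical_context_normalizes_to_one(self):
        ctx = NuclearContext(v_nuc=500.0, n_mol=2.0)
        assert effective_search_time(100.0, ctx, 100.0, ctx) == pytest.approx(1.0)

    def test_halved_volume_halves_ratio(self):
        ref = NuclearContext(v_nuc=500.0, n_mol=2.0)
        half = NuclearContext(v_nuc=250.0, n_mol=2.0)
        assert effective_search_time(100.0, half, 100.0, ref) == pytest.approx(0.5)

    def test_three_stage_trajectory_matches_hand_computation(self):
        # tau * V / N: 100*400/1, 200*200/4, 50*100/8 -> relative 1, 0.25, 0.015625
        stages = [(100.0, 400.0, 1.0), (200.0, 200.0, 4.0), (50.0, 100.0, 8.0)]
        ref_tau, ref_v, ref_n = stages[0]
        ref = NuclearContext(ref_v, ref_n)
        ratios = [
            effective_search_time(t, NuclearContext(v, n), ref_tau, ref)
            for t, v, n in stages
        ]
        assert ratios == pytest.approx([1.0, 0.25, 0.015625])


class TestNuclearVolume:
    def test_unit_area(self):
        assert nuclear_volume_from_cross_section(math.pi) == pytest.approx(4 * math.pi / 3)

    def test_cubic_scaling(self):
        v1 = nuclear_volume_from_cross_section(7.0)
        v2 = nuclear_volume_from_cross_section(7.0 * 4.0)  # area x s^2 with s=2
        assert v2 == pytest.approx(8.0 * v1)

    def test_formula_evaluation(self):
        # r = sqrt(100/pi) = 5.6419 µm, V = (4/3) pi r^3 = 752.25 µm^3
        assert nuclear_volume_from_cross_section(100.0) == pytest.approx(752.2527780636748)


class TestBoundFractionPrediction:
    def test_equal_ratios_give_one_third(self):
        assert predict_bound_fraction(1.0, 1.0, 1.0, 1.0) == pytest.approx(1 / 3)

    def test_langmuir_limit_without_unspecific_binding(self):
        ratio = 0.5
        assert predict_bound_fraction(0.5, 1.0, 0.0, 1.0) == pytest.approx(ratio / (ratio + 1))

    def test_nonpositive_off_rate_rejected(self):
        with pytest.raises(ValueError):
            predict_bound_fraction(1.0, 0.0, 1.0, 1.0)

    @given(k_on_s=rates, k_off_s=rates, k_on_u=rates, k_off_u=rates)
    @settings(max_examples=100, deadline=None)
    def test_rate_fraction_round_trip_is_identity(self, k_on_s, k_off_s, k_on_u, k_off_u):
        # rates -> fractions -> rates -> fractions: identity to machine precision
        p_f, p_b_u, p_b_s = fractions_from_rates(k_on_s, k_off_s, k_on_u, k_off_u)
        assert p_f + p_b_u + p_b_s == pytest.approx(1.0, abs=1e-12)
        k_on_s2 = pseudo_on_rate(k_off_s, p_b_s, p_f)
        k_on_u2 = pseudo_on_rate(k_off_u, p_b_u, p_f)
        p2 = fractions_from_rates(k_on_s2, k_off_s, k_on_u2, k_off_u)
        assert p2 == pytest.approx((p_f, p_b_u, p_b_s), rel=1e-12)

    @given(k_on_s=rates, k_off_s=rates, k_on_u=rates, k_off_u=rates)
    @settings(max_examples=100, deadline=None)
    def test_measured_and_kinetic_routes_agree(self, k_on_s, k_off_s, k_on_u, k_off_u):
        # p_b,s = f_b * A^s_s equals the pure-rate expression when both
        # derive from the same equilibrium
        p_f, p_b_u, p_b_s = fractions_from_rates(k_on_s, k_off_s, k_on_u, k_off_u)
        f_b = p_b_u + p_b_s
        state_fraction_s = p_b_s / f_b
        via_fractions = bound_fraction_from_fractions(f_b, state_fraction_s)
        via_rates = predict_bound_fraction(k_on_s, k_off_s, k_on_u, k_off_u)
        assert via_fractions == pytest.approx(via_rates, rel=1e-10)


class TestPropagateGaussian:
    def test_sum_of_independent_errors(self):
        val, sd = propagate_gaussian(lambda a, b: a + b, [1.0, 2.0], [0.5, 0.5])
        assert val == 3.0
        assert sd == pytest.approx(0.5 * math.sqrt(2))

    def test_ratio_with_exact_denominator(self):
        val, sd = propagate_gaussian(lambda a, b: a / b, [6.0, 2.0], [0.3, 0.0])
        assert val == 3.0
        assert sd == pytest.approx(0.3 / 2.0)

    def test_matches_monte_carlo_for_small_relative_errors(self, rng):
        # delta method vs 1e5-draw Monte Carlo within 5%
        def f(a, b, c):
            return a * b / (c + 1.0)

        values, sds = [2.0, 3.0, 1.5], [0.04, 0.06, 0.03]
        _, sd = propagate_gaussian(f, values, sds)
        draws = f(
            rng.normal(values[0], sds[0], 100_000),
            rng.normal(values[1], sds[1], 100_000),
            rng.normal(values[2], sds[2], 100_000),
        )
        assert sd == pytest.approx(draws.std(), rel=0.05)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            propagate_gaussian(lambda a: a, [1.0], [0.1, 0.2])
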