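"""Closed-form LSS gradient algebra: slopes, retention factors, predictions."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lssgrad.core import (
    LN10,
    ElutionRegime,
    GradientProgram,
    LSSParameters,
    delta_ce,
    elution_composition,
    log_retention_factor_initial,
    normalized_slope,
    predict_retention_time,
    retention_factor,
    retention_factor_at_elution,
    steepness,
)
from lssgrad.simulate import RetentionModel, gradient_time_for_b, oracle_retention_time


class TestGradientProgram:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(Ci=0.5, Cf=0.3, tg=10, t0=0.1),  # Ci >= Cf
            dict(Ci=0.2, Cf=0.2, tg=10, t0=0.1),  # zero span
            dict(Ci=-0.1, Cf=0.5, tg=10, t0=0.1),
            dict(Ci=0.2, Cf=1.2, tg=10, t0=0.1),
            dict(Ci=0.2, Cf=0.5, tg=0.0, t0=0.1),
            dict(Ci=0.2, Cf=0.5, tg=10, t0=0.0),
            dict(Ci=0.2, Cf=0.5, tg=10, t0=0.1, tD=-0.5),
        ],
    )
    def test_invalid_programs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GradientProgram(**kwargs)

    def test_from_volumes(self):
        g = GradientProgram.from_volumes(
            Ci=0.05, Cf=0.5, tg=10.0, V0_ml=0.11, VD_ml=0.17, flow_ml_min=0.5
        )
        assert g.t0 == pytest.approx(0.22)
        assert g.tD == pytest.approx(0.34)

    def test_nonphysical_parameters_rejected(self):
        with pytest.raises(ValueError):
            LSSParameters(S=-3.0, log_k0=5.0)
        with pytest.raises(ValueError):
            LSSParameters(S=10.0, log_k0=float("inf"))


class TestNormalizedSlopeAndSteepness:
    @pytest.mark.parametrize(
        "Ci, Cf, t0, tg, expected",
        [(0.25, 0.45, 0.1, 10.0, 0.002), (0.05, 0.95, 0.2, 9.0, 0.02)],
    )
    def test_normalized_slope_values(self, Ci, Cf, t0, tg, expected):
        g = GradientProgram(Ci=Ci, Cf=Cf, tg=tg, t0=t0, tD=0.0)
        assert normalized_slope(g) == pytest.approx(expected)

    def test_slope_inverse_in_gradient_time(self):
        g = GradientProgram(Ci=0.25, Cf=0.45, tg=10.0, t0=0.1, tD=0.0)
        assert normalized_slope(g.with_tg(100.0)) == pytest.approx(normalized_slope(g) / 10)

    @pytest.mark.parametrize(
        "S, sstar, expected", [(150.0, 0.002, 0.3), (6.0, 0.02, 0.12)]
    )
    def test_steepness_is_S_times_slope(self, S, sstar, expected):
        # pick tg to realize the wanted s* in a fixed window
        g = GradientProgram(Ci=0.25, Cf=0.45, tg=0.1 * 0.2 / sstar, t0=0.1, tD=0.0)
        p = LSSParameters(S=S, log_k0=20.0)
        assert steepness(p, g) == pytest.approx(expected)

    @pytest.mark.parametrize("b_target", [0.05, 0.1, 0.2, 0.3, 0.5, 1.0])
    def test_gradient_time_for_b_round_trip(self, b_target):
        p = LSSParameters(S=80.0, log_k0=25.0)
        window = GradientProgram(Ci=0.25, Cf=0.45, tg=1.0, t0=0.42, tD=0.2)
        tg = gradient_time_for_b(p, window, b_target)
        assert steepness(p, window.with_tg(tg)) == pytest.approx(b_target)


class TestRetentionFactor:
    def test_log_k_at_composition(self):
        p = LSSParameters(S=150.0, log_k0=60.0)
        assert math.log10(retention_factor(p, 0.25)) == pytest.approx(22.5)

    def test_pure_water_gives_k0(self):
        p = LSSParameters(S=7.0, log_k0=2.5)
        assert retention_factor(p, 0.0) == pytest.approx(10.0**2.5)

    def test_small_molecule_example(self):
        p = LSSParameters(S=6.0, log_k0=3.0)
        k = retention_factor(p, 0.05)
        assert math.log10(k) == pytest.approx(2.7)
        assert k == pytest.approx(501.187, rel=1e-5)
        assert log_retention_factor_initial(p, 0.05) == pytest.approx(2.7)

    def test_composition_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            retention_factor(LSSParameters(S=5, log_k0=2), 1.5)


class TestRetentionFactorAtElution:
    def test_exact_form(self):
        # b = 0.12 with ki ~ 501.2: ke = 1/(ln10*0.12 + 1/501.2)
        p = LSSParameters(S=6.0, log_k0=3.0)
        g = GradientProgram(Ci=0.05, Cf=0.95, tg=6.0 * 0.2 * 0.9 / 0.12, t0=0.2, tD=0.0)
        ke = retention_factor_at_elution(p, g)
        assert ke == pytest.approx(1.0 / (LN10 * 0.12 + 1.0 / 501.187), rel=1e-6)
        # the conventional rounded-constant evaluation differs by < 0.15%
        assert ke == pytest.approx(1.0 / (0.276 + 0.0019952), rel=2e-3)

    def test_approximate_form(self):
        p = LSSParameters(S=150.0, log_k0=60.0)
        g = GradientProgram(Ci=0.25, Cf=0.45, tg=10.0, t0=0.1, tD=0.0)  # b = 0.3
        assert retention_factor_at_elution(p, g, approximate=True) == pytest.approx(
            1.0 / (LN10 * 0.3)
        )

    @given(
        st.floats(min_value=0.05, max_value=1.0),
        st.floats(min_value=0.5, max_value=8.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_approximation_always_overestimates(self, b_target, log_ki):
        S = 20.0
        p = LSSParameters(S=S, log_k0=log_ki + S * 0.05)
        g = GradientProgram(
            Ci=0.05, Cf=0.5, tg=S * 0.1 * 0.45 / b_target, t0=0.1, tD=0.0
        )
        exact = retention_factor_at_elution(p, g)
        approx = retention_factor_at_elution(p, g, approximate=True)
        assert exact < approx
        # relative gap is 1/(ln10 * b * ki): below 1% once log ki + log10(ln10*b) >= 2
        if log_ki + math.log10(LN10 * steepness(p, g)) >= 2.0:
            assert (approx - exact) / exact < 0.01


class TestElutionComposition:
    def test_forward_predict_then_invert(self, protein_params, protein_gradient):
        tr, _ = predict_retention_time(protein_params, protein_gradient)
        ce = elution_composition(protein_gradient, tr)
        assert ce.in_window
        assert ce.value == pytest.approx(0.39893, abs=1e-5)
        # cross-check against Ce = (1/S) * log10(k0 / ke_exact)
        ke = retention_factor_at_elution(protein_params, protein_gradient)
        ce_from_ke = (protein_params.log_k0 - math.log10(ke)) / protein_params.S
        assert ce.value == pytest.approx(ce_from_ke, abs=1e-9)

    def test_window_boundaries(self, protein_gradient):
        g = protein_gradient
        assert elution_composition(g, g.t0 + g.tD).value == pytest.approx(g.Ci)
        assert elution_composition(g, g.t0 + g.tD + g.tg).value == pytest.approx(g.Cf)

    def test_out_of_window_is_flagged_not_raised(self, protein_gradient):
        ce = elution_composition(protein_gradient, 0.05)
        assert not ce.in_window
        assert ce.value < protein_gradient.Ci


class TestPredictRetentionTime:
    def test_in_gradient_worked_example(self, protein_params, protein_gradient):
        tr, regime = predict_retention_time(protein_params, protein_gradient)
        assert regime is ElutionRegime.IN_GRADIENT
        assert tr == pytest.approx(7.7465, abs=1e-4)
        # independently verified by the piecewise-integration oracle
        oracle = oracle_retention_time(RetentionModel.linear(protein_params), protein_gradient)
        assert tr == pytest.approx(oracle.tr, abs=1e-4)

    def test_pre_gradient_weakly_retained(self):
        # ki = 1: isocratic elution at t0*(1+ki) = 0.2 min, before the
        # gradient front arrives at t0 + tD = 0.3 min
        p = LSSParameters(S=1.0, log_k0=0.2)
        g = GradientProgram(Ci=0.2, Cf=0.5, tg=5.0, t0=0.1, tD=0.2)
        tr, regime = predict_retention_time(p, g)
        assert regime is ElutionRegime.PRE_GRADIENT
        assert tr == pytest.approx(0.2)

    def test_post_gradient_when_window_too_short(self, protein_params):
        # required elution composition (~0.399) exceeds Cf = 0.38, so the
        # solute is still on the column when the ramp ends
        g = GradientProgram(Ci=0.25, Cf=0.38, tg=10.0, t0=0.1, tD=0.2)
        tr, regime = predict_retention_time(protein_params, g)
        assert regime is ElutionRegime.POST_GRADIENT
        assert tr > g.ramp_end()
        oracle = oracle_retention_time(
            RetentionModel.linear(protein_params), g, horizon_factor=1e6
        )
        assert oracle.regime is ElutionRegime.POST_GRADIENT
        assert tr == pytest.approx(oracle.tr, abs=1e-6)

    def test_raising_Ci_above_elution_composition_washes_solute_out(self, protein_params):
        # at Ci = 0.44 this compound has ki = 1e-6: it is no longer retained
        # at the start and leaves before the gradient front
        g = GradientProgram(Ci=0.44, Cf=0.45, tg=10.0, t0=0.1, tD=0.2)
        tr, regime = predict_retention_time(protein_params, g)
        assert regime is ElutionRegime.PRE_GRADIENT
        assert tr == pytest.approx(g.t0 * (1.0 + 1e-6))

    @given(st.floats(min_value=3.0, max_value=300.0))
    @settings(max_examples=60, derandomize=True)
    def test_strictly_decreasing_in_S(self, S):
        Ci = 0.05
        g = GradientProgram(Ci=Ci, Cf=0.5, tg=20.0, t0=0.1, tD=0.1)
        p_lo = LSSParameters(S=S, log_k0=6.0 + S * Ci)
        p_hi = LSSParameters(S=S * 1.05, log_k0=6.0 + S * 1.05 * Ci)
        tr_lo, r1 = predict_retention_time(p_lo, g)
        tr_hi, r2 = predict_retention_time(p_hi, g)
        if r1 is ElutionRegime.IN_GRADIENT and r2 is ElutionRegime.IN_GRADIENT:
            assert tr_hi < tr_lo

    @given(
        st.floats(min_value=4.0, max_value=25.0),
        st.floats(min_value=10.0, max_value=250.0),
        st.floats(min_value=2.0, max_value=60.0),
    )
    @settings(max_examples=80, derandomize=True)
    def test_round_trip_matches_elution_retention_factor(self, log_ki, S, tg):
        """Predict then invert: Ce equals (1/S)*log10(k0/ke_exact) when
        in-gradient. Exact for a dwell-free system; with dwell the identity
        only holds asymptotically in ki."""
        Ci = 0.1
        p = LSSParameters(S=S, log_k0=log_ki + S * Ci)
        g = GradientProgram(Ci=Ci, Cf=0.9, tg=tg, t0=0.15, tD=0.0)
        tr, regime = predict_retention_time(p, g)
        if regime is not ElutionRegime.IN_GRADIENT:
            return
        ce = elution_composition(g, tr).value
        ke = retention_factor_at_elution(p, g)
        assert abs(ce - (p.log_k0 - math.log10(ke)) / p.S) < 1e-9

    def test_huge_log_ki_stays_finite(self):
        # on-off retained mAb: log ki far beyond float overflow territory
        p = LSSParameters(S=500.0, log_k0=200.0)
        g = GradientProgram(Ci=0.25, Cf=0.45, tg=20.0, t0=0.4, tD=0.2)
        tr, regime = predict_retention_time(p, g)
        assert math.isfinite(tr)
        assert regime is ElutionRegime.IN_GRADIENT


class TestDeltaCe:
    def test_decade_slope_ratio(self):
        assert delta_ce(LSSParameters(S=100.0, log_k0=30.0), 0.002, 0.02) == pytest.approx(0.01)

    def test_albumin_scale_shift(self):
        # an S ~ 222 protein moves only 0.45% in composition across a
        # ten-fold change of gradient slope
        dce = delta_ce(LSSParameters(S=222.2, log_k0=70.0), 0.001, 0.01)
        assert 100 * dce == pytest.approx(0.45, abs=0.001)

    def test_equal_slopes_give_zero(self):
        assert delta_ce(LSSParameters(S=17.0, log_k0=5.0), 0.004, 0.004) == 0.0

    def test_consistent_with_two_predictions(self):
        """Two predict->invert cycles reproduce the closed form for large ki."""
        p = LSSParameters(S=100.0, log_k0=40.0)
        window = GradientProgram(Ci=0.2, Cf=0.6, tg=1.0, t0=0.1, tD=0.15)
        g1 = window.with_tg(gradient_time_for_b(p, window, 0.5))
        g2 = window.with_tg(gradient_time_for_b(p, window, 0.05))
        ce1 = elution_composition(g1, predict_retention_time(p, g1).tr).value
        ce2 = elution_composition(g2, predict_retention_time(p, g2).tr).value
        expected = delta_ce(p, normalized_slope(g1), normalized_slope(g2))
        assert ce2 - ce1 == pytest.approx(expected, abs=1e-4)
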