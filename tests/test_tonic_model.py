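"""The recursive tonic-current prediction and its superposition oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbnephys.errors import NonFiniteInput
from cbnephys.kinetics import BiexpFit
from cbnephys.tonic_model import (AS_PRINTED, ENDPOINT_EXACT,
                                  exact_superposition_tonic,
                                  interpolate_kinetics, predict_tonic)

FIRST = BiexpFit.from_parameters(1.5, 6.0, 0.80)
LAST = BiexpFit.from_parameters(2.0, 6.5, 0.45)


def _single_exp_fit(tau):
    return BiexpFit.from_parameters(tau, tau, 1.0)


def _reference_recursion(P, tau, latency=8.4):
    """Independent hand-coded oracle for constant single-exponential kinetics."""
    D = np.exp(-latency / tau)
    out, prev = [], 0.0
    for p in P:
        prev = (p + prev) * D
        out.append(prev)
    return np.asarray(out)


class TestInterpolation:
    def test_first_stimulus_returns_first_fit_exactly(self):
        assert interpolate_kinetics(FIRST, LAST, 1, 20) == (
            FIRST.tau_fast_ms, FIRST.tau_slow_ms, FIRST.frac_fast, FIRST.frac_slow)

    def test_midpoint_at_stimulus_11(self):
        tau_f, tau_s, f_f, f_s = interpolate_kinetics(FIRST, LAST, 11, 20)
        assert tau_f == pytest.approx((FIRST.tau_fast_ms + LAST.tau_fast_ms) / 2)
        assert tau_s == pytest.approx((FIRST.tau_slow_ms + LAST.tau_slow_ms) / 2)
        assert f_f == pytest.approx((FIRST.frac_fast + LAST.frac_fast) / 2)
        assert f_f + f_s == pytest.approx(1.0, abs=1e-12)

    def test_stimulus_20_does_not_reach_last_fit(self):
        """The fixed /20 weights leave stimulus 20 at 0.05*first + 0.95*last."""
        tau_f, *_ = interpolate_kinetics(FIRST, LAST, 20, 20, mode=AS_PRINTED)
        assert tau_f == pytest.approx(
            0.05 * FIRST.tau_fast_ms + 0.95 * LAST.tau_fast_ms, abs=1e-12)
        assert tau_f != pytest.approx(LAST.tau_fast_ms, abs=1e-6)

    def test_endpoint_exact_reaches_last_fit(self):
        tau_f, tau_s, f_f, _ = interpolate_kinetics(
            FIRST, LAST, 20, 20, mode=ENDPOINT_EXACT)
        assert (tau_f, tau_s, f_f) == pytest.approx(
            (LAST.tau_fast_ms, LAST.tau_slow_ms, LAST.frac_fast))

    def test_verbatim_slow_interpolation_variant(self):
        """The strict-as-printed variant anchors tau_s at the first FAST tau."""
        _, tau_s, _, _ = interpolate_kinetics(FIRST, LAST, 1, 20,
                                              slow_from_fast_typo=True)
        assert tau_s == FIRST.tau_fast_ms

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            interpolate_kinetics(FIRST, LAST, 21, 20)


class TestRecursion:
    def test_half_decay_single_stimulus(self):
        fit = _single_exp_fit(8.4 / np.log(2.0))
        assert predict_tonic([100.0], fit, fit).tonic_pA[0] == pytest.approx(50.0)

    def test_hand_unrolled_three_stimuli(self):
        fit = _single_exp_fit(10.0)
        got = predict_tonic([100.0] * 3, fit, fit).tonic_pA
        assert np.allclose(got, _reference_recursion([100.0] * 3, 10.0), rtol=1e-10)
        assert got == pytest.approx([43.17, 61.81, 69.85], abs=0.005)

    def test_infinite_tau_gives_cumulative_sum(self):
        fit = _single_exp_fit(1e12)
        P = np.array([100.0, 80.0, 60.0])
        got = predict_tonic(P, fit, fit).tonic_pA
        assert np.allclose(got, np.cumsum(P), rtol=1e-9)

    def test_zero_tau_limit_kills_tonic(self):
        fit = _single_exp_fit(1e-3)
        assert np.all(predict_tonic([100.0] * 5, fit, fit).tonic_pA < 1e-12)

    def test_strict_grouping_variant_decays_phasic_only(self):
        fit = _single_exp_fit(10.0)
        P = [100.0, 100.0]
        got = predict_tonic(P, fit, fit, decay_accumulated=False).tonic_pA
        D = np.exp(-8.4 / 10.0)
        assert got == pytest.approx([100 * D, 100 * D + 100 * D], rel=1e-12)

    def test_non_finite_input_rejected(self):
        fit = _single_exp_fit(10.0)
        with pytest.raises(NonFiniteInput):
            predict_tonic([100.0, np.nan], fit, fit)
        with pytest.raises(NonFiniteInput):
            predict_tonic([], fit, fit)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        P=st.lists(st.floats(1.0, 500.0), min_size=1, max_size=12),
        scale=st.floats(0.1, 10.0),
    )
    def test_linearity_in_phasic_amplitudes(self, P, scale):
        base = predict_tonic(P, FIRST, LAST).tonic_pA
        scaled = predict_tonic(np.asarray(P) * scale, FIRST, LAST).tonic_pA
        assert np.allclose(scaled, base * scale, rtol=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        P=st.lists(st.floats(1.0, 500.0), min_size=2, max_size=12),
        k=st.integers(0, 11),
        bump=st.floats(1.0, 100.0),
    )
    def test_monotone_nondecreasing_in_each_phasic(self, P, k, bump):
        k = k % len(P)
        hi = list(P)
        hi[k] += bump
        lo_T = predict_tonic(P, FIRST, LAST).tonic_pA
        hi_T = predict_tonic(hi, FIRST, LAST).tonic_pA
        assert np.all(hi_T - lo_T >= -1e-12)


class TestSuperpositionOracle:
    def test_single_stimulus_identical_to_recursion(self):
        got = exact_superposition_tonic([250.0], 1.5, 6.0, 0.8,
                                        isi_ms=10.0, latency_ms=8.4)
        pred = predict_tonic([250.0], FIRST, FIRST).tonic_pA
        assert got[0] == pytest.approx(pred[0], rel=1e-12)

    def test_identity_when_isi_equals_latency(self):
        """For constant single-exponential kinetics and isi = latency the
        recursion is algebraically exact."""
        fit = _single_exp_fit(10.0)
        P = [100.0, 70.0, 55.0, 50.0]
        rec = predict_tonic(P, fit, fit).tonic_pA
        sup = exact_superposition_tonic(P, 10.0, 10.0, 1.0,
                                        isi_ms=8.4, latency_ms=8.4)
        assert np.allclose(rec, sup, rtol=1e-12)

    def test_three_pulse_value_and_recursion_overestimate(self):
        sup = exact_superposition_tonic([100.0] * 3, 10.0, 10.0, 1.0,
                                        isi_ms=10.0, latency_ms=8.4)
        assert sup[2] == pytest.approx(64.90, abs=0.005)
        rec = _reference_recursion([100.0] * 3, 10.0)
        assert sup[2] < rec[2]   # the 8.4-ms factor overestimates retention

    def test_non_finite_rejected(self):
        with pytest.raises(NonFiniteInput):
            exact_superposition_tonic([np.inf], 1.0, 2.0, 0.5)
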