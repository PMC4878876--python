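"""Phasic/tonic decomposition, mGluR differences, holding currents, ramps."""

import dataclasses

import numpy as np
import pytest

from cbnephys.errors import (EmptyGroup, StimulusOutsideTrace, TooFewStimuli,
                             UnevokedTrace, WindowTooShort)
from cbnephys.synthetic import (SynthIPSCParams, generate_ipsc_train_trace,
                                generate_ramp_trace)
from cbnephys.trace import Trace
from cbnephys.trains import (RampProtocol, TrainDecomposition,
                             holding_current_stats, mean_tonic_5_10,
                             measure_train, mglur_tonic_difference,
                             ramp_difference_currents, steady_state_depression)

PRE_MS = 150.0


def _flat_trace(level=0.0, n=20000, dt=0.02):
    stim = PRE_MS + 10.0 * np.arange(10)
    return Trace(values=np.full(n, level), sample_interval_ms=dt,
                 stim_times_ms=stim)


def test_flat_trace_decomposes_to_zero():
    d = measure_train(_flat_trace(level=-40.0))
    assert np.allclose(d.phasic_pA, 0.0)
    assert np.allclose(d.tonic_pA, 0.0)
    assert d.baseline_pA == pytest.approx(-40.0)


def test_single_noiseless_ipsc_peak_and_tonic_are_analytic(noiseless_params):
    """P_1 equals the generating amplitude; T_1 equals the biexponential
    decay value at the 8.4-ms measurement point."""
    p = dataclasses.replace(noiseless_params, n_stimuli=1)
    tr = generate_ipsc_train_trace(p, seed=0)
    d = measure_train(tr)
    assert d.phasic_pA[0] == pytest.approx(p.peak_amplitude_pA, rel=1e-9)
    rel = 8.4 - p.peak_time_ms
    expected = p.peak_amplitude_pA * (
        p.frac_fast_first * np.exp(-rel / p.tau_fast_first_ms)
        + (1 - p.frac_fast_first) * np.exp(-rel / p.tau_slow_first_ms))
    assert d.tonic_pA[0] == pytest.approx(expected, rel=1e-3)


def test_noiseless_train_matches_generator_truth(noiseless_params):
    """Measured T_n tracks the analytic ground truth to < 0.5% of P_1, and
    P_n + T_{n-1} reconstructs the measured peaks exactly."""
    tr = generate_ipsc_train_trace(noiseless_params, seed=0)
    d = measure_train(tr)
    gt = np.asarray(tr.ground_truth["tonic_pA"])
    p1 = noiseless_params.peak_amplitude_pA
    assert np.max(np.abs(d.tonic_pA - gt)) < 0.005 * p1
    recon = d.phasic_pA + np.concatenate([[0.0], d.tonic_pA[:-1]])
    assert np.allclose(recon, d.peak_pA, atol=1e-9)


def test_normalized_outputs_invariant_under_rescaling(noiseless_params):
    tr = generate_ipsc_train_trace(noiseless_params, seed=0)
    d1 = measure_train(tr)
    tr2 = dataclasses.replace(tr, values=tr.values * 3.7)
    d2 = measure_train(tr2)
    assert np.allclose(d1.tonic_pct, d2.tonic_pct, atol=1e-9)
    assert np.allclose(d1.phasic_pct, d2.phasic_pct, atol=1e-9)
    assert d1.phasic_pct[0] == 100.0


def test_unevoked_noisy_trace_rejected():
    rng = np.random.default_rng(0)
    tr = _flat_trace()
    tr = dataclasses.replace(tr, values=rng.normal(0.0, 5.0, tr.n_samples))
    with pytest.raises(UnevokedTrace):
        measure_train(tr)


def test_measurement_point_outside_trace_rejected(noiseless_params):
    tr = generate_ipsc_train_trace(noiseless_params, seed=0, post_ms=50.0)
    short = dataclasses.replace(tr, values=tr.values[:int(345 / 0.02)])
    with pytest.raises(StimulusOutsideTrace):
        measure_train(short)


class TestMeanTonic:
    def _decomp(self, tonic_pct):
        tonic = np.asarray(tonic_pct, dtype=float)
        return TrainDecomposition(
            baseline_pA=0.0, peak_pA=np.full(tonic.size, 100.0),
            phasic_pA=np.full(tonic.size, 100.0), tonic_pA=tonic)

    def test_constant_tonic(self):
        assert mean_tonic_5_10(self._decomp([8.0] * 10)) == pytest.approx(8.0)

    def test_ramp_values(self):
        tonic = [0, 0, 0, 0, 5, 6, 7, 8, 9, 10]
        assert mean_tonic_5_10(self._decomp(tonic)) == pytest.approx(7.5)

    def test_too_few_stimuli(self):
        with pytest.raises(TooFewStimuli):
            mean_tonic_5_10(self._decomp([1.0] * 9))

    def test_steady_state_depression_metric(self):
        d = TrainDecomposition(
            baseline_pA=0.0, peak_pA=np.array([100.0] * 5 + [40.0] * 5),
            phasic_pA=np.ones(10), tonic_pA=np.zeros(10))
        assert steady_state_depression(d) == pytest.approx(40.0)


def test_mglur_difference_zero_for_identical_groups(noiseless_params):
    tr = generate_ipsc_train_trace(noiseless_params, seed=0)
    d = measure_train(tr)
    diff = mglur_tonic_difference([d, d], [d, d])
    assert diff.mean_diff == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(EmptyGroup):
        mglur_tonic_difference([], [d])


def test_mglur_difference_matches_generator_arithmetic(noiseless_params):
    """Control with a -40 pA mGluR inward component vs drug without: the
    antagonist-minus-control tonic difference equals the mean mGluR level
    over stimuli 5-10 as a % of P_1 (derived from the generator's onset
    formula), within measurement tolerance."""
    ctrl_p = dataclasses.replace(noiseless_params, mglur_tonic_amplitude_pA=-40.0)
    ctrl = [measure_train(generate_ipsc_train_trace(ctrl_p, seed=s)) for s in (0, 1)]
    drug = [measure_train(generate_ipsc_train_trace(noiseless_params, seed=s))
            for s in (0, 1)]
    diff = mglur_tonic_difference(ctrl, drug)
    levels = [ctrl_p.mglur_level(n) for n in range(5, 11)]
    expected = -np.mean(levels) / ctrl_p.peak_amplitude_pA * 100.0
    assert diff.mean_diff == pytest.approx(expected, abs=0.2)
    assert diff.mean_diff > 5.0   # a sizeable unmasked outward tonic current


class TestHoldingCurrent:
    def test_constant_current(self):
        tr = Trace(values=np.full(10000, -300.0), sample_interval_ms=0.1)
        mean, var = holding_current_stats(tr, (0.0, 1000.0))
        assert mean == pytest.approx(-300.0)
        assert var == pytest.approx(0.0)

    def test_white_noise_variance(self):
        rng = np.random.default_rng(1)
        tr = Trace(values=rng.normal(-300.0, 10.0, 20000), sample_interval_ms=0.1)
        mean, var = holding_current_stats(tr, (0.0, 2000.0))
        assert var == pytest.approx(100.0, rel=0.1)
        assert mean == pytest.approx(-300.0, abs=1.0)

    def test_short_window_rejected(self):
        tr = Trace(values=np.zeros(100), sample_interval_ms=0.1)
        with pytest.raises(WindowTooShort):
            holding_current_stats(tr, (0.0, 0.5))


class TestRamps:
    protocol = RampProtocol()

    def test_identical_conditions_give_zero_difference(self):
        tr = generate_ramp_trace(self.protocol, noise_sd_pA=0.0)[0]
        rc = ramp_difference_currents(tr, tr, tr, self.protocol)
        assert np.allclose(rc.transporter_induced, 0.0)
        assert np.allclose(rc.antagonist_sensitive, 0.0)

    def test_antagonist_sensitive_recovers_injected_leak_slope(self):
        """A TBOA-added linear leak of -2 pA/mV that the antagonist removes
        appears in the antagonist-sensitive difference with that slope."""
        ctrl = generate_ramp_trace(self.protocol, noise_sd_pA=1.0, seed=1)
        tboa = generate_ramp_trace(self.protocol, extra_leak_pA_per_mV=2.0,
                                   noise_sd_pA=1.0, seed=2)
        ant = generate_ramp_trace(self.protocol, noise_sd_pA=1.0, seed=3)
        rc = ramp_difference_currents(ctrl, tboa, ant, self.protocol)
        slope = np.polyfit(rc.voltage_mV, rc.antagonist_sensitive, 1)[0]
        assert slope == pytest.approx(2.0, rel=0.02)

    def test_sweep_average_of_identical_sweeps_equals_single(self):
        sweeps = generate_ramp_trace(self.protocol, noise_sd_pA=0.0, n_sweeps=3)
        rc3 = ramp_difference_currents(sweeps, sweeps[0], sweeps[1], self.protocol)
        rc1 = ramp_difference_currents(sweeps[0], sweeps[0], sweeps[0], self.protocol)
        assert np.allclose(rc3.current_control, rc1.current_control)

    def test_grid_spacing_is_4_ms(self):
        times, volts = self.protocol.ramp_grid()
        assert np.allclose(np.diff(times), 4.0)
        assert volts[0] == pytest.approx(-20.0)
        assert volts[-1] == pytest.approx(-80.0, abs=1.0)
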