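"""Generator correctness: analytic superposition, ground truth, determinism."""

import dataclasses

import numpy as np
import pytest

from cbnephys.kinetics import fit_ipsc
from cbnephys.synthetic import (SynthIPSCParams, SynthSpikingParams,
                                analytic_train_current, generate_cohort,
                                generate_ipsc_train_trace,
                                generate_spiking_trace, ground_truth_tonic)
from cbnephys.tonic_model import exact_superposition_tonic

PRE_MS = 150.0


def test_noiseless_trace_equals_analytic_superposition(noiseless_params):
    """Outside artifact blanks the noiseless trace is the exact analytic sum."""
    p = dataclasses.replace(noiseless_params, mglur_tonic_amplitude_pA=-30.0)
    tr = generate_ipsc_train_trace(p, seed=0)
    ana = analytic_train_current(p, tr.time_ms - PRE_MS, 0.0)
    dev = np.abs(tr.values - ana)[~tr.artifact_mask()]
    assert np.max(dev) < 1e-9 * p.peak_amplitude_pA


def test_single_event_decay_is_analytic_biexponential(noiseless_params):
    """A lone noiseless IPSC decays as the generating biexponential exactly."""
    p = dataclasses.replace(noiseless_params, n_stimuli=1)
    tr = generate_ipsc_train_trace(p, seed=0)
    t = tr.time_ms
    decay = t > PRE_MS + p.peak_time_ms
    rel = t[decay] - PRE_MS - p.peak_time_ms
    expected = p.peak_amplitude_pA * (
        p.frac_fast_first * np.exp(-rel / p.tau_fast_first_ms)
        + (1 - p.frac_fast_first) * np.exp(-rel / p.tau_slow_first_ms))
    assert np.allclose(tr.values[decay], expected, atol=1e-9 * p.peak_amplitude_pA)


def test_ground_truth_tonic_matches_superposition_oracle(nodrift_params):
    """With drift disabled, generator tonic truth equals the independent
    exact-superposition oracle at every measurement time."""
    p = nodrift_params
    gt = ground_truth_tonic(p)
    P = np.array([p.phasic_amplitude(n) for n in range(1, p.n_stimuli + 1)])
    oracle = exact_superposition_tonic(
        P, p.tau_fast_first_ms, p.tau_slow_first_ms, p.frac_fast_first,
        isi_ms=p.isi_ms, latency_ms=8.4 - p.peak_time_ms)
    assert np.max(np.abs(gt - oracle)) < 1e-9 * P[0]


def test_ground_truth_tonic_nonnegative_without_mglur(noiseless_params):
    assert np.all(ground_truth_tonic(noiseless_params) >= 0)


def test_generated_weighted_tau_is_fraction_weighted_sum(presets):
    for preset in presets.values():
        p = preset.ipsc
        assert p.weighted_tau_first_ms() == pytest.approx(
            p.frac_fast_first * p.tau_fast_first_ms
            + (1 - p.frac_fast_first) * p.tau_slow_first_ms, abs=1e-12)


def test_depression_follows_plateau_model(noiseless_params):
    p = noiseless_params
    d, k = p.depression_plateau_frac, p.depression_rate_stimuli
    for n in (1, 2, 5, 20):
        expected = p.peak_amplitude_pA * (d + (1 - d) * np.exp(-(n - 1) / k))
        assert p.phasic_amplitude(n) == pytest.approx(expected, rel=1e-12)
    assert p.phasic_amplitude(1) == pytest.approx(p.peak_amplitude_pA)


@pytest.mark.parametrize("override", [
    {"tau_fast_first_ms": -1.0},
    {"frac_fast_first": 1.4},
    {"tau_fast_first_ms": 7.0},          # exceeds tau_slow
    {"n_stimuli": 0},
    {"sample_interval_ms": 0.0},
    {"depression_plateau_frac": 0.0},
    {"mglur_tonic_amplitude_pA": 5.0},   # must be inward
])
def test_invalid_params_rejected(override):
    with pytest.raises(ValueError):
        SynthIPSCParams(**override)


def test_train_longer_than_trace_rejected(noiseless_params):
    with pytest.raises(ValueError):
        generate_ipsc_train_trace(noiseless_params, seed=0, duration_ms=200.0)


def test_same_seed_gives_bitwise_identical_traces(presets):
    p = presets["wt_male"].ipsc
    a = generate_ipsc_train_trace(p, seed=7)
    b = generate_ipsc_train_trace(p, seed=7)
    assert np.array_equal(a.values, b.values)
    c = generate_spiking_trace(SynthSpikingParams(), seed=7)
    d = generate_spiking_trace(SynthSpikingParams(), seed=7)
    assert np.array_equal(c.values, d.values)
    assert c.ground_truth["spike_times_ms"] == d.ground_truth["spike_times_ms"]


def test_cohort_deterministic_and_cv_zero_equals_presets(presets):
    groups = list(presets.values())
    one = generate_cohort(groups, 1, seed=5, cv=0.0, include_spiking=False)
    for cell, preset in zip(one, groups):
        assert cell.ipsc_params.peak_amplitude_pA == preset.ipsc.peak_amplitude_pA
        assert cell.ipsc_params.tau_fast_first_ms == preset.ipsc.tau_fast_first_ms
        assert cell.ipsc_params.mglur_tonic_amplitude_pA == \
            preset.ipsc.mglur_tonic_amplitude_pA
    again = generate_cohort(groups, 1, seed=5, cv=0.0, include_spiking=False)
    for a, b in zip(one, again):
        assert np.array_equal(a.traces["control"].values, b.traces["control"].values)


def test_cohort_drug_condition_removes_mglur_component(presets):
    cell = generate_cohort([presets["mut_male"]], 1, seed=1, cv=0.0,
                           include_spiking=False)[0]
    ctrl = np.asarray(cell.traces["control"].ground_truth["mglur_pA"])
    drug = np.asarray(cell.traces["cpccoet"].ground_truth["mglur_pA"])
    assert np.any(ctrl < 0)
    assert np.all(drug == 0)


def test_first_ipsc_fit_recovers_preset_weighted_tau(presets):
    """The wild-type-male preset (weighted tau 2.3 ms) is recovered within 5%
    by the decay fit at the default noise level."""
    p = presets["wt_male"].ipsc
    errors = []
    for seed in range(20):
        tr = generate_ipsc_train_trace(p, seed=seed)
        fit = fit_ipsc(tr, 0)
        errors.append(abs(fit.weighted_tau_ms - 2.3) / 2.3)
    assert np.median(errors) < 0.05


def test_spiking_trace_rates_near_nominal(rebound_params):
    """Generated spike counts in the pre/rebound windows track the nominal
    rates within a few renewal-process standard deviations."""
    counts_pre, counts_post = [], []
    for seed in range(30):
        tr = generate_spiking_trace(rebound_params, seed=seed)
        gt = tr.ground_truth
        spikes = np.asarray(gt["spike_times_ms"])
        on, off = gt["train_onset_ms"], gt["train_end_ms"]
        counts_pre.append(np.sum((spikes >= on - 500) & (spikes < on)))
        counts_post.append(np.sum((spikes >= off) & (spikes < off + 300)))
    assert np.mean(counts_pre) == pytest.approx(20.0, abs=1.0)   # 40 Hz * 0.5 s
    assert np.mean(counts_post) == pytest.approx(18.0, abs=1.0)  # 60 Hz * 0.3 s


def test_spike_template_single_maximum_enforced():
    bad = np.array([0.0, 30.0, 5.0, 30.0, 0.0])
    with pytest.raises(ValueError):
        SynthSpikingParams(spike_template=bad)
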