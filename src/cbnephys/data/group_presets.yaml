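# Generating presets for the four sex x genotype groups of cerebellar-nucleus
# cells.  Printed group means anchor: first/last IPSC weighted decay time
# constants (2.3/4.4 ms wild-type males, 2.5/3.2 mutant males, 1.8/2.3
# wild-type females, 1.8/3.1 mutant females; fast/slow split chosen so
# F_f*tau_f + F_s*tau_s reproduces these exactly), spontaneous firing rates
# (65/92/98/96 spikes/s), holding currents at -40 mV (-565/-491/-406/-424 pA),
# TBOA-unmasked mGluR currents (-297/-419/-184/-184 pA), and the
# antagonist-sensitive rebound components (7/53/39/25 percentage points).
# Evoked mGluR tonic amplitudes and control rebound changes are qualitative
# calibrations (the source figures are graphical): wild-type males carry no
# evoked mGluR inward component, mutant males the largest.
groups:
  wt_male:
    sex: male
    genotype: "+/+"
    ipsc:
      peak_amplitude_pA: 400.0
      tau_fast_first_ms: 1.5
      tau_slow_first_ms: 6.0
      frac_fast_first: 0.8222222222222222
      tau_fast_last_ms: 2.0
      tau_slow_last_ms: 6.5
      frac_fast_last: 0.4666666666666667
      mglur_tonic_amplitude_pA: 0.0
    spiking:
      baseline_rate_Hz: 65.0
    holding_current_pA: -565.0
    mglur_tboa_current_pA: -297.0
    rebound_pre_rate_Hz: 40.0
    rebound_change_control_pct: 50.0
    rebound_change_mglur_pct: 7.0
  mut_male:
    sex: male
    genotype: "m-/p+"
    ipsc:
      peak_amplitude_pA: 400.0
      tau_fast_first_ms: 1.5
      tau_slow_first_ms: 6.0
      frac_fast_first: 0.7777777777777778
      tau_fast_last_ms: 2.0
      tau_slow_last_ms: 6.5
      frac_fast_last: 0.7333333333333333
      mglur_tonic_amplitude_pA: -30.0
    spiking:
      baseline_rate_Hz: 92.0
    holding_current_pA: -491.0
    mglur_tboa_current_pA: -419.0
    rebound_pre_rate_Hz: 40.0
    rebound_change_control_pct: 90.0
    rebound_change_mglur_pct: 53.0
  wt_female:
    sex: female
    genotype: "+/+"
    ipsc:
      peak_amplitude_pA: 400.0
      tau_fast_first_ms: 1.5
      tau_slow_first_ms: 6.0
      frac_fast_first: 0.9333333333333333
      tau_fast_last_ms: 2.0
      tau_slow_last_ms: 6.5
      frac_fast_last: 0.9333333333333333
      mglur_tonic_amplitude_pA: -25.0
    spiking:
      baseline_rate_Hz: 98.0
    holding_current_pA: -406.0
    mglur_tboa_current_pA: -184.0
    rebound_pre_rate_Hz: 40.0
    rebound_change_control_pct: 80.0
    rebound_change_mglur_pct: 39.0
  mut_female:
    sex: female
    genotype: "m-/p+"
    ipsc:
      peak_amplitude_pA: 400.0
      tau_fast_first_ms: 1.5
      tau_slow_first_ms: 6.0
      frac_fast_first: 0.9333333333333333
      tau_fast_last_ms: 2.0
      tau_slow_last_ms: 6.5
      frac_fast_last: 0.7555555555555555
      mglur_tonic_amplitude_pA: -20.0
    spiking:
      baseline_rate_Hz: 96.0
    holding_current_pA: -424.0
    mglur_tboa_current_pA: -184.0
    rebound_pre_rate_Hz: 40.0
    rebound_change_control_pct: 70.0
    rebound_change_mglur_pct: 25.0
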