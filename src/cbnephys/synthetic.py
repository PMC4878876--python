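"""Synthetic patch-clamp traces with known ground truth.

This module emulates the recordings the analysis pipeline consumes, so every
downstream stage can be validated against exact, analytically known answers:

* 100-Hz, 200-ms evoked IPSC trains at a -40 mV holding potential.  Each
  IPSC is a rise-filtered biexponential; decay kinetics drift linearly from
  first-IPSC to last-IPSC values over the train; per-stimulus phasic peaks
  depress exponentially toward a plateau; an optional stimulus-driven tonic
  inward (mGluR-like) current builds up over the train.
* current-clamp traces with spontaneous spiking (gamma-interval renewal
  process) and a 500-ms inhibitory-train rebound protocol.
* whole cohorts over the four sex x genotype groups, with multiplicative
  lognormal cell-to-cell variability and paired control / mGluR-antagonist
  conditions.

Sign convention: voltage-clamp current is outward-positive (GABAergic IPSCs
at -40 mV are positive deflections; mGluR- and TBOA-dependent standing
currents are negative).

Waveform details.  Each IPSC rises as (1 - exp(-t/rise_tau)), normalized to
reach the biexponential decay curve at ``peak_time_ms`` after stimulus onset;
decay amplitude and fractions are referenced AT THE PEAK, so the measured
peak equals the generating P_n exactly and a decay-phase fit recovers the
generating (tau_f, tau_s, F_f) exactly on noiseless data.  A large decaying
artifact transient is confined strictly to the ``artifact_blank_ms`` window
after each stimulus; outside blanks the noiseless trace equals the analytic
superposition to floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .trace import CURRENT_CLAMP, VOLTAGE_CLAMP, Trace

TONIC_LATENCY_MS = 8.4


# ----------------------------------------------------------------------
# parameter containers
# ----------------------------------------------------------------------
@dataclass
class SynthIPSCParams:
    """Parameters of a synthetic evoked IPSC train (voltage clamp)."""

    peak_amplitude_pA: float = 400.0        # first IPSC, outward-positive
    tau_fast_first_ms: float = 1.5
    tau_slow_first_ms: float = 6.0
    frac_fast_first: float = 0.8222222222222222   # weighted tau 2.3 ms
    tau_fast_last_ms: float = 2.0
    tau_slow_last_ms: float = 6.5
    frac_fast_last: float = 0.4666666666666667    # weighted tau 4.4 ms
    rise_tau_ms: float = 0.3
    peak_time_ms: float = 0.8               # stimulus onset -> IPSC peak
    depression_plateau_frac: float = 0.55   # steady-state P_n / P_1
    depression_rate_stimuli: float = 2.0
    mglur_tonic_amplitude_pA: float = 0.0   # inward, <= 0
    mglur_onset_tau_stimuli: float = 2.0
    noise_sd_pA: float = 4.0
    artifact_blank_ms: float = 0.6
    n_stimuli: int = 20
    stim_freq_Hz: float = 100.0
    sample_interval_ms: float = 0.02

    def __post_init__(self) -> None:
        taus = (self.tau_fast_first_ms, self.tau_slow_first_ms,
                self.tau_fast_last_ms, self.tau_slow_last_ms, self.rise_tau_ms)
        if any(tau <= 0 for tau in taus):
            raise ValueError("all time constants must be positive")
        for f in (self.frac_fast_first, self.frac_fast_last):
            if not 0.0 <= f <= 1.0:
                raise ValueError("frac_fast must lie in [0, 1]")
        if self.tau_fast_first_ms > self.tau_slow_first_ms:
            raise ValueError("first-IPSC tau_fast must not exceed tau_slow")
        if self.tau_fast_last_ms > self.tau_slow_last_ms:
            raise ValueError("last-IPSC tau_fast must not exceed tau_slow")
        if self.n_stimuli < 1:
            raise ValueError("n_stimuli must be >= 1")
        if self.sample_interval_ms <= 0:
            raise ValueError("sample_interval_ms must be positive")
        if not 0.0 < self.depression_plateau_frac <= 1.5:
            raise ValueError("depression_plateau_frac must lie in (0, 1.5]")
        if self.mglur_tonic_amplitude_pA > 0:
            raise ValueError("mGluR tonic amplitude is inward (<= 0)")

    @property
    def isi_ms(self) -> float:
        return 1000.0 / self.stim_freq_Hz

    def weighted_tau_first_ms(self) -> float:
        return self.frac_fast_first * self.tau_fast_first_ms + \
            (1 - self.frac_fast_first) * self.tau_slow_first_ms

    def weighted_tau_last_ms(self) -> float:
        return self.frac_fast_last * self.tau_fast_last_ms + \
            (1 - self.frac_fast_last) * self.tau_slow_last_ms

    def kinetics_at(self, n: int) -> tuple[float, float, float]:
        """(tau_f, tau_s, F_f) of stimulus n (1-based), linearly
        interpolated so stimulus n_stimuli equals the last-IPSC values."""
        w = 0.0 if self.n_stimuli == 1 else (n - 1) / (self.n_stimuli - 1)
        return (
            (1 - w) * self.tau_fast_first_ms + w * self.tau_fast_last_ms,
            (1 - w) * self.tau_slow_first_ms + w * self.tau_slow_last_ms,
            (1 - w) * self.frac_fast_first + w * self.frac_fast_last,
        )

    def phasic_amplitude(self, n: int) -> float:
        """P_n = P_1 * (d + (1-d) * exp(-(n-1)/k))."""
        d = self.depression_plateau_frac
        return self.peak_amplitude_pA * (
            d + (1 - d) * np.exp(-(n - 1) / self.depression_rate_stimuli))

    def mglur_level(self, n: int) -> float:
        """mGluR tonic current in effect from stimulus n (inward, <= 0)."""
        if self.mglur_tonic_amplitude_pA == 0:
            return 0.0
        return self.mglur_tonic_amplitude_pA * (
            1 - np.exp(-(n - 1) / self.mglur_onset_tau_stimuli))


@dataclass
class SynthSpikingParams:
    """Parameters of a synthetic current-clamp spiking trace."""

    baseline_rate_Hz: float = 65.0
    rate_cv: float = 0.3                  # cohort-level lognormal variability
    spike_template: np.ndarray | None = None
    rebound_rate_Hz: float = 60.0
    rebound_duration_ms: float = 300.0
    suppression_train_ms: float = 500.0   # 0 disables the rebound protocol
    suppressed_rate_Hz: float = 2.0
    pre_window_ms: float = 500.0
    post_window_ms: float = 300.0
    noise_sd_mV: float = 0.5
    baseline_mV: float = -55.0
    spike_amplitude_mV: float = 45.0
    regularity_shape: float = 10.0        # gamma renewal shape (ISI CV ~ 0.32)
    sample_interval_ms: float = 0.05

    def __post_init__(self) -> None:
        rates = (self.baseline_rate_Hz, self.rebound_rate_Hz, self.suppressed_rate_Hz)
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        if self.pre_window_ms <= 0 or self.post_window_ms <= 0:
            raise ValueError("analysis windows must be positive")
        if self.spike_template is not None:
            tpl = np.asarray(self.spike_template, dtype=float)
            if np.sum((np.diff(np.sign(np.diff(tpl))) < 0)) > 1:
                raise ValueError("spike template must have a single maximum")


@dataclass
class GroupPreset:
    """Generating parameters for one sex x genotype group."""

    name: str
    sex: str                              # "male" | "female"
    genotype: str                         # "+/+" | "m-/p+"
    strain: str = "Gabrb3"
    ipsc: SynthIPSCParams = field(default_factory=SynthIPSCParams)
    spiking: SynthSpikingParams = field(default_factory=SynthSpikingParams)
    holding_current_pA: float = -565.0
    mglur_tboa_current_pA: float = -297.0
    rebound_pre_rate_Hz: float = 40.0
    rebound_change_control_pct: float = 50.0
    rebound_change_mglur_pct: float = 7.0  # component removed by antagonist

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.genotype not in ("+/+", "m-/p+"):
            raise ValueError("genotype must be '+/+' or 'm-/p+'")


# ----------------------------------------------------------------------
# evoked IPSC trains
# ----------------------------------------------------------------------
def default_spike_template(sample_interval_ms: float,
                           amplitude_mV: float = 45.0,
                           sigma_ms: float = 0.15,
                           half_support_ms: float = 1.2) -> np.ndarray:
    """Gaussian action-potential template (single maximum at the centre)."""
    t = np.arange(-half_support_ms, half_support_ms + sample_interval_ms / 2,
                  sample_interval_ms)
    return amplitude_mV * np.exp(-0.5 * (t / sigma_ms) ** 2)


def _rise_factor(t: np.ndarray, rise_tau: float, t_peak: float) -> np.ndarray:
    """Saturating rise, 0 at onset and exactly 1 at the peak time."""
    norm = 1.0 - np.exp(-t_peak / rise_tau)
    return np.clip((1.0 - np.exp(-t / rise_tau)) / norm, 0.0, None)


def analytic_train_current(params: SynthIPSCParams, t_ms: np.ndarray,
                           first_stim_ms: float,
                           include_mglur: bool = True) -> np.ndarray:
    """Noiseless, artifact-free superposition of the train at times t_ms.

    Each stimulus n contributes P_n * rise(t') * g_n(t' - t_peak) for
    t' = t - t_n, with the biexponential decay g_n referenced at the peak.
    The mGluR component is piecewise-constant over inter-stimulus intervals,
    stepping at each stimulus onset and holding its final level after the
    train.
    """
    total = np.zeros_like(t_ms, dtype=float)
    for n in range(1, params.n_stimuli + 1):
        t_n = first_stim_ms + (n - 1) * params.isi_ms
        rel = t_ms - t_n
        active = rel > 0
        if not np.any(active):
            continue
        tau_f, tau_s, f_f = params.kinetics_at(n)
        r = rel[active]
        rise = _rise_factor(r, params.rise_tau_ms, params.peak_time_ms)
        decay_t = np.clip(r - params.peak_time_ms, 0.0, None)
        g = f_f * np.exp(-decay_t / tau_f) + (1 - f_f) * np.exp(-decay_t / tau_s)
        wave = np.where(r < params.peak_time_ms, rise, g)
        total[active] += params.phasic_amplitude(n) * wave
    if include_mglur and params.mglur_tonic_amplitude_pA != 0:
        total += _mglur_waveform(params, t_ms, first_stim_ms)
    return total


def _mglur_waveform(params: SynthIPSCParams, t_ms: np.ndarray,
                    first_stim_ms: float) -> np.ndarray:
    levels = np.array([params.mglur_level(n) for n in range(1, params.n_stimuli + 1)])
    out = np.zeros_like(t_ms, dtype=float)
    for n in range(1, params.n_stimuli + 1):
        t_n = first_stim_ms + (n - 1) * params.isi_ms
        out[t_ms >= t_n] = levels[n - 1]
    return out


def ground_truth_tonic(params: SynthIPSCParams,
                       include_mglur: bool = True) -> np.ndarray:
    """Analytic tonic current T_n at t_n + 8.4 ms, baseline-subtracted."""
    t_meas = np.array([(n - 1) * params.isi_ms + TONIC_LATENCY_MS
                       for n in range(1, params.n_stimuli + 1)])
    return analytic_train_current(params, t_meas, 0.0, include_mglur=include_mglur)


def generate_ipsc_train_trace(
    params: SynthIPSCParams,
    seed: int,
    baseline_pA: float = 0.0,
    pre_ms: float = 150.0,
    post_ms: float = 50.0,
    duration_ms: float | None = None,
) -> Trace:
    """Generate a voltage-clamp IPSC-train trace with ground truth attached.

    The trace holds ``pre_ms`` of baseline, then ``n_stimuli`` IPSCs at
    ``stim_freq_Hz``, then ``post_ms`` of tail.  Ground truth (per-stimulus
    phasic amplitudes, tonic currents with and without the mGluR component,
    per-stimulus kinetics) is stored on ``trace.ground_truth``.
    """
    isi = params.isi_ms
    train_ms = params.n_stimuli * isi
    if duration_ms is None:
        duration_ms = pre_ms + train_ms + post_ms
    if pre_ms + train_ms > duration_ms:
        raise ValueError(
            f"train of {train_ms:.0f} ms at {params.stim_freq_Hz} Hz does not "
            f"fit in a {duration_ms:.0f} ms trace with {pre_ms:.0f} ms baseline")
    dt = params.sample_interval_ms
    n_samples = int(round(duration_ms / dt))
    t = np.arange(n_samples) * dt
    stim_times = pre_ms + isi * np.arange(params.n_stimuli)

    values = baseline_pA + analytic_train_current(params, t, pre_ms)

    # stimulus artifact: large decaying transient strictly inside the blank
    if params.artifact_blank_ms > 0:
        for t_n in stim_times:
            in_blank = (t >= t_n) & (t < t_n + params.artifact_blank_ms)
            values[in_blank] += 5.0 * params.peak_amplitude_pA * \
                np.exp(-(t[in_blank] - t_n) / 0.1)

    rng = np.random.default_rng(seed)
    if params.noise_sd_pA > 0:
        values = values + rng.normal(0.0, params.noise_sd_pA, n_samples)

    kin = np.array([params.kinetics_at(n) for n in range(1, params.n_stimuli + 1)])
    truth = {
        "phasic_pA": [params.phasic_amplitude(n) for n in range(1, params.n_stimuli + 1)],
        "tonic_pA": ground_truth_tonic(params).tolist(),
        "tonic_gaba_pA": ground_truth_tonic(params, include_mglur=False).tolist(),
        "mglur_pA": [params.mglur_level(n) for n in range(1, params.n_stimuli + 1)],
        "tau_fast_ms": kin[:, 0].tolist(),
        "tau_slow_ms": kin[:, 1].tolist(),
        "frac_fast": kin[:, 2].tolist(),
        "peak_times_ms": (stim_times + params.peak_time_ms).tolist(),
        "weighted_tau_first_ms": params.weighted_tau_first_ms(),
        "weighted_tau_last_ms": params.weighted_tau_last_ms(),
        "baseline_pA": baseline_pA,
        "seed": seed,
    }
    return Trace(
        values=values, sample_interval_ms=dt, mode=VOLTAGE_CLAMP, units="pA",
        stim_times_ms=stim_times, artifact_blank_ms=params.artifact_blank_ms,
        meta={"protocol": "ipsc_train", "stim_freq_Hz": params.stim_freq_Hz},
        ground_truth=truth,
    )


# ----------------------------------------------------------------------
# current-clamp spiking traces
# ----------------------------------------------------------------------
def _renewal_spikes(rng: np.random.Generator, rate_Hz: float, t0_ms: float,
                    t1_ms: float, shape: float) -> np.ndarray:
    """Gamma-interval renewal spike times in [t0, t1).

    The process is started several mean intervals before t0 and clipped, so
    counts inside the window are free of start-up transients.
    """
    if rate_Hz <= 0 or t1_ms <= t0_ms:
        return np.empty(0)
    mean_isi = 1000.0 / rate_Hz
    start = t0_ms - 5.0 * mean_isi
    n_draw = max(int((t1_ms - start) / mean_isi * 2) + 20, 20)
    times = start + np.cumsum(rng.gamma(shape, mean_isi / shape, n_draw))
    while times.size and times[-1] < t1_ms:
        times = np.concatenate([
            times, times[-1] + np.cumsum(rng.gamma(shape, mean_isi / shape, n_draw))])
    return times[(times >= t0_ms) & (times < t1_ms)]


def generate_spiking_trace(
    params: SynthSpikingParams,
    seed: int,
    lead_ms: float = 100.0,
    tail_ms: float = 100.0,
) -> Trace:
    """Generate a current-clamp trace with known spike times.

    Layout: lead-in, ``pre_window_ms`` at the baseline rate, an optional
    suppression train (near-zero rate), a rebound period at
    ``rebound_rate_Hz`` for ``rebound_duration_ms``, return to baseline for
    the rest of the post window, then a tail.  Ground-truth spike times and
    the train onset/end are attached to the trace.
    """
    train = params.suppression_train_ms
    post_extra = max(params.post_window_ms - params.rebound_duration_ms, 0.0)
    t_train_on = lead_ms + params.pre_window_ms
    t_train_off = t_train_on + train
    duration = t_train_off + (params.rebound_duration_ms + post_extra if train > 0
                              else 0.0) + tail_ms
    if train == 0:
        duration = lead_ms + params.pre_window_ms + params.post_window_ms + tail_ms

    rng = np.random.default_rng(seed)
    if train > 0:
        segments = [
            (0.0, t_train_on, params.baseline_rate_Hz),
            (t_train_on, t_train_off, params.suppressed_rate_Hz),
            (t_train_off, t_train_off + params.rebound_duration_ms, params.rebound_rate_Hz),
            (t_train_off + params.rebound_duration_ms, duration, params.baseline_rate_Hz),
        ]
    else:
        segments = [(0.0, duration, params.baseline_rate_Hz)]
    spike_times = np.concatenate([
        _renewal_spikes(rng, r, a, b, params.regularity_shape)
        for a, b, r in segments]) if segments else np.empty(0)
    spike_times.sort()

    dt = params.sample_interval_ms
    n_samples = int(round(duration / dt))
    values = np.full(n_samples, params.baseline_mV)
    template = params.spike_template
    if template is None:
        template = default_spike_template(dt, params.spike_amplitude_mV)
    template = np.asarray(template, dtype=float)
    centre = int(np.argmax(template))
    for ts in spike_times:
        i = int(round(ts / dt))
        lo = i - centre
        hi = lo + template.size
        s0, s1 = max(lo, 0), min(hi, n_samples)
        if s1 > s0:
            values[s0:s1] += template[s0 - lo:s1 - lo]
    if params.noise_sd_mV > 0:
        values = values + rng.normal(0.0, params.noise_sd_mV, n_samples)

    truth = {
        "spike_times_ms": spike_times.tolist(),
        "train_onset_ms": t_train_on if train > 0 else None,
        "train_end_ms": t_train_off if train > 0 else None,
        "baseline_rate_Hz": params.baseline_rate_Hz,
        "rebound_rate_Hz": params.rebound_rate_Hz if train > 0 else None,
        "seed": seed,
    }
    return Trace(
        values=values, sample_interval_ms=dt, mode=CURRENT_CLAMP, units="mV",
        stim_times_ms=np.empty(0), artifact_blank_ms=0.0,
        meta={"protocol": "rebound" if train > 0 else "spontaneous"},
        ground_truth=truth,
    )


# ----------------------------------------------------------------------
# voltage-ramp traces
# ----------------------------------------------------------------------
def generate_ramp_trace(
    protocol,
    g_leak_pA_per_mV: float = 4.0,
    e_leak_mV: float = -30.0,
    ltype_amp_pA: float = -150.0,
    extra_leak_pA_per_mV: float = 0.0,
    offset_pA: float = 0.0,
    noise_sd_pA: float = 2.0,
    seed: int = 0,
    n_sweeps: int = 1,
) -> "list[Trace]":
    """Synthetic current response(s) to a voltage-ramp protocol.

    The current is an ohmic leak g*(V - E) plus a voltage-gated L-type-like
    inward component (active above ~-50 mV), an optional extra linear leak
    ``extra_leak_pA_per_mV * V`` (an mGluR/TBOA-dependent conductance), and a
    holding offset.  Returns ``n_sweeps`` traces sharing the protocol.
    """
    t = protocol.time_ms()
    v = protocol.voltage_mV()
    activation = 1.0 / (1.0 + np.exp(-(v + 40.0) / 4.0))   # L-type-ish gate
    base = (g_leak_pA_per_mV * (v - e_leak_mV)
            + ltype_amp_pA * activation * (v + 10.0) / -50.0
            + extra_leak_pA_per_mV * v + offset_pA)
    rng = np.random.default_rng(seed)
    sweeps = []
    for _ in range(n_sweeps):
        values = base + (rng.normal(0.0, noise_sd_pA, t.size) if noise_sd_pA > 0
                         else 0.0)
        sweeps.append(Trace(
            values=values, sample_interval_ms=protocol.sample_interval_ms,
            mode=VOLTAGE_CLAMP, units="pA",
            meta={"protocol": "voltage_ramp", "ramp": protocol.describe()},
        ))
    return sweeps


# ----------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------
@dataclass
class CohortCell:
    """One synthetic cell: its group labels, drawn parameters and traces."""

    cell_id: str
    sex: str
    genotype: str
    strain: str
    group: str
    ipsc_params: SynthIPSCParams
    holding_current_pA: float
    traces: dict = field(default_factory=dict)         # condition -> train Trace
    spiking_traces: dict = field(default_factory=dict)  # condition -> rebound Trace
    spontaneous_trace: Trace | None = None


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative factor with mean 1 and coefficient of variation cv."""
    if cv <= 0:
        return 1.0
    sigma = np.sqrt(np.log(1.0 + cv ** 2))
    return float(rng.lognormal(-sigma ** 2 / 2.0, sigma))


def _draw_cell_params(rng: np.random.Generator, preset: GroupPreset,
                      cv: float) -> SynthIPSCParams:
    p = preset.ipsc
    amp = p.peak_amplitude_pA * _lognormal_factor(rng, cv)
    tau_first = _lognormal_factor(rng, cv / 2)
    tau_last = _lognormal_factor(rng, cv / 2)
    mglur = p.mglur_tonic_amplitude_pA * _lognormal_factor(rng, cv)
    return replace(
        p,
        peak_amplitude_pA=amp,
        tau_fast_first_ms=p.tau_fast_first_ms * tau_first,
        tau_slow_first_ms=p.tau_slow_first_ms * tau_first,
        tau_fast_last_ms=p.tau_fast_last_ms * tau_last,
        tau_slow_last_ms=p.tau_slow_last_ms * tau_last,
        mglur_tonic_amplitude_pA=mglur,
    )


def generate_cohort(
    presets: Sequence[GroupPreset],
    n_cells_per_group: int,
    seed: int,
    cv: float = 0.3,
    include_trains: bool = True,
    include_spiking: bool = True,
    include_spontaneous: bool = False,
) -> list[CohortCell]:
    """Draw a synthetic cohort around the group presets.

    Per-cell parameters are drawn with multiplicative lognormal variability
    (coefficient of variation ``cv``; time constants use cv/2 and scale the
    fast/slow pair jointly so their order and ratios are preserved).  Every
    cell receives a control and an mGluR-antagonist ("cpccoet") condition;
    the antagonist condition removes the mGluR tonic component from trains
    and the mGluR-dependent part of the rebound.  Deterministic for a fixed
    seed.
    """
    if n_cells_per_group < 1:
        raise ValueError("n_cells_per_group must be >= 1")
    root = np.random.SeedSequence(seed)
    cells: list[CohortCell] = []
    for preset, group_seq in zip(presets, root.spawn(len(presets))):
        for j, cell_seq in enumerate(group_seq.spawn(n_cells_per_group)):
            rng = np.random.default_rng(cell_seq)
            trace_seeds = rng.integers(0, 2 ** 31 - 1, 6)
            params = _draw_cell_params(rng, preset, cv)
            cell = CohortCell(
                cell_id=f"{preset.name}_c{j:02d}",
                sex=preset.sex, genotype=preset.genotype, strain=preset.strain,
                group=preset.name, ipsc_params=params,
                holding_current_pA=preset.holding_current_pA,
            )
            if include_trains:
                drug_params = replace(params, mglur_tonic_amplitude_pA=0.0)
                cell.traces["control"] = generate_ipsc_train_trace(
                    params, int(trace_seeds[0]))
                cell.traces["cpccoet"] = generate_ipsc_train_trace(
                    drug_params, int(trace_seeds[1]))
            if include_spiking:
                pre = preset.rebound_pre_rate_Hz * _lognormal_factor(rng, 0.05)
                ctrl_change = preset.rebound_change_control_pct
                drug_change = ctrl_change - preset.rebound_change_mglur_pct
                sp = preset.spiking
                cell.spiking_traces["control"] = generate_spiking_trace(
                    replace(sp, baseline_rate_Hz=pre,
                            rebound_rate_Hz=pre * (1 + ctrl_change / 100.0)),
                    int(trace_seeds[2]))
                cell.spiking_traces["cpccoet"] = generate_spiking_trace(
                    replace(sp, baseline_rate_Hz=pre,
                            rebound_rate_Hz=pre * (1 + drug_change / 100.0)),
                    int(trace_seeds[3]))
            if include_spontaneous:
                sp = preset.spiking
                rate = sp.baseline_rate_Hz * _lognormal_factor(rng, sp.rate_cv)
                cell.spontaneous_trace = generate_spiking_trace(
                    replace(sp, baseline_rate_Hz=rate, suppression_train_ms=0.0,
                            pre_window_ms=2000.0, post_window_ms=100.0),
                    int(trace_seeds[4]))
            cells.append(cell)
    return cells
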