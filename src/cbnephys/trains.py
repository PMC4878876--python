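"""Phasic/tonic decomposition of evoked 100-Hz trains and standing-current
measurements.

During a train the synaptic current evoked by each stimulus ("phasic", P_n)
sums with the residual current left from earlier stimuli ("tonic", T_n).
The decomposition measures, per stimulus n:

* T_n: current 8.4 ms after stimulus onset, baseline-subtracted (T_0 = 0);
* peak_n: maximum current in the post-artifact peak window, baseline-
  subtracted;
* P_n = peak_n - T_{n-1}.

Both are reported raw (pA) and normalized to the first phasic amplitude (%).
Baseline is the mean current over the 50 ms preceding the first stimulus.

The module also provides the group-level mGluR contribution (difference in
mean tonic current for stimuli 5-10 between mGluR-antagonist and control
conditions), holding-current mean/variance, and voltage-ramp difference
currents (transporter-induced and mGluR-antagonist-sensitive components).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (EmptyGroup, ProtocolMismatch, StimulusOutsideTrace,
                     TooFewStimuli, UnevokedTrace, WindowTooShort)
from .stats import GroupDifference, unpaired_difference
from .trace import Trace

TONIC_LATENCY_MS = 8.4
#: median half-window around the tonic measurement point
TONIC_HALF_WINDOW_MS = 0.2
BASELINE_WINDOW_MS = 50.0
PEAK_SEARCH_END_MS = 3.5
#: P_1 must exceed this many baseline SDs, else the trace is unevoked
NOISE_FLOOR_SDS = 5.0


@dataclass
class TrainDecomposition:
    """Per-stimulus phasic and tonic currents of one evoked train."""

    baseline_pA: float
    peak_pA: np.ndarray
    phasic_pA: np.ndarray
    tonic_pA: np.ndarray
    measurement_latency_ms: float = TONIC_LATENCY_MS

    @property
    def n_stimuli(self) -> int:
        return self.phasic_pA.size

    @property
    def phasic_pct(self) -> np.ndarray:
        return 100.0 * self.phasic_pA / self.phasic_pA[0]

    @property
    def tonic_pct(self) -> np.ndarray:
        return 100.0 * self.tonic_pA / self.phasic_pA[0]

    @property
    def peak_pct(self) -> np.ndarray:
        return 100.0 * self.peak_pA / self.peak_pA[0]


def measure_train(
    trace: Trace,
    stim_times_ms: Sequence[float] | None = None,
    latency_ms: float = TONIC_LATENCY_MS,
    baseline_window_ms: float = BASELINE_WINDOW_MS,
) -> TrainDecomposition:
    """Decompose an evoked train into per-stimulus phasic and tonic currents.

    Stimulus times default to the trace annotations.  The peak of stimulus n
    is searched in (t_n + artifact_blank, t_n + 3.5] ms; the tonic current is
    the median over +-0.2 ms around t_n + 8.4 ms, baseline-subtracted.

    Raises :class:`UnevokedTrace` when the first phasic amplitude does not
    exceed the baseline noise floor, :class:`StimulusOutsideTrace` when a
    measurement point falls outside the recording.
    """
    stims = np.asarray(stim_times_ms if stim_times_ms is not None
                       else trace.stim_times_ms, dtype=float)
    if stims.size == 0:
        raise TooFewStimuli("no stimulus times supplied")
    if stims.size > 1:
        isi = np.diff(stims)
        if np.ptp(isi) > 1e-6 * np.mean(isi) + 1e-9:
            raise ValueError("stimulus times must be uniformly spaced")
        if latency_ms >= float(np.mean(isi)) + trace.sample_interval_ms:
            raise StimulusOutsideTrace(
                "tonic measurement latency exceeds the inter-stimulus interval")
    if stims[0] < baseline_window_ms:
        raise WindowTooShort(
            f"need >= {baseline_window_ms} ms of pre-stimulus baseline")
    if latency_ms <= trace.artifact_blank_ms:
        raise StimulusOutsideTrace(
            "tonic measurement point falls inside the artifact blank")
    if stims[-1] + latency_ms + TONIC_HALF_WINDOW_MS > trace.duration_ms:
        raise StimulusOutsideTrace("trace ends before the last measurement point")

    base_samples = trace.slice(stims[0] - baseline_window_ms, stims[0])
    baseline = float(np.mean(base_samples))
    baseline_sd = float(np.std(base_samples, ddof=1)) if base_samples.size > 1 else 0.0

    time = trace.time_ms
    blank_mask = trace.artifact_mask()
    n = stims.size
    peaks = np.empty(n)
    tonic = np.empty(n)
    for i, t_n in enumerate(stims):
        sel = (time > t_n + trace.artifact_blank_ms) & \
              (time <= t_n + PEAK_SEARCH_END_MS) & ~blank_mask
        if not np.any(sel):
            raise WindowTooShort(f"empty peak window for stimulus {i + 1}")
        peaks[i] = float(np.max(trace.values[sel])) - baseline
        tonic[i] = trace.value_at(t_n + latency_ms, TONIC_HALF_WINDOW_MS) - baseline

    phasic = np.empty(n)
    phasic[0] = peaks[0]
    phasic[1:] = peaks[1:] - tonic[:-1]
    if phasic[0] < NOISE_FLOOR_SDS * baseline_sd:
        raise UnevokedTrace(
            f"first phasic amplitude {phasic[0]:.1f} pA below the noise floor "
            f"({NOISE_FLOOR_SDS} x {baseline_sd:.1f} pA)")
    return TrainDecomposition(
        baseline_pA=baseline, peak_pA=peaks, phasic_pA=phasic, tonic_pA=tonic,
        measurement_latency_ms=latency_ms,
    )


def mean_tonic_5_10(d: TrainDecomposition) -> float:
    """Mean tonic current over stimuli 5-10 inclusive, in % of P_1."""
    if d.n_stimuli < 10:
        raise TooFewStimuli(f"need >= 10 stimuli, got {d.n_stimuli}")
    return float(np.mean(d.tonic_pct[4:10]))


def steady_state_depression(d: TrainDecomposition, n_last: int = 5) -> float:
    """Mean of the last ``n_last`` peak amplitudes in % of the first peak
    (the steady-state train amplitude metric, used for EPSC trains)."""
    if d.n_stimuli < n_last + 1:
        raise TooFewStimuli(f"need > {n_last} stimuli, got {d.n_stimuli}")
    return float(np.mean(d.peak_pct[-n_last:]))


def mglur_tonic_difference(
    control: Sequence[TrainDecomposition],
    drug: Sequence[TrainDecomposition],
) -> GroupDifference:
    """Group-level mGluR contribution to the tonic current.

    The mean tonic current for stimuli 5-10 is computed per cell in each
    condition; the returned difference is antagonist minus control, so a
    positive value is the outward tonic current unmasked when the mGluR
    inward component is blocked.  Conditions are treated as unpaired groups
    with SEMs combined in quadrature.
    """
    if len(control) == 0 or len(drug) == 0:
        raise EmptyGroup("both conditions need at least one cell")
    a = np.array([mean_tonic_5_10(d) for d in drug])
    b = np.array([mean_tonic_5_10(d) for d in control])
    return unpaired_difference(
        float(np.mean(a)), _sem(a), a.size,
        float(np.mean(b)), _sem(b), b.size,
        label_A="cpccoet", label_B="control",
    )


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0


def holding_current_stats(trace: Trace, window_ms: tuple[float, float],
                          min_samples: int = 10) -> tuple[float, float]:
    """Mean and sample variance (pA, pA^2) of the current in a quiet window."""
    samples = trace.slice(*window_ms)
    if samples.size < min_samples:
        raise WindowTooShort(f"holding window has {samples.size} samples")
    return float(np.mean(samples)), float(np.var(samples, ddof=1))


# ----------------------------------------------------------------------
# voltage ramps
# ----------------------------------------------------------------------
@dataclass
class RampProtocol:
    """Step-then-ramp voltage-clamp protocol.

    From the holding potential the cell is stepped to ``step_mV`` for
    ``step_ms`` and then ramped linearly to ``ramp_end_mV`` over ``ramp_ms``.
    """

    hold_mV: float = -40.0
    hold_ms: float = 50.0
    step_mV: float = -20.0
    step_ms: float = 100.0
    ramp_end_mV: float = -80.0
    ramp_ms: float = 250.0
    tail_ms: float = 50.0
    sample_interval_ms: float = 0.02

    @property
    def duration_ms(self) -> float:
        return self.hold_ms + self.step_ms + self.ramp_ms + self.tail_ms

    def time_ms(self) -> np.ndarray:
        return np.arange(int(round(self.duration_ms / self.sample_interval_ms))) \
            * self.sample_interval_ms

    def voltage_mV(self, t_ms: np.ndarray | None = None) -> np.ndarray:
        t = self.time_ms() if t_ms is None else np.asarray(t_ms, dtype=float)
        v = np.full(t.shape, self.hold_mV)
        t0 = self.hold_ms
        t1 = t0 + self.step_ms
        t2 = t1 + self.ramp_ms
        v[(t >= t0) & (t < t1)] = self.step_mV
        ramp = (t >= t1) & (t < t2)
        v[ramp] = self.step_mV + (self.ramp_end_mV - self.step_mV) * (t[ramp] - t1) / self.ramp_ms
        v[t >= t2] = self.hold_mV
        return v

    def ramp_grid(self, grid_ms: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
        """(times, voltages) at grid_ms spacing across the ramp segment."""
        t1 = self.hold_ms + self.step_ms
        times = np.arange(t1, t1 + self.ramp_ms + grid_ms / 2, grid_ms)
        times = times[times <= t1 + self.ramp_ms]
        return times, self.voltage_mV(times)

    def describe(self) -> dict:
        return {
            "hold_mV": self.hold_mV, "hold_ms": self.hold_ms,
            "step_mV": self.step_mV, "step_ms": self.step_ms,
            "ramp_end_mV": self.ramp_end_mV, "ramp_ms": self.ramp_ms,
        }


@dataclass
class RampCurrents:
    """Ramp currents per condition on a common voltage grid, and the
    pointwise difference currents."""

    time_ms: np.ndarray
    voltage_mV: np.ndarray
    current_control: np.ndarray
    current_tboa: np.ndarray
    current_tboa_antagonist: np.ndarray
    transporter_induced: np.ndarray = field(init=False)
    antagonist_sensitive: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.voltage_mV, self.current_control,
                                    self.current_tboa, self.current_tboa_antagonist)}
        if len(shapes) != 1:
            raise ProtocolMismatch("ramp currents do not share the voltage grid")
        # control minus TBOA: current suppressed by intact glutamate transport
        self.transporter_induced = self.current_control - self.current_tboa
        # TBOA minus (TBOA + mGluR1/5 antagonist): mGluR-dependent component
        self.antagonist_sensitive = self.current_tboa - self.current_tboa_antagonist


def _average_sweeps(traces: Trace | Sequence[Trace]) -> Trace:
    if isinstance(traces, Trace):
        return traces
    if len(traces) == 0:
        raise EmptyGroup("condition supplies no sweeps")
    if len({t.n_samples for t in traces}) != 1:
        raise ProtocolMismatch("sweeps differ in length")
    first = traces[0]
    mean = np.mean(np.stack([t.values for t in traces]), axis=0)
    return Trace(values=mean, sample_interval_ms=first.sample_interval_ms,
                 mode=first.mode, units=first.units, meta=dict(first.meta))


def ramp_difference_currents(
    control: Trace | Sequence[Trace],
    tboa: Trace | Sequence[Trace],
    tboa_antagonist: Trace | Sequence[Trace],
    protocol: RampProtocol,
    grid_ms: float = 4.0,
) -> RampCurrents:
    """Average sweeps per condition and compute ramp difference currents.

    Currents are resampled on a ``grid_ms`` grid across the ramp segment
    (mean over +-grid/2 around each grid point) and differenced pointwise.
    """
    conds = [_average_sweeps(c) for c in (control, tboa, tboa_antagonist)]
    for c in conds:
        ramp_meta = c.meta.get("ramp")
        if ramp_meta is not None and ramp_meta != protocol.describe():
            raise ProtocolMismatch("trace recorded under a different ramp protocol")
        if c.n_samples != int(round(protocol.duration_ms / protocol.sample_interval_ms)):
            raise ProtocolMismatch("trace length does not match the protocol")
    times, volts = protocol.ramp_grid(grid_ms)
    sampled = []
    for c in conds:
        vals = [np.mean(c.slice(max(t - grid_ms / 2, 0.0),
                                min(t + grid_ms / 2, c.duration_ms)))
                for t in times]
        sampled.append(np.asarray(vals))
    return RampCurrents(time_ms=times, voltage_mV=volts,
                        current_control=sampled[0], current_tboa=sampled[1],
                        current_tboa_antagonist=sampled[2])
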