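"""Spike detection and firing metrics for current-clamp recordings.

Metrics: spontaneous firing rate, action-potential half-width, the
post-inhibitory rebound percent change (firing rate over the 300 ms after a
500-ms inhibitory train relative to the 500 ms before it), and the paired
mGluR-dependent component of the rebound (cell-by-cell control minus
antagonist difference).

Spike detection: an upward crossing of dV/dt >= 20 mV/ms followed by a peak
reaching at least -20 mV within 2 ms, with a 1-ms refractory period between
accepted peaks.  Both thresholds are standard for high-rate cerebellar
neurons and are exposed as arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (InsufficientWindow, NotCurrentClamp, TooFewSpikes,
                     UnpairedInput, ZeroPreRate)
from .trace import CURRENT_CLAMP, Trace

DVDT_THRESHOLD_mV_PER_MS = 20.0
PEAK_MIN_mV = -20.0
PEAK_SEARCH_MS = 2.0
REFRACTORY_MS = 1.0
PRE_WINDOW_MS = 500.0
POST_WINDOW_MS = 300.0


@dataclass
class SpikeTrainMetrics:
    """Firing metrics of one cell under one condition."""

    spike_times_ms: np.ndarray
    spontaneous_rate_Hz: float | None = None
    ap_half_width_ms: float | None = None
    pre_rate_Hz: float | None = None
    post_rate_Hz: float | None = None
    percent_change: float | None = None
    condition: str = "control"


def detect_spikes(
    trace: Trace,
    dvdt_threshold: float = DVDT_THRESHOLD_mV_PER_MS,
    peak_min_mV: float = PEAK_MIN_mV,
    refractory_ms: float = REFRACTORY_MS,
) -> np.ndarray:
    """Detect action potentials; returns peak times in ms.

    Candidate onsets are upward crossings of the dV/dt threshold; a
    candidate is accepted if the voltage reaches ``peak_min_mV`` within 2 ms,
    and peaks closer than the refractory period to the previous accepted
    peak are discarded.
    """
    if trace.mode != CURRENT_CLAMP:
        raise NotCurrentClamp(f"spike detection needs a current-clamp trace, got {trace.mode}")
    dt = trace.sample_interval_ms
    v = trace.values
    dvdt = np.gradient(v, dt)
    above = dvdt >= dvdt_threshold
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    search = max(int(round(PEAK_SEARCH_MS / dt)), 1)
    peak_times = []
    last_peak = -np.inf
    for i in onsets:
        seg = v[i:i + search + 1]
        if seg.size == 0:
            continue
        j = int(np.argmax(seg))
        if seg[j] < peak_min_mV:
            continue
        t_peak = (i + j) * dt
        if t_peak - last_peak < refractory_ms:
            continue
        peak_times.append(t_peak)
        last_peak = t_peak
    return np.asarray(peak_times)


def spontaneous_rate(spike_times_ms: Sequence[float] | np.ndarray,
                     window_ms: tuple[float, float]) -> float:
    """Firing rate (Hz) as spike count over window duration; window >= 1 s."""
    t0, t1 = window_ms
    if t1 - t0 < 1000.0:
        raise InsufficientWindow("spontaneous rate needs a window of >= 1 s")
    return _rate(np.asarray(spike_times_ms), t0, t1)


def _rate(spikes: np.ndarray, t0: float, t1: float) -> float:
    count = int(np.sum((spikes >= t0) & (spikes < t1)))
    return 1000.0 * count / (t1 - t0)


def ap_half_width(trace: Trace, spike_times_ms: Sequence[float] | np.ndarray,
                  dvdt_threshold: float = DVDT_THRESHOLD_mV_PER_MS,
                  min_spikes: int = 10) -> float:
    """Mean action-potential width (ms) at half amplitude.

    Amplitude is measured from the dV/dt-threshold voltage (spike onset) to
    the peak; the width is the time between the upward and downward
    crossings of the half-amplitude level, with linear interpolation between
    samples.
    """
    if trace.mode != CURRENT_CLAMP:
        raise NotCurrentClamp("half-width needs a current-clamp trace")
    spikes = np.asarray(spike_times_ms, dtype=float)
    if spikes.size < min_spikes:
        raise TooFewSpikes(f"half-width needs >= {min_spikes} spikes, got {spikes.size}")
    dt = trace.sample_interval_ms
    v = trace.values
    dvdt = np.gradient(v, dt)
    widths = []
    back = int(round(PEAK_SEARCH_MS / dt))
    for ts in spikes:
        p = int(round(ts / dt))
        if not 0 < p < v.size - 1:
            continue
        # onset: last threshold crossing of dV/dt before the peak
        lo = max(p - back, 1)
        seg = dvdt[lo:p + 1]
        idx = np.flatnonzero(seg >= dvdt_threshold)
        if idx.size == 0:
            continue
        onset = lo + idx[0]
        v_thr = v[onset]
        half = v_thr + 0.5 * (v[p] - v_thr)
        t_up = _cross_time(v, half, p, -1, dt)
        t_down = _cross_time(v, half, p, +1, dt)
        if t_up is not None and t_down is not None:
            widths.append(t_down - t_up)
    if len(widths) < min_spikes:
        raise TooFewSpikes(f"only {len(widths)} measurable spikes")
    return float(np.mean(widths))


def _cross_time(v: np.ndarray, level: float, peak: int, direction: int,
                dt: float) -> float | None:
    """Time where v crosses ``level`` walking from the peak; interpolated."""
    i = peak
    limit = v.size - 1 if direction > 0 else 0
    while i != limit:
        j = i + direction
        if v[j] <= level <= v[i] or v[i] <= level <= v[j]:
            if v[j] == v[i]:
                return i * dt
            frac = (level - v[i]) / (v[j] - v[i])
            return (i + direction * abs(frac)) * dt
        i = j
        if abs(i - peak) * dt > 5.0:   # give up far from the peak
            return None
    return None


def rebound_percent_change(
    trace: Trace,
    train_onset_ms: float,
    train_end_ms: float,
    pre_window_ms: float = PRE_WINDOW_MS,
    post_window_ms: float = POST_WINDOW_MS,
    spike_times_ms: np.ndarray | None = None,
) -> SpikeTrainMetrics:
    """Percent change of firing rate after an inhibitory train.

    pre window = [onset - 500, onset), post window = [end, end + 300);
    percent change = 100 * (post - pre) / pre.  Spikes are detected unless
    supplied.
    """
    if train_onset_ms - pre_window_ms < 0:
        raise InsufficientWindow("trace starts less than the pre window before the train")
    if train_end_ms + post_window_ms > trace.duration_ms:
        raise InsufficientWindow("trace ends less than the post window after the train")
    spikes = detect_spikes(trace) if spike_times_ms is None \
        else np.asarray(spike_times_ms, dtype=float)
    pre = _rate(spikes, train_onset_ms - pre_window_ms, train_onset_ms)
    post = _rate(spikes, train_end_ms, train_end_ms + post_window_ms)
    if pre <= 0:
        raise ZeroPreRate("pre-stimulus rate is zero; percent change undefined")
    return SpikeTrainMetrics(
        spike_times_ms=spikes, pre_rate_Hz=pre, post_rate_Hz=post,
        percent_change=100.0 * (post - pre) / pre,
    )


def mglur_rebound_component(
    control: dict[str, float],
    drug: dict[str, float],
) -> tuple[float, float, np.ndarray]:
    """Paired mGluR-dependent component of the rebound rate increase.

    ``control`` and ``drug`` map cell id -> rebound percent change under
    control and mGluR-antagonist conditions.  Returns (mean, SEM, per-cell
    differences) of control - drug over cells present in both.
    """
    if set(control) != set(drug):
        raise UnpairedInput("control and drug conditions cover different cells")
    if not control:
        raise UnpairedInput("no paired cells supplied")
    cells = sorted(control)
    diffs = np.array([control[c] - drug[c] for c in cells])
    semv = float(np.std(diffs, ddof=1) / np.sqrt(diffs.size)) if diffs.size > 1 else 0.0
    return float(np.mean(diffs)), semv, diffs
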