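"""Biexponential IPSC decay fitting and the weighted decay time constant.

The decay phase of an IPSC is modelled as

    I(t) = baseline + A * [F_f * exp(-t/tau_f) + F_s * exp(-t/tau_s)]

with t measured from the fit reference (the IPSC peak), F_f + F_s = 1 and
tau_f <= tau_s.  The summary kinetic parameter is the weighted time constant

    tau_w = F_f * tau_f + F_s * tau_s,

i.e. each time constant scaled by its fractional contribution to the total
amplitude.  Fits whose two time constants converge (within 5%) or whose minor
fraction falls below 0.02 are collapsed to a single exponential with
frac_fast = 1.

Initialization follows the classical peeling scheme: a log-linear regression
on the tail of the window seeds the slow component, the slow component is
subtracted, and a second log-linear regression on the early residual seeds
the fast component.  The optimizer restarts from perturbed seeds before
declaring :class:`~cbnephys.errors.NonConvergence`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import NoDecay, NonConvergence, WindowTooShort
from .trace import Trace

TAU_BOUNDS_MS = (0.1, 100.0)
#: relative tau separation below which the fit collapses to one exponential
TAU_MERGE_REL = 0.05
FRAC_COLLAPSE = 0.02
MIN_SAMPLES = 30


@dataclass
class BiexpFit:
    """Result of a biexponential decay fit.

    Amplitude is outward-positive and referenced at ``t_ref_ms`` (the IPSC
    peak time within the source trace); fractions sum to one.
    """

    baseline_pA: float
    amplitude_pA: float
    tau_fast_ms: float
    tau_slow_ms: float
    frac_fast: float
    frac_slow: float
    weighted_tau_ms: float
    fit_rmse_pA: float
    fit_window_ms: tuple[float, float]
    t_ref_ms: float = 0.0
    single_exponential: bool = False

    def __post_init__(self) -> None:
        if abs(self.frac_fast + self.frac_slow - 1.0) > 1e-9:
            raise ValueError("frac_fast + frac_slow must equal 1")
        if not 0 < self.tau_fast_ms <= self.tau_slow_ms:
            raise ValueError("require 0 < tau_fast <= tau_slow")

    @classmethod
    def from_parameters(cls, tau_fast_ms: float, tau_slow_ms: float,
                        frac_fast: float, amplitude_pA: float = 1.0,
                        baseline_pA: float = 0.0) -> "BiexpFit":
        """Construct a fit object directly from known decay parameters."""
        if tau_fast_ms > tau_slow_ms:
            tau_fast_ms, tau_slow_ms = tau_slow_ms, tau_fast_ms
            frac_fast = 1.0 - frac_fast
        return cls(
            baseline_pA=baseline_pA, amplitude_pA=amplitude_pA,
            tau_fast_ms=tau_fast_ms, tau_slow_ms=tau_slow_ms,
            frac_fast=frac_fast, frac_slow=1.0 - frac_fast,
            weighted_tau_ms=frac_fast * tau_fast_ms + (1 - frac_fast) * tau_slow_ms,
            fit_rmse_pA=0.0, fit_window_ms=(0.0, 0.0),
            single_exponential=tau_fast_ms == tau_slow_ms or frac_fast in (0.0, 1.0),
        )

    def decay(self, t_ms: np.ndarray | float) -> np.ndarray | float:
        """Unit-amplitude decay value(s) at time t after the reference."""
        return self.frac_fast * np.exp(-np.asarray(t_ms) / self.tau_fast_ms) + \
            self.frac_slow * np.exp(-np.asarray(t_ms) / self.tau_slow_ms)


def weighted_tau(fit: BiexpFit) -> float:
    """F_fast*tau_fast + F_slow*tau_slow, in ms."""
    return fit.frac_fast * fit.tau_fast_ms + fit.frac_slow * fit.tau_slow_ms


def _model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    b, a_f, tau_f, a_s, tau_s = params
    return b + a_f * np.exp(-t / tau_f) + a_s * np.exp(-t / tau_s)


def _loglinear_tau(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope-based (tau, amplitude-at-0) seed from log-linear regression."""
    pos = y > 0
    if pos.sum() < 3:
        return np.nan, np.nan
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    if slope >= 0:
        return np.nan, np.nan
    return -1.0 / slope, float(np.exp(intercept))


def _seed(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Peeling initialization: tail regression seeds the slow component,
    its subtraction seeds the fast one."""
    b0 = float(np.min(y))
    yc = y - b0
    span = t[-1] - t[0]
    tail = t >= t[0] + 2 * span / 3
    tau_s, a_s = _loglinear_tau(t[tail] - t[0], yc[tail])
    if not np.isfinite(tau_s):
        tau_s, a_s = max(span / 2, 1.0), max(yc[0] * 0.3, 1e-6)
    resid = yc - a_s * np.exp(-(t - t[0]) / tau_s)
    head = t <= t[0] + span / 3
    tau_f, a_f = _loglinear_tau(t[head] - t[0], resid[head])
    if not np.isfinite(tau_f) or tau_f >= tau_s:
        tau_f, a_f = tau_s / 3, max(yc[0] - a_s, 1e-6)
    lo, hi = TAU_BOUNDS_MS
    return np.array([b0, max(a_f, 1e-6), np.clip(tau_f, lo, hi),
                     max(a_s, 1e-6), np.clip(tau_s, lo, hi)])


def fit_biexponential(
    trace: Trace,
    decay_window: tuple[float, float],
    t_ref_ms: float | None = None,
    max_restarts: int = 3,
    fixed_baseline_pA: float | None = None,
) -> BiexpFit:
    """Fit baseline + A*(F_f e^{-t/tau_f} + F_s e^{-t/tau_s}) to a decay phase.

    Parameters
    ----------
    decay_window : (start_ms, end_ms) within the trace; should begin at or
        after the IPSC peak and avoid artifact-blanked samples.
    t_ref_ms : time origin for the exponentials; defaults to the window
        start.  Amplitudes and fractions are referenced here.
    fixed_baseline_pA : pin the baseline to a known value (e.g. the
        pre-stimulus holding current) instead of fitting it.  Over windows
        much shorter than the slow time constant a free baseline is nearly
        collinear with the slow component, so pinning it when it is known
        greatly improves conditioning.

    Raises
    ------
    WindowTooShort, NoDecay, NonConvergence
    """
    t0, t1 = decay_window
    if t_ref_ms is None:
        t_ref_ms = t0
    mask = ~trace.artifact_mask()
    time = trace.time_ms
    sel = (time >= t0 - 1e-9) & (time <= t1 + 1e-9) & mask
    t = time[sel] - t_ref_ms
    y = trace.values[sel]
    if t.size < MIN_SAMPLES:
        raise WindowTooShort(f"decay window has {t.size} samples (< {MIN_SAMPLES})")
    third = t.size // 3
    if np.mean(y[:third]) <= np.mean(y[-third:]):
        raise NoDecay("signal does not decrease over the decay window")

    seed = _seed(t, y)
    if fixed_baseline_pA is not None:
        seed[0] = fixed_baseline_pA
    lo, hi = TAU_BOUNDS_MS
    span = float(np.ptp(y))
    fixed = fixed_baseline_pA is not None
    if fixed:
        bounds = (np.array([0.0, lo, 0.0, lo]),
                  np.array([100 * span, hi, 100 * span, hi]))

        def residual(p):
            return _model(np.concatenate([[fixed_baseline_pA], p]), t) - y

        full_seed = seed[1:]
    else:
        bounds = (
            np.array([np.min(y) - 10 * span, 0.0, lo, 0.0, lo]),
            np.array([np.max(y) + 10 * span, 100 * span, hi, 100 * span, hi]),
        )

        def residual(p):
            return _model(p, t) - y

        full_seed = seed
    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_restarts + 1):
        x0 = full_seed if attempt == 0 else full_seed * rng.lognormal(0.0, 0.3, full_seed.size)
        x0 = np.clip(x0, bounds[0] + 1e-12, bounds[1] - 1e-12)
        res = least_squares(residual, x0, bounds=bounds,
                            method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if res.success and (best is None or res.cost < best.cost):
            best = res
        if best is not None and best.cost <= (1e-12 * max(span, 1.0)) ** 2 * t.size:
            break
    if best is None:
        raise NonConvergence("biexponential fit failed after restarts")

    x = np.concatenate([[fixed_baseline_pA], best.x]) if fixed else best.x
    b, a_f, tau_f, a_s, tau_s = x
    if tau_f > tau_s:
        a_f, a_s, tau_f, tau_s = a_s, a_f, tau_s, tau_f
    amp = a_f + a_s
    frac_f = a_f / amp if amp > 0 else 1.0
    rmse = float(np.sqrt(np.mean((_model(x, t) - y) ** 2)))

    # degenerate case: effectively a single exponential
    if tau_s - tau_f <= TAU_MERGE_REL * tau_s or min(frac_f, 1 - frac_f) < FRAC_COLLAPSE:
        tau, b, amp, rmse = _fit_single(t, y, seed, fixed_baseline_pA)
        return BiexpFit(
            baseline_pA=b, amplitude_pA=amp, tau_fast_ms=tau, tau_slow_ms=tau,
            frac_fast=1.0, frac_slow=0.0, weighted_tau_ms=tau,
            fit_rmse_pA=rmse, fit_window_ms=(t0, t1), t_ref_ms=t_ref_ms,
            single_exponential=True,
        )
    return BiexpFit(
        baseline_pA=float(b), amplitude_pA=float(amp),
        tau_fast_ms=float(tau_f), tau_slow_ms=float(tau_s),
        frac_fast=float(frac_f), frac_slow=float(1 - frac_f),
        weighted_tau_ms=float(frac_f * tau_f + (1 - frac_f) * tau_s),
        fit_rmse_pA=rmse, fit_window_ms=(t0, t1), t_ref_ms=t_ref_ms,
    )


def fit_ipsc(
    trace: Trace,
    stim_index: int = 0,
    peak_offset_ms: float = 0.2,
    peak_search_end_ms: float = 3.5,
    tail_window_ms: float = 40.0,
    baseline_window_ms: float = 50.0,
    pin_baseline: bool | None = None,
) -> BiexpFit:
    """Locate and fit the decay of the IPSC evoked by one stimulus.

    The peak is found after the artifact blank within ``peak_search_end_ms``
    of the stimulus; the decay window runs from 0.2 ms after the peak to the
    next stimulus minus the artifact blank, or — for the last (or an
    isolated) IPSC — up to ``tail_window_ms`` into the post-train tail,
    where the long window makes the slow component well conditioned.

    For the first stimulus the baseline defaults to the measured
    pre-stimulus mean (pinned); within a train the local baseline is the
    unknown residual tonic current, so it is fitted freely.  Override with
    ``pin_baseline``.  The fit is referenced at the peak time.
    """
    stims = np.asarray(trace.stim_times_ms, dtype=float)
    if not 0 <= stim_index < stims.size:
        raise IndexError(f"stimulus index {stim_index} outside 0..{stims.size - 1}")
    t_n = stims[stim_index]
    time = trace.time_ms
    sel = (time > t_n + trace.artifact_blank_ms) & \
          (time <= t_n + peak_search_end_ms) & ~trace.artifact_mask()
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise WindowTooShort(f"no samples in peak window of stimulus {stim_index}")
    t_pk = float(time[idx[np.argmax(trace.values[idx])]])
    if stim_index + 1 < stims.size:
        end = float(stims[stim_index + 1]) - trace.artifact_blank_ms
    else:
        end = min(t_n + tail_window_ms, trace.duration_ms)
    if pin_baseline is None:
        pin_baseline = stim_index == 0 and stims[0] >= baseline_window_ms
    fixed = None
    if pin_baseline:
        if stims[0] < baseline_window_ms:
            raise WindowTooShort("not enough pre-stimulus data to pin the baseline")
        fixed = float(np.mean(trace.slice(stims[0] - baseline_window_ms, stims[0])))
    return fit_biexponential(trace, (t_pk + peak_offset_ms, end), t_ref_ms=t_pk,
                             fixed_baseline_pA=fixed)


def _fit_single(t, y, seed, fixed_baseline_pA=None) -> tuple[float, float, float, float]:
    """Single-exponential fallback fit; returns (tau, baseline, amp, rmse)."""
    span = float(np.ptp(y))
    lo, hi = TAU_BOUNDS_MS
    if fixed_baseline_pA is not None:
        def model(p):
            return fixed_baseline_pA + p[0] * np.exp(-t / p[1])

        x0 = np.array([seed[1] + seed[3], min(max(seed[2], seed[4]), hi - 1)])
        bounds = (np.array([0.0, lo]), np.array([100 * span, hi]))
    else:
        def model(p):
            return p[0] + p[1] * np.exp(-t / p[2])

        x0 = np.array([seed[0], seed[1] + seed[3], min(max(seed[2], seed[4]), hi - 1)])
        bounds = (np.array([np.min(y) - 10 * span, 0.0, lo]),
                  np.array([np.max(y) + 10 * span, 100 * span, hi]))
    res = least_squares(lambda p: model(p) - y, np.clip(x0, bounds[0], bounds[1]),
                        bounds=bounds, method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success:
        raise NonConvergence("single-exponential fallback failed")
    rmse = float(np.sqrt(np.mean((model(res.x) - y) ** 2)))
    if fixed_baseline_pA is not None:
        return float(res.x[1]), float(fixed_baseline_pA), float(res.x[0]), rmse
    return float(res.x[2]), float(res.x[0]), float(res.x[1]), rmse
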