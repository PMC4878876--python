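"""Uniformly sampled recording with stimulus annotations.

A :class:`Trace` is the universal input to every analysis stage: a current
recording in pA (voltage clamp) or a voltage recording in mV (current clamp),
with the sampling interval, stimulus times, and an artifact-blank width that
marks samples immediately after each stimulus as unusable.

On-disk format is a plain CSV (``time_ms,value``) plus a JSON sidecar holding
the metadata (mode, units, stimulus times, blank width, free-form ``meta`` and
any generator ground truth).  The sidecar lives next to the CSV with the same
stem and a ``.json`` suffix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import StimulusOutsideTrace, WindowTooShort

VOLTAGE_CLAMP = "voltage_clamp"
CURRENT_CLAMP = "current_clamp"


@dataclass
class Trace:
    values: np.ndarray
    sample_interval_ms: float
    mode: str = VOLTAGE_CLAMP
    units: str = "pA"
    stim_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    artifact_blank_ms: float = 0.0
    meta: dict = field(default_factory=dict)
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.stim_times_ms = np.asarray(self.stim_times_ms, dtype=float)
        if self.sample_interval_ms <= 0:
            raise ValueError("sample_interval_ms must be positive")
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.sample_interval_ms

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_interval_ms

    def index_at(self, t_ms: float) -> int:
        """Index of the sample nearest ``t_ms``; errors outside the trace."""
        if not 0.0 <= t_ms <= self.duration_ms:
            raise StimulusOutsideTrace(f"time {t_ms} ms outside trace of {self.duration_ms} ms")
        return min(int(round(t_ms / self.sample_interval_ms)), self.n_samples - 1)

    def slice(self, t0_ms: float, t1_ms: float) -> np.ndarray:
        """Samples with t0 <= t < t1 (t0 inclusive, t1 exclusive)."""
        i0 = max(int(np.ceil(t0_ms / self.sample_interval_ms - 1e-9)), 0)
        i1 = min(int(np.ceil(t1_ms / self.sample_interval_ms - 1e-9)), self.n_samples)
        if i1 <= i0:
            raise WindowTooShort(f"window [{t0_ms}, {t1_ms}) ms contains no samples")
        return self.values[i0:i1]

    def value_at(self, t_ms: float, half_window_ms: float = 0.0) -> float:
        """Signal value at ``t_ms``; median over ±half_window if requested."""
        if half_window_ms <= 0:
            return float(self.values[self.index_at(t_ms)])
        lo = max(t_ms - half_window_ms, 0.0)
        hi = min(t_ms + half_window_ms, self.duration_ms)
        return float(np.median(self.slice(lo, hi + self.sample_interval_ms / 2)))

    def artifact_mask(self) -> np.ndarray:
        """Boolean mask, True for samples inside a stimulus-artifact blank."""
        mask = np.zeros(self.n_samples, dtype=bool)
        if self.artifact_blank_ms <= 0:
            return mask
        dt = self.sample_interval_ms
        for t in self.stim_times_ms:
            i0 = max(int(np.ceil(t / dt - 1e-9)), 0)
            i1 = min(int(np.ceil((t + self.artifact_blank_ms) / dt - 1e-9)), self.n_samples)
            mask[i0:i1] = True
        return mask

    # ------------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write ``time_ms,value`` CSV and the JSON metadata sidecar."""
        path = Path(path)
        data = np.column_stack([self.time_ms, self.values])
        with open(path, "w") as fh:
            fh.write(f"# units={self.units} mode={self.mode} sample_interval_ms={self.sample_interval_ms}\n")
            fh.write("time_ms,value\n")
            np.savetxt(fh, data, fmt="%.17g", delimiter=",")
        sidecar = {
            "mode": self.mode,
            "units": self.units,
            "sample_interval_ms": self.sample_interval_ms,
            "stim_times_ms": self.stim_times_ms.tolist(),
            "artifact_blank_ms": self.artifact_blank_ms,
            "meta": _jsonable(self.meta),
            "ground_truth": _jsonable(self.ground_truth),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trace":
        import pandas as pd

        path = Path(path)
        frame = pd.read_csv(path, comment="#")
        if not {"time_ms", "value"} <= set(frame.columns):
            raise ValueError(f"{path}: expected columns time_ms,value")
        data = frame[["time_ms", "value"]].to_numpy(dtype=float)
        side = json.loads(path.with_suffix(".json").read_text())
        return cls(
            values=data[:, 1],
            sample_interval_ms=float(side["sample_interval_ms"]),
            mode=side["mode"],
            units=side["units"],
            stim_times_ms=np.asarray(side["stim_times_ms"], dtype=float),
            artifact_blank_ms=float(side.get("artifact_blank_ms", 0.0)),
            meta=side.get("meta") or {},
            ground_truth=side.get("ground_truth"),
        )


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays so json.dumps accepts them."""
    if obj is None:
        return None
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
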