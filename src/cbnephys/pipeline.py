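"""End-to-end orchestration: generate -> fit -> decompose -> predict -> compare.

:func:`run_pipeline` executes the full synthetic-cohort analysis and writes
per-cell and per-group CSV tables plus a JSON manifest (seed, config hash,
package version), so a run is reproducible from its output directory alone.

The stages can also be driven individually (see :mod:`cbnephys.cli`); the
library functions here operate on in-memory objects and are I/O-free except
for the explicit ``write_outputs`` step.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import CbnEphysError
from .kinetics import fit_ipsc
from .presets import default_presets, load_presets
from .spiking import mglur_rebound_component, rebound_percent_change
from .stats import group_summary
from .synthetic import CohortCell, generate_cohort
from .tonic_model import AS_PRINTED, predict_tonic
from .trains import mean_tonic_5_10, measure_train

log = logging.getLogger("cbnephys.pipeline")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    preset_file: str | None = None
    n_cells_per_group: int = 11
    seed: int = 0
    interpolation_mode: str = AS_PRINTED
    out_dir: str | None = None
    cv: float = 0.3
    run_trains: bool = True       # generate/fit/decompose/predict evoked trains
    run_spiking: bool = True      # rebound protocol and mGluR component

    def __post_init__(self) -> None:
        if not (self.run_trains or self.run_spiking):
            raise ValueError("at least one stage group must be enabled")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """In-memory result of a pipeline run."""

    config: RunConfig
    cells: pd.DataFrame                    # one row per cell x condition
    per_stimulus: pd.DataFrame             # decomposition + prediction rows
    tonic_comparison: pd.DataFrame         # group-level predicted vs measured
    rebound: pd.DataFrame = field(default_factory=pd.DataFrame)
    rebound_components: pd.DataFrame = field(default_factory=pd.DataFrame)
    warnings: list = field(default_factory=list)


def analyze_train_cell(cell: CohortCell, condition: str,
                       mode: str = AS_PRINTED) -> tuple[dict, pd.DataFrame]:
    """Fit, decompose and predict one cell's evoked train.

    Returns a per-cell summary row and the per-stimulus table.
    """
    trace = cell.traces[condition]
    d = measure_train(trace)
    n = d.n_stimuli
    first = fit_ipsc(trace, 0)
    last = fit_ipsc(trace, n - 1)
    pred = predict_tonic(d.phasic_pA, first, last, mode=mode)
    pred_pct = 100.0 * pred.tonic_pA / d.phasic_pA[0]
    row = {
        "cell_id": cell.cell_id, "group": cell.group, "sex": cell.sex,
        "genotype": cell.genotype, "strain": cell.strain, "condition": condition,
        "baseline_pA": d.baseline_pA, "p1_pA": d.phasic_pA[0],
        "weighted_tau_first_ms": first.weighted_tau_ms,
        "weighted_tau_last_ms": last.weighted_tau_ms,
        "mean_tonic_5_10_pct": mean_tonic_5_10(d),
        "mean_predicted_tonic_5_10_pct": float(np.mean(pred_pct[4:10])),
    }
    per_stim = pd.DataFrame({
        "cell_id": cell.cell_id, "group": cell.group, "condition": condition,
        "stimulus": np.arange(1, n + 1),
        "peak_pA": d.peak_pA, "phasic_pA": d.phasic_pA, "tonic_pA": d.tonic_pA,
        "phasic_pct": d.phasic_pct, "tonic_pct": d.tonic_pct,
        "predicted_tonic_pA": pred.tonic_pA, "predicted_tonic_pct": pred_pct,
    })
    return row, per_stim


def analyze_rebound_cell(cell: CohortCell) -> dict:
    """Rebound percent change under both conditions, plus the paired difference."""
    row = {"cell_id": cell.cell_id, "group": cell.group, "sex": cell.sex,
           "genotype": cell.genotype}
    for condition, trace in cell.spiking_traces.items():
        gt = trace.ground_truth
        m = rebound_percent_change(trace, gt["train_onset_ms"], gt["train_end_ms"])
        row[f"pre_rate_{condition}_Hz"] = m.pre_rate_Hz
        row[f"post_rate_{condition}_Hz"] = m.post_rate_Hz
        row[f"percent_change_{condition}"] = m.percent_change
    return row


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages on a freshly generated cohort."""
    presets = (load_presets(config.preset_file) if config.preset_file
               else default_presets())
    cohort = generate_cohort(
        list(presets.values()), config.n_cells_per_group, config.seed,
        cv=config.cv, include_trains=config.run_trains,
        include_spiking=config.run_spiking,
    )
    log.info("generated cohort: %d groups x %d cells (seed %d)",
             len(presets), config.n_cells_per_group, config.seed)

    warnings: list[str] = []
    cell_rows, stim_frames, rebound_rows = [], [], []
    if config.run_trains:
        for cell in cohort:
            for condition in cell.traces:
                try:
                    row, per_stim = analyze_train_cell(
                        cell, condition, config.interpolation_mode)
                except CbnEphysError as exc:
                    warnings.append(f"{cell.cell_id}/{condition}: {exc}")
                    log.warning("rejected %s/%s: %s", cell.cell_id, condition, exc)
                    continue
                cell_rows.append(row)
                stim_frames.append(per_stim)
        log.info("train analysis: %d accepted, %d rejected",
                 len(cell_rows), len(warnings))
    if config.run_spiking:
        for cell in cohort:
            try:
                rebound_rows.append(analyze_rebound_cell(cell))
            except CbnEphysError as exc:
                warnings.append(f"{cell.cell_id}/rebound: {exc}")
                log.warning("rejected %s rebound: %s", cell.cell_id, exc)
        log.info("rebound analysis: %d cells", len(rebound_rows))

    cells = pd.DataFrame(cell_rows)
    per_stimulus = (pd.concat(stim_frames, ignore_index=True)
                    if stim_frames else pd.DataFrame())
    tonic_comparison = _tonic_comparison(cells)
    rebound = pd.DataFrame(rebound_rows)
    rebound_components = _rebound_components(rebound)

    report = RunReport(config=config, cells=cells, per_stimulus=per_stimulus,
                       tonic_comparison=tonic_comparison, rebound=rebound,
                       rebound_components=rebound_components, warnings=warnings)
    if config.out_dir:
        write_outputs(report, Path(config.out_dir))
    return report


def _tonic_comparison(cells: pd.DataFrame) -> pd.DataFrame:
    """Group-level predicted vs measured tonic current (control condition)."""
    if cells.empty:
        return pd.DataFrame()
    ctrl = cells[cells["condition"] == "control"]
    rows = []
    for group, sub in ctrl.groupby("group", sort=True):
        measured = sub["mean_tonic_5_10_pct"].to_numpy()
        predicted = sub["mean_predicted_tonic_5_10_pct"].to_numpy()
        rows.append({
            "group": group, "n": len(sub),
            "measured_tonic_pct": float(np.mean(measured)),
            "measured_sem": float(np.std(measured, ddof=1) / np.sqrt(len(sub))),
            "predicted_tonic_pct": float(np.mean(predicted)),
            "predicted_sem": float(np.std(predicted, ddof=1) / np.sqrt(len(sub))),
            "predicted_minus_measured_pct": float(np.mean(predicted - measured)),
        })
    return pd.DataFrame(rows)


def _rebound_components(rebound: pd.DataFrame) -> pd.DataFrame:
    if rebound.empty or "percent_change_cpccoet" not in rebound.columns:
        return pd.DataFrame()
    rows = []
    for group, sub in rebound.groupby("group", sort=True):
        control = dict(zip(sub["cell_id"], sub["percent_change_control"]))
        drug = dict(zip(sub["cell_id"], sub["percent_change_cpccoet"]))
        mean, sem, _ = mglur_rebound_component(control, drug)
        rows.append({"group": group, "n": len(sub),
                     "mglur_component_pct": mean, "sem": sem})
    return pd.DataFrame(rows)


def write_outputs(report: RunReport, out_dir: Path) -> dict:
    """Write the report tables and a manifest; returns the manifest dict."""
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    tables = {
        "cells.csv": report.cells,
        "per_stimulus.csv": report.per_stimulus,
        "predicted_vs_measured_tonic.csv": report.tonic_comparison,
        "rebound.csv": report.rebound,
        "rebound_mglur_components.csv": report.rebound_components,
    }
    for name, frame in tables.items():
        if frame is None or frame.empty:
            continue
        path = out_dir / name
        frame.to_csv(path, index=False, float_format="%.12g")
        files[name] = len(frame)
    summaries = []
    if not report.cells.empty:
        for metric in ("mean_tonic_5_10_pct", "weighted_tau_first_ms",
                       "weighted_tau_last_ms"):
            summaries.append(group_summary(report.cells, metric))
    if summaries:
        path = out_dir / "group_summary.csv"
        pd.concat(summaries, ignore_index=True).to_csv(
            path, index=False, float_format="%.12g")
        files["group_summary.csv"] = sum(len(s) for s in summaries)
    manifest = {
        "package": "cbnephys",
        "version": __version__,
        "seed": report.config.seed,
        "config": asdict(report.config),
        "config_hash": report.config.digest(),
        "files": files,
        "n_warnings": len(report.warnings),
        "warnings": report.warnings,
        "complete": True,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
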