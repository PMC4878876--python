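"""Group presets for the four sex x genotype cohorts.

Presets are shipped as a YAML file (``data/group_presets.yaml``) whose values
are anchored to printed group means (weighted decay time constants,
spontaneous firing rates, holding and TBOA-unmasked currents, rebound
components); see the file header and docs/methods.md for the provenance of
each number.  Custom preset files with the same layout can be loaded with
:func:`load_presets`.
"""

from __future__ import annotations

from dataclasses import replace
from importlib import resources
from pathlib import Path

import yaml

from .synthetic import GroupPreset, SynthIPSCParams, SynthSpikingParams

GROUP_ORDER = ("wt_male", "mut_male", "wt_female", "mut_female")


def load_presets(path: str | Path | None = None) -> dict[str, GroupPreset]:
    """Load group presets from a YAML file (package default if none given)."""
    if path is None:
        text = resources.files("cbnephys").joinpath("data/group_presets.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    presets: dict[str, GroupPreset] = {}
    for name, spec in raw["groups"].items():
        ipsc = replace(SynthIPSCParams(), **spec.get("ipsc", {}))
        spiking = replace(SynthSpikingParams(), **spec.get("spiking", {}))
        presets[name] = GroupPreset(
            name=name,
            sex=spec["sex"],
            genotype=spec["genotype"],
            strain=spec.get("strain", "Gabrb3"),
            ipsc=ipsc,
            spiking=spiking,
            holding_current_pA=float(spec.get("holding_current_pA", 0.0)),
            mglur_tboa_current_pA=float(spec.get("mglur_tboa_current_pA", 0.0)),
            rebound_pre_rate_Hz=float(spec.get("rebound_pre_rate_Hz", 40.0)),
            rebound_change_control_pct=float(spec.get("rebound_change_control_pct", 50.0)),
            rebound_change_mglur_pct=float(spec.get("rebound_change_mglur_pct", 0.0)),
        )
    return presets


def default_presets() -> dict[str, GroupPreset]:
    """The four shipped sex x genotype presets, in canonical order."""
    presets = load_presets()
    return {name: presets[name] for name in GROUP_ORDER if name in presets}
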