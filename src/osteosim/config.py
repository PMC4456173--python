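"""TOML run configuration -> Scenario.

A config file holds one section per module, mirroring the parameter
dataclasses; any omitted key keeps its default. Example::

    [scenario]
    gap_mm = 8.0
    gel_present = true
    bmp2_dose_ug = 5.0
    horizon_days = 84
    mesh_h = 0.4

    [geometry]
    length = 20.0

    [rules]
    psi_bone_max = 6e-3

    [modulation.anchors.bone_production]
    csv = "anchors/bone_production.csv"   # optional anchor override
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path

from .bmp2 import BMPParams
from .hydrogel import AlginateParams
from .materials import TissueProperties
from .mechanics import LoadCase
from .modulation import load_anchor_csv
from .rules import RuleThresholds
from .scenarios import Geometry, Scenario
from .transport import MotilityParams

__all__ = ["load_config", "scenario_from_dict"]

_SECTIONS = {
    "geometry": ("geometry", Geometry),
    "bmp2": ("bmp", BMPParams),
    "hydrogel": ("alginate", AlginateParams),
    "motility": ("motility", MotilityParams),
    "rules": ("rules", RuleThresholds),
    "load": ("load", LoadCase),
}


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def scenario_from_dict(cfg: dict, base_dir: Path | None = None) -> Scenario:
    """Build a Scenario from a nested configuration dictionary."""
    cfg = dict(cfg)
    kwargs = dict(cfg.pop("scenario", {}))
    for section, (attr, cls) in _SECTIONS.items():
        if section in cfg:
            data = cfg.pop(section)
            if section == "load" and "cortex_band" in data:
                data["cortex_band"] = tuple(data["cortex_band"])
            kwargs[attr] = _build(cls, data)
    mod = cfg.pop("modulation", {})
    anchors = {}
    for name, entry in mod.get("anchors", {}).items():
        if "csv" in entry:
            path = Path(entry["csv"])
            if base_dir is not None and not path.is_absolute():
                path = base_dir / path
            anchors[name] = load_anchor_csv(path)
        else:
            anchors[name] = tuple(
                (float(g), float(f)) for g, f in entry["points"])
    if anchors:
        kwargs["modulation_anchors"] = anchors
    properties = cfg.pop("tissue_properties", None)
    if properties:
        table = {name: tuple(v) for name, v in properties.items()}
        base = TissueProperties()
        merged = dict(base.table)
        merged.update(table)
        kwargs["props"] = TissueProperties(table=merged)
    if cfg:
        raise ValueError(f"unknown config sections: {sorted(cfg)}")
    return Scenario(**kwargs)


def load_config(path) -> Scenario:
    """Read a TOML run configuration from disk."""
    path = Path(path)
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    return scenario_from_dict(cfg, base_dir=path.parent)
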