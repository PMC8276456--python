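"""Run configuration: conventions, segmentation parameters, seed.

Two normalization conventions for the barycenter distance exist in the
field (TAD radius of gyration vs half the TAD major axis); both are
implemented and the one in force is recorded in every output row.  The
config validates every enum at load time so a typo fails early.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .model import ConfigError

ALLOWED = {
    "convention": ("half_major_axis", "rg"),
    "tendency": ("median", "mean"),
    "dimensionality": ("2d_projected", "3d"),
}

_DEFAULT_SEGMENTATION = {
    "method": "dbscan",
    # nm radii / minimum neighbor counts, keyed by target type
    "tad": {"r": 60.0, "n_min": 10, "r_ref": 60.0},
    "foci": {"r": 30.0, "n_min": 15, "r_ref": 30.0},
    # density factors follow the SR-Tesseler convention: 3 for chromatin
    # domains, 20 for replication origins/foci, 3.5 for protein clusters
    "voronoi": {"density_factor": 3.0, "min_detections": 20},
}

_DEFAULT_SIMULATION = {
    "presets": ["g1s_peripheral", "g1_uniform", "interior"],
    "n_cells": 16,
    "tad_radius": 200.0,          # nm, uniform-ball radius; Rg(3D) ~ 155 nm
    "n_tad_localizations": 2500,
    "n_foci": 7,
    "focus_diameter": 30.0,       # nm
    "locs_per_focus": 300,
    "precision": [20.0, 50.0],    # nm lateral, nm axial
}


@dataclass
class AnalysisConfig:
    """Resolved analysis configuration (defaults filled, enums validated)."""

    convention: str = "half_major_axis"
    tendency: str = "median"
    dimensionality: str = "2d_projected"
    seed: int = 0
    output_dir: str = "runs"
    segmentation: dict = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_SEGMENTATION))
    simulation: dict = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_SIMULATION))

    def __post_init__(self) -> None:
        for key, allowed in ALLOWED.items():
            val = getattr(self, key)
            if val not in allowed:
                raise ConfigError(
                    f"config key '{key}' = {val!r} not allowed; "
                    f"allowed values: {', '.join(allowed)}")
        self.seed = int(self.seed)

    @classmethod
    def from_dict(cls, d: dict | None) -> "AnalysisConfig":
        d = dict(d or {})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(
                f"unknown config keys: {sorted(unknown)}; "
                f"allowed: {sorted(known)}")
        for key in ("segmentation", "simulation"):
            if key in d:
                base = copy.deepcopy(
                    _DEFAULT_SEGMENTATION if key == "segmentation"
                    else _DEFAULT_SIMULATION)
                for k, v in d[key].items():
                    if isinstance(v, dict) and isinstance(base.get(k), dict):
                        base[k].update(v)
                    else:
                        base[k] = v
                d[key] = base
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> AnalysisConfig:
    """Load a YAML config; absent keys fall back to defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{Path(path).name}: config root must be a mapping")
    return AnalysisConfig.from_dict(data)
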