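"""TOML run configuration.

A run config bundles everything a reproducible scan/analysis needs: the scan
grid, camera settings, optics model (for the simulator and for physical-unit
conversions), analysis and mosaic parameters and the master seed.  Every CLI
run writes its resolved config as JSON next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path
from typing import Union

from .acquire import CameraSettings
from .mosaic import MosaicConfig
from .particles import AnalysisConfig
from .planner import FieldOfView, ScanPlanSpec, spec_from_dict
from .simulate import OpticsModel, SampleSpec

__all__ = [
    "load_toml",
    "optics_from_dict",
    "sample_from_dict",
    "analysis_from_dict",
    "mosaic_from_dict",
    "camera_from_dict",
    "scan_from_dict",
    "resolved_config_json",
]


def load_toml(path: Union[str, Path]) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _build(cls, d: dict, **overrides):
    """Instantiate a dataclass from a dict, ignoring unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {k: v for k, v in d.items() if k in names}
    kwargs.update(overrides)
    return cls(**kwargs)


def optics_from_dict(d: dict) -> OpticsModel:
    d = dict(d)
    if "fov_width_mm" in d or "fov_height_mm" in d:
        d["fov"] = FieldOfView(
            float(d.pop("fov_width_mm", 6.5403)), float(d.pop("fov_height_mm", 4.9020))
        )
    return _build(OpticsModel, d)


def sample_from_dict(d: dict) -> SampleSpec:
    return _build(SampleSpec, d)


def analysis_from_dict(d: dict) -> AnalysisConfig:
    return _build(AnalysisConfig, d)


def mosaic_from_dict(d: dict) -> MosaicConfig:
    return _build(MosaicConfig, d)


def camera_from_dict(d: dict) -> CameraSettings:
    d = dict(d)
    if "wb_gains" in d:
        d["wb_gains"] = tuple(d["wb_gains"])
    return _build(CameraSettings, d)


def scan_from_dict(d: dict) -> ScanPlanSpec:
    return spec_from_dict(d)


def resolved_config_json(config: dict, path: Path) -> None:
    """Write the resolved run configuration next to the run outputs."""
    path.write_text(json.dumps(config, indent=1, sort_keys=True, default=str))
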