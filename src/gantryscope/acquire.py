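"""Scan execution and image-conditioning primitives.

:func:`run_scan` drives a scan plan against a stage endpoint and a camera
endpoint, capturing one tile per planned position (after an ``M400``
motion-complete sync and an optional settle delay) and writing each tile as a
TIFF plus a JSON pose sidecar, atomically, under ``tile_r{row}_c{col}``
names.  A manifest recording the plan hash and completed tiles is always
written; an aborted scan leaves a partial manifest and raises.

The conditioning primitives mirror the standard pre-analysis steps on this
class of instrument: mean binning (the sensor's 4056 x 3040 frames are binned
4x to 1014 x 760 because resolution is optics-limited), the 180-degree
orientation flip applied before stitching, and single-channel extraction.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import tifffile

from . import motion
from .motion import StagePose
from .planner import PlanPosition, plan_to_csv
from .simulate import OpticsModel, SyntheticSample, pose_seed, render_tile

__all__ = [
    "CameraSettings",
    "Tile",
    "VirtualCamera",
    "ScanAbortedError",
    "run_scan",
    "bin_image",
    "orient_image",
    "extract_channel",
    "write_tile",
    "read_tile",
    "read_tile_dir",
]


@dataclass(frozen=True)
class CameraSettings:
    """Camera acquisition settings (exposure in microseconds)."""

    exposure_us: float = 5000.0
    wb_gains: tuple = (4.0, 1.0)  # (red, blue)
    binning: int = 1

    def __post_init__(self) -> None:
        if self.exposure_us <= 0:
            raise ValueError("exposure must be positive")
        if self.binning not in (1, 2, 4, 8):
            raise ValueError("binning must be one of {1, 2, 4, 8}")

    def to_dict(self) -> dict:
        return {
            "exposure_us": self.exposure_us,
            "wb_gains": list(self.wb_gains),
            "binning": self.binning,
        }


@dataclass
class Tile:
    """One acquired field: image raster + capture pose + provenance."""

    image: np.ndarray
    pose: StagePose
    row: int
    col: int
    modality: str = "fluorescence"
    settings: CameraSettings = field(default_factory=CameraSettings)
    timestamp: float = 0.0

    @property
    def name(self) -> str:
        return f"tile_r{self.row}_c{self.col}"

    def sidecar(self) -> dict:
        return {
            "row": self.row,
            "col": self.col,
            "x_mm": self.pose.x,
            "y_mm": self.pose.y,
            "z_mm": self.pose.z,
            "modality": self.modality,
            "timestamp": self.timestamp,
            **self.settings.to_dict(),
        }


class ScanAbortedError(RuntimeError):
    """A capture failed mid-scan; the partial manifest lists completed tiles."""

    def __init__(self, message: str, manifest_path: Path):
        super().__init__(message)
        self.manifest_path = manifest_path


class VirtualCamera:
    """Camera endpoint rendering the synthetic sample at the stage truth pose.

    ``stage_to_sample_mm`` maps stage coordinates into the sample-canvas frame
    (sample_mm = stage_mm - offset); the noise stream is derived from the pose
    so captures are bit-reproducible regardless of scan order.
    """

    def __init__(
        self,
        sample: SyntheticSample,
        optics: OpticsModel,
        stage,
        modality: str = "fluorescence",
        base_seed: int = 0,
        stage_to_sample_mm: tuple = (0.0, 0.0),
    ):
        self.sample = sample
        self.optics = optics
        self.stage = stage
        self.modality = modality
        self.base_seed = base_seed
        self.stage_to_sample_mm = stage_to_sample_mm

    def capture(
        self, settings: Optional[CameraSettings] = None, modality: Optional[str] = None
    ) -> np.ndarray:
        truth = self.stage.truth_pose
        ox, oy = self.stage_to_sample_mm
        pose = StagePose(truth.x - ox, truth.y - oy, truth.z)
        img = render_tile(
            self.sample, pose, self.optics,
            modality=modality or self.modality, seed=self.base_seed,
        )
        if settings is not None and settings.binning > 1:
            img = bin_image(img, settings.binning)
        return img


def _write_json_atomic(path: Path, payload: dict) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(payload, indent=1, sort_keys=True))
    os.replace(tmp, path)


def write_tile(directory: Path, tile: Tile) -> Path:
    """Write ``tile_r{row}_c{col}.tif`` plus its JSON sidecar atomically."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img_path = directory / f"{tile.name}.tif"
    tmp = img_path.with_suffix(".tif.tmp")
    tifffile.imwrite(tmp, tile.image)
    os.replace(tmp, img_path)
    _write_json_atomic(directory / f"{tile.name}.json", tile.sidecar())
    return img_path


def read_tile(directory: Path, row: int, col: int) -> Tile:
    directory = Path(directory)
    name = f"tile_r{row}_c{col}"
    img_path = directory / f"{name}.tif"
    meta_path = directory / f"{name}.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    return Tile(
        image=tifffile.imread(img_path),
        pose=StagePose(meta["x_mm"], meta["y_mm"], meta["z_mm"]),
        row=meta["row"],
        col=meta["col"],
        modality=meta.get("modality", "fluorescence"),
        settings=CameraSettings(
            exposure_us=meta.get("exposure_us", 5000.0),
            wb_gains=tuple(meta.get("wb_gains", (4.0, 1.0))),
            binning=meta.get("binning", 1),
        ),
        timestamp=meta.get("timestamp", 0.0),
    )


def read_tile_dir(directory: Path) -> List[Tile]:
    """Read every tile (TIFF + sidecar) in a scan directory, row-major order."""
    directory = Path(directory)
    tiles = []
    for meta_path in directory.glob("tile_r*_c*.json"):
        meta = json.loads(meta_path.read_text())
        tiles.append(read_tile(directory, meta["row"], meta["col"]))
    if not tiles:
        raise FileNotFoundError(f"no tiles with sidecars found in {directory}")
    tiles.sort(key=lambda t: (t.row, t.col))
    return tiles


def run_scan(
    plan: Sequence[PlanPosition],
    stage,
    camera,
    settings: CameraSettings,
    out_dir: Path,
    modality: str = "fluorescence",
    settle_s: float = 0.0,
    home_first: bool = True,
) -> dict:
    """Execute a scan plan: move, sync, settle, capture, write — per position.

    Returns the manifest dict (also written to ``manifest.json``).  On a
    capture failure the manifest of completed tiles is written and a
    :class:`ScanAbortedError` is raised.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plan = list(plan)
    plan_hash = hashlib.sha256(plan_to_csv(plan).encode()).hexdigest()
    manifest = {
        "plan_hash": plan_hash,
        "n_planned": len(plan),
        "modality": modality,
        "settings": settings.to_dict(),
        "tiles": [],
        "completed": False,
    }
    manifest_path = out_dir / "manifest.json"
    motion.initialize(stage)
    if home_first:
        motion.send(motion.home(), stage)
    try:
        for pos in plan:
            motion.send(
                motion.render_move(pos.pose, limits=getattr(stage, "limits", None)),
                stage,
            )
            motion.send(motion.await_motion_complete(), stage)
            if settle_s > 0:
                time.sleep(settle_s)
            image = camera.capture(settings, modality)
            tile = Tile(
                image=image, pose=pos.pose, row=pos.row, col=pos.col,
                modality=modality, settings=settings, timestamp=time.time(),
            )
            write_tile(out_dir, tile)
            manifest["tiles"].append(tile.name)
    except Exception as exc:
        _write_json_atomic(manifest_path, manifest)
        raise ScanAbortedError(
            f"scan aborted after {len(manifest['tiles'])}/{len(plan)} tiles: {exc}",
            manifest_path,
        ) from exc
    manifest["completed"] = True
    _write_json_atomic(manifest_path, manifest)
    return manifest


# ---------------------------------------------------------------------------
# conditioning primitives
# ---------------------------------------------------------------------------

def bin_image(image: np.ndarray, factor: int) -> np.ndarray:
    """Bin by the block MEAN so brightness is invariant to the binning factor.

    Trailing rows/columns not filling a full block are dropped with a warning.
    Works on 2-D and on (H, W, C) images (spatial axes only).
    """
    if not isinstance(factor, int) or factor < 1:
        raise ValueError(f"binning factor must be an integer >= 1, got {factor!r}")
    if factor == 1:
        return image
    h, w = image.shape[:2]
    hh, ww = (h // factor) * factor, (w // factor) * factor
    if (hh, ww) != (h, w):
        warnings.warn(
            f"image {h}x{w} not divisible by {factor}; dropping trailing "
            f"{h - hh} rows and {w - ww} cols",
            stacklevel=2,
        )
    img = image[:hh, :ww].astype(np.float64)
    new_shape = (hh // factor, factor, ww // factor, factor) + img.shape[2:]
    binned = img.reshape(new_shape).mean(axis=(1, 3))
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return np.clip(np.rint(binned), info.min, info.max).astype(image.dtype)
    return binned.astype(image.dtype)


def orient_image(image: np.ndarray) -> np.ndarray:
    """Flip both axes (180-degree rotation) — the pre-stitching orientation."""
    return image[::-1, ::-1].copy()


def extract_channel(image: np.ndarray, channel) -> np.ndarray:
    """Extract one channel of an RGB image ('red'/'green'/'blue' or index)."""
    names = {"red": 0, "green": 1, "blue": 2}
    idx = names.get(channel, channel)
    if image.ndim != 3:
        raise ValueError("extract_channel expects a multi-channel (H, W, C) image")
    if not isinstance(idx, int) or not (0 <= idx < image.shape[2]):
        raise ValueError(f"channel {channel!r} not present in image with "
                         f"{image.shape[2]} channels")
    return image[:, :, idx].copy()
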