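"""Position-based stitching and overlap cropping.

Because the stage reports its position for every tile, a composite can be
assembled directly from stage coordinates and the sample-plane pixel pitch,
with an optional cross-correlation refinement for residual camera/axis
misalignment.  Offsets are rounded to whole pixels — no sub-pixel resampling —
so no intensity interpolation happens before thresholding.

``crop_overlaps`` implements the tile-cropping used by the lightweight
total-area method: each tile loses its trailing overlap (rightmost columns
and top rows in the scan direction) so the cropped tiles tile the plane with
no pixel counted twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.registration import phase_cross_correlation

from .acquire import Tile

__all__ = [
    "MosaicConfig",
    "place_tiles",
    "refine_offsets",
    "crop_overlaps",
]


@dataclass(frozen=True)
class MosaicConfig:
    """Stitching configuration.

    ``overlap_policy`` resolves doubly covered pixels: ``last-wins`` pastes in
    order, ``feather`` blends with a linear ramp (display), ``crop`` trims
    each tile's trailing overlap before pasting (quantification — conserves
    area).  ``refine='cross-correlation'`` registers overlap strips within
    ``max_refine_shift`` px before placement.
    """

    pixel_pitch_um: float = 6.45
    overlap_policy: str = "last-wins"
    refine: str = "none"
    max_refine_shift: int = 10

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.overlap_policy not in ("last-wins", "feather", "crop"):
            raise ValueError(f"unknown overlap_policy {self.overlap_policy!r}")
        if self.refine not in ("none", "cross-correlation"):
            raise ValueError(f"unknown refine mode {self.refine!r}")
        if self.max_refine_shift < 0:
            raise ValueError("max_refine_shift must be >= 0")


def _nominal_offsets(tiles: Sequence[Tile], pitch_mm: float) -> np.ndarray:
    xs = np.array([t.pose.x for t in tiles])
    ys = np.array([t.pose.y for t in tiles])
    rows = np.rint((ys - ys.min()) / pitch_mm).astype(int)
    cols = np.rint((xs - xs.min()) / pitch_mm).astype(int)
    return np.column_stack([rows, cols])


def place_tiles(
    tiles: Sequence[Tile], config: MosaicConfig
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Assemble tiles into a composite using stage coordinates.

    Tile (row, col) is placed at pixel offset (pose - min pose) / pitch,
    rounded to the nearest pixel.  Returns the composite and a per-tile
    offsets table (row, col, offset_row_px, offset_col_px).
    """
    tiles = list(tiles)
    if not tiles:
        raise ValueError("no tiles to place")
    shape0 = tiles[0].image.shape
    modality0 = tiles[0].modality
    for t in tiles:
        if t.image.shape != shape0:
            raise ValueError(
                f"inconsistent tile shapes: {t.name} is {t.image.shape}, expected {shape0}"
            )
        if t.modality != modality0:
            raise ValueError("tiles mix modalities")
    pitch_mm = config.pixel_pitch_um / 1000.0
    offsets = _nominal_offsets(tiles, pitch_mm)
    if config.refine == "cross-correlation":
        offsets = refine_offsets(tiles, offsets, config.max_refine_shift)

    th, tw = shape0[:2]
    H = int(offsets[:, 0].max()) + th
    W = int(offsets[:, 1].max()) + tw
    dtype = tiles[0].image.dtype

    if config.overlap_policy == "feather":
        acc = np.zeros((H, W), dtype=np.float64)
        wacc = np.zeros((H, W), dtype=np.float64)
        ramp_r = np.minimum(np.arange(th) + 1, th - np.arange(th)).astype(float)
        ramp_c = np.minimum(np.arange(tw) + 1, tw - np.arange(tw)).astype(float)
        weight = np.outer(ramp_r, ramp_c)
        for t, (r, c) in zip(tiles, offsets):
            acc[r : r + th, c : c + tw] += t.image.astype(np.float64) * weight
            wacc[r : r + th, c : c + tw] += weight
        with np.errstate(invalid="ignore"):
            composite = np.where(wacc > 0, acc / np.maximum(wacc, 1e-12), 0.0)
        if np.issubdtype(dtype, np.integer):
            composite = np.rint(composite).astype(dtype)
        else:
            composite = composite.astype(dtype)
    else:
        composite = np.zeros((H, W), dtype=dtype)
        for t, (r, c) in zip(tiles, offsets):
            img = t.image
            rr, cc = r, c
            if config.overlap_policy == "crop":
                # trailing-overlap trim computed from neighbour spacing
                oy, ox = _grid_overlap_px(tiles, offsets, (th, tw))
                img = crop_overlaps(img, ox, oy)
            composite[rr + (th - img.shape[0]) : rr + th, cc : cc + img.shape[1]] = img

    table = pd.DataFrame(
        {
            "row": [t.row for t in tiles],
            "col": [t.col for t in tiles],
            "offset_row_px": offsets[:, 0],
            "offset_col_px": offsets[:, 1],
        }
    )
    return composite, table


def _grid_overlap_px(
    tiles: Sequence[Tile], offsets: np.ndarray, tile_shape: Tuple[int, int]
) -> Tuple[int, int]:
    """Overlap in px implied by nominal grid spacing (0 if single row/col)."""
    th, tw = tile_shape
    rows = sorted(set(int(o) for o in offsets[:, 0]))
    cols = sorted(set(int(o) for o in offsets[:, 1]))
    oy = max(0, th - (rows[1] - rows[0])) if len(rows) > 1 else 0
    ox = max(0, tw - (cols[1] - cols[0])) if len(cols) > 1 else 0
    return oy, ox


def crop_overlaps(tile_image: np.ndarray, x_overlap_px: int, y_overlap_px: int) -> np.ndarray:
    """Remove the trailing overlap: rightmost columns and top rows.

    With every tile of a plan cropped this way the cropped tiles partition the
    stepped footprint — no pixel is counted twice, which is the property the
    lightweight total-area method depends on.
    """
    h, w = tile_image.shape[:2]
    if x_overlap_px < 0 or y_overlap_px < 0:
        raise ValueError("overlaps must be >= 0")
    if x_overlap_px >= w or y_overlap_px >= h:
        raise ValueError(
            f"overlap ({x_overlap_px}, {y_overlap_px}) px >= tile dimension ({w}, {h})"
        )
    return tile_image[y_overlap_px:, : w - x_overlap_px]


def refine_offsets(
    tiles: Sequence[Tile],
    initial_offsets: np.ndarray,
    max_shift: int,
) -> np.ndarray:
    """Register adjacent tiles on their overlap strips and propagate shifts.

    Pairwise shifts come from phase cross-correlation on the nominal overlap
    strip (>= 8 px wide on the refined axis); shifts beyond ``max_shift`` or
    from featureless strips are discarded with a warning and the initial
    offset kept.  Corrections are propagated left-to-right along each row,
    then row anchors are chained top-to-bottom.
    """
    tiles = list(tiles)
    offsets = np.asarray(initial_offsets, dtype=int).copy()
    th, tw = tiles[0].image.shape[:2]
    index = {(t.row, t.col): i for i, t in enumerate(tiles)}
    rows = sorted(set(t.row for t in tiles))
    cols = sorted(set(t.col for t in tiles))

    def pair_shift(i: int, j: int, axis: int) -> Optional[np.ndarray]:
        """Measured (dr, dc) correction for tile j relative to its nominal
        offset, using tile i as anchor. axis=1: j right of i; axis=0: below."""
        oi, oj = offsets[i], offsets[j]
        a, b = tiles[i].image, tiles[j].image
        if axis == 1:
            ov = oi[1] + tw - oj[1]
            if ov < 8:
                return None
            strip_a = a[:, tw - ov :]
            strip_b = b[:, :ov]
        else:
            ov = oi[0] + th - oj[0]
            if ov < 8:
                return None
            strip_a = a[th - ov :, :]
            strip_b = b[:ov, :]
        if strip_a.std() < 1.0 or strip_b.std() < 1.0:
            warnings.warn(
                f"featureless overlap between {tiles[i].name} and {tiles[j].name}; "
                "keeping stage offset", stacklevel=2,
            )
            return None
        shift, error, _ = phase_cross_correlation(
            strip_a.astype(float), strip_b.astype(float)
        )
        if np.any(np.abs(shift) > max_shift):
            warnings.warn(
                f"refinement shift {shift} exceeds max_shift={max_shift} between "
                f"{tiles[i].name} and {tiles[j].name}; keeping stage offset",
                stacklevel=2,
            )
            return None
        return np.rint(shift).astype(int)

    corrections = np.zeros_like(offsets)
    # chain row anchors (first tile of each row) vertically
    for ri in range(1, len(rows)):
        i = index.get((rows[ri - 1], cols[0]))
        j = index.get((rows[ri], cols[0]))
        if i is None or j is None:
            continue
        s = pair_shift(i, j, axis=0)
        corrections[j] = corrections[i] + (s if s is not None else 0)
    # chain along each row
    for r in rows:
        for ci in range(1, len(cols)):
            i = index.get((r, cols[ci - 1]))
            j = index.get((r, cols[ci]))
            if i is None or j is None:
                continue
            s = pair_shift(i, j, axis=1)
            corrections[j] = corrections[i] + (s if s is not None else 0)
    refined = offsets + corrections
    refined -= refined.min(axis=0, keepdims=True)
    return refined
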