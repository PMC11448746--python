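"""Serpentine ("snake") scan planning.

A tiled scan covers the sample with a grid of ``x_win`` x ``y_win`` fields
spaced ``x_step`` x ``y_step`` millimetres apart, visited row by row with the
traversal direction alternating on each row so the stage never makes a return
sweep.  ``z`` is held constant for the whole plan: on this class of instrument
the bed is levelled optically before scanning, which replaces autofocus.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from typing import List, Tuple

from .motion import StagePose

__all__ = [
    "ScanPlanSpec",
    "FieldOfView",
    "PlanPosition",
    "plan_snake",
    "overlap_fractions",
    "plan_to_csv",
    "plan_from_csv",
    "spec_from_dict",
]


@dataclass(frozen=True)
class FieldOfView:
    """Field of view at the sample plane, in mm."""

    width_mm: float
    height_mm: float

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("field of view dimensions must be positive")


@dataclass(frozen=True)
class ScanPlanSpec:
    """Grid geometry of a scan: field counts, steps (mm) and origin pose."""

    x_win: int
    y_win: int
    x_step: float
    y_step: float
    origin: StagePose = StagePose(0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("x_win", "y_win"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        if self.x_step <= 0 or self.y_step <= 0:
            raise ValueError("steps must be strictly positive")

    @property
    def n_fields(self) -> int:
        return self.x_win * self.y_win


@dataclass(frozen=True)
class PlanPosition:
    row: int
    col: int
    pose: StagePose


def plan_snake(spec: ScanPlanSpec) -> List[PlanPosition]:
    """Enumerate the serpentine scan order.

    Row ``r`` sits at ``origin.y + r*y_step``; even rows traverse columns
    left-to-right, odd rows right-to-left, so consecutive positions differ by
    exactly one step along exactly one axis.
    """
    out: List[PlanPosition] = []
    for r in range(spec.y_win):
        cols = range(spec.x_win) if r % 2 == 0 else range(spec.x_win - 1, -1, -1)
        for c in cols:
            pose = StagePose(
                spec.origin.x + c * spec.x_step,
                spec.origin.y + r * spec.y_step,
                spec.origin.z,
                feedrate=spec.origin.feedrate,
            )
            out.append(PlanPosition(row=r, col=c, pose=pose))
    return out


def overlap_fractions(
    spec: ScanPlanSpec, fov: FieldOfView
) -> Tuple[float, float]:
    """Fractional overlap between adjacent fields, per axis.

    overlap = (fov - step) / fov, clipped at zero when the step exceeds the
    field of view (abutting or gapped fields).
    """
    ox = max(0.0, (fov.width_mm - spec.x_step) / fov.width_mm)
    oy = max(0.0, (fov.height_mm - spec.y_step) / fov.height_mm)
    return ox, oy


_CSV_HEADER = ["row", "col", "x_mm", "y_mm", "z_mm"]


def plan_to_csv(plan: List[PlanPosition]) -> str:
    """Serialize a plan as CSV (row, col, x_mm, y_mm, z_mm) for audit."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(_CSV_HEADER)
    for p in plan:
        w.writerow([p.row, p.col, f"{p.pose.x:.4f}", f"{p.pose.y:.4f}", f"{p.pose.z:.4f}"])
    return buf.getvalue()


def plan_from_csv(text: str) -> List[PlanPosition]:
    rows = list(csv.reader(io.StringIO(text)))
    if not rows or rows[0] != _CSV_HEADER:
        raise ValueError("not a scan-plan CSV (bad header)")
    return [
        PlanPosition(int(r), int(c), StagePose(float(x), float(y), float(z)))
        for r, c, x, y, z in rows[1:]
    ]


def spec_from_dict(d: dict) -> ScanPlanSpec:
    """Build a :class:`ScanPlanSpec` from a TOML ``[scan]`` table."""
    origin = d.get("origin", {})
    pose = StagePose(
        float(origin.get("x_mm", 0.0)),
        float(origin.get("y_mm", 0.0)),
        float(origin.get("z_mm", 0.0)),
        feedrate=origin.get("feedrate"),
    )
    return ScanPlanSpec(
        x_win=int(d["x_win"]),
        y_win=int(d["y_win"]),
        x_step=float(d["x_step"]),
        y_step=float(d["y_step"]),
        origin=pose,
    )
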