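"""Synthetic instrument: ground-truthed samples and QC targets.

Everything downstream of the camera (stitching, particle quantification,
optical QC) is validated against scenes rendered by this module, which plays
the role of the physical microscope: a filter-paper disc bearing fluorescent
and non-fluorescent plastic particles and fibres with known positions, areas
and shapes, plus the standard bench targets (slanted edge, printed wedge, dot
grid, blank field).

The optics/sensor chain applied to every rendered image is, in order:

1. radial (barrel/pincushion) distortion with a single ``k1`` coefficient,
2. Gaussian blur whose sigma grows once the scene leaves the focus band:
   ``sigma(dz) = sigma0 * (1 + defocus_slope * max(0, |dz|/h - 1))`` where
   ``h`` is the depth-of-field half-width,
3. a cos^4-shaped vignette scaled so the corner intensity is
   ``1 - vignette_strength`` of the centre,
4. additive Gaussian sensor noise,
5. quantization to the sensor bit depth.

Rendering is deterministic per (spec, seed, optics): the noise stream for a
tile is derived from the pose, so a scan may be replayed in any order.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import erf
from skimage.draw import ellipse as draw_ellipse

from .motion import StagePose
from .planner import FieldOfView

__all__ = [
    "OpticsModel",
    "SampleSpec",
    "GroundTruth",
    "SyntheticSample",
    "PackingError",
    "CoverageError",
    "render_sample",
    "render_tile",
    "render_wedge",
    "render_slanted_edge",
    "render_dot_grid",
    "render_dot_field",
    "render_blank_field",
    "vignette_profile",
    "pose_seed",
]


class PackingError(ValueError):
    """The requested particle load cannot be placed on the disc."""


class CoverageError(ValueError):
    """A tile pose maps (partly) outside the sample canvas."""


@dataclass(frozen=True)
class OpticsModel:
    """Parametric optics + sensor model shared by the simulator and by
    physical-unit conversions.

    The default pixel pitch (6.45 um/px at the sample plane after 4x sensor
    binning) is a calibration default chosen so that a 1014 x 760 binned frame
    spans 6.54 x 4.90 mm — slightly more than the 6.2 x 4.5 mm scan steps used
    for whole-filter scans, giving the small positive overlap stitching needs.
    """

    pixel_pitch_sample_um: float = 6.45
    fov: FieldOfView = FieldOfView(6.5403, 4.9020)
    dof_halfwidth_mm: float = 0.25
    defocus_slope: float = 8.0
    vignette_strength: float = 0.05
    radial_distortion_k1: float = 0.0
    blur_sigma_in_focus_px: float = 1.0
    noise_sd: float = 2.0
    bit_depth: int = 8
    focus_z_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_pitch_sample_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if not (0.0 <= self.vignette_strength < 1.0):
            raise ValueError("vignette_strength must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")
        if self.blur_sigma_in_focus_px < 0 or self.dof_halfwidth_mm <= 0:
            raise ValueError("blur sigma must be >= 0 and DOF half-width > 0")

    @property
    def pitch_mm(self) -> float:
        return self.pixel_pitch_sample_um / 1000.0

    @property
    def tile_shape(self) -> Tuple[int, int]:
        """(rows, cols) of one rendered tile."""
        return (
            int(round(self.fov.height_mm / self.pitch_mm)),
            int(round(self.fov.width_mm / self.pitch_mm)),
        )

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth <= 8 else np.uint16

    def blur_sigma_at(self, z_mm: float) -> float:
        """Defocus blur sigma (px) at axial position ``z_mm``."""
        dz = abs(z_mm - self.focus_z_mm)
        excess = max(0.0, dz / self.dof_halfwidth_mm - 1.0)
        return self.blur_sigma_in_focus_px * (1.0 + self.defocus_slope * excess)


@dataclass(frozen=True)
class SampleSpec:
    """Parameters of a synthetic filter-paper sample.

    Defaults emulate a 90 mm filter disc bearing shredded-plastic particles:
    per-particle areas are log-normal with median ~0.06 mm^2 and quartile
    ratio ~3 (mu = ln 0.06 ~ -2.81, sigma = 1.63), matching the particle-size
    summaries observed on environmental scans with this class of instrument.
    """

    disc_diameter_mm: float = 90.0
    n_particles: int = 150
    area_lognorm_mu: float = -2.81
    area_lognorm_sigma: float = 1.63
    min_area_mm2: float = 0.0
    fraction_fluorescent: float = 0.5
    fraction_fibres: float = 0.2
    fibre_aspect: float = 8.0
    particle_aspect_max: float = 2.0
    background_texture_sd: float = 6.0
    min_separation_mm: float = 0.3
    margin_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_fluorescent", "fraction_fibres"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.disc_diameter_mm <= 0:
            raise ValueError("disc diameter must be positive")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if self.fibre_aspect < 1 or self.particle_aspect_max < 1:
            raise ValueError("aspect ratios must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Per-particle truth table plus totals — the oracle for every detector."""

    particles: pd.DataFrame  # id, x_mm, y_mm, area_mm2, circularity, is_fluorescent, is_fibre

    @property
    def n(self) -> int:
        return len(self.particles)

    @property
    def total_area_mm2(self) -> float:
        return float(self.particles["area_mm2"].sum()) if self.n else 0.0

    @property
    def total_fluorescent_area_mm2(self) -> float:
        if not self.n:
            return 0.0
        sel = self.particles["is_fluorescent"]
        return float(self.particles.loc[sel, "area_mm2"].sum())


@dataclass(frozen=True)
class SyntheticSample:
    """Rendered scene rasters (pre-sensor radiance) plus ground truth."""

    fluorescence: np.ndarray  # float32, 0..255 scale
    reflected: np.ndarray
    pixel_pitch_um: float
    ground_truth: GroundTruth

    @property
    def shape(self) -> Tuple[int, int]:
        return self.fluorescence.shape

    def channel(self, modality: str) -> np.ndarray:
        if modality not in ("fluorescence", "reflected"):
            raise ValueError(f"unknown modality {modality!r}")
        return getattr(self, modality)


def _ellipse_perimeter_mm(a: float, b: float) -> float:
    # Ramanujan's second approximation
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


def render_sample(spec: SampleSpec, pixel_pitch_um: float = 6.45) -> SyntheticSample:
    """Render a particle-bearing filter disc at ``pixel_pitch_um`` per pixel.

    Particles are filled rotated ellipses (fibres are high-aspect ellipses)
    placed without mutual contact inside the disc.  Fluorescent particles are
    bright on a near-black background in the fluorescence channel; in the
    reflected channel all particles sit on textured bright paper, dark
    particles darker and fluorescent (orange) ones brighter than the paper.
    """
    rng = np.random.default_rng(spec.seed)
    pitch_mm = pixel_pitch_um / 1000.0
    canvas_mm = spec.disc_diameter_mm + 2 * spec.margin_mm
    n_px = int(round(canvas_mm / pitch_mm))
    center_mm = canvas_mm / 2.0
    disc_r_mm = spec.disc_diameter_mm / 2.0

    # background: bed, then textured paper disc
    reflected = np.full((n_px, n_px), 30.0, dtype=np.float32)
    fluor = np.full((n_px, n_px), 5.0, dtype=np.float32)
    yy, xx = np.mgrid[0:n_px, 0:n_px]
    r_px = np.hypot((yy + 0.5) * pitch_mm - center_mm, (xx + 0.5) * pitch_mm - center_mm)
    disc = r_px <= disc_r_mm
    if spec.background_texture_sd > 0:
        texture = gaussian_filter(
            rng.normal(0.0, spec.background_texture_sd * 3.0, size=(n_px, n_px)), 2.0
        ).astype(np.float32)
    else:
        texture = np.zeros((n_px, n_px), dtype=np.float32)
    reflected[disc] = 170.0 + texture[disc]

    # particle parameter draws
    n = spec.n_particles
    areas = np.exp(rng.normal(spec.area_lognorm_mu, spec.area_lognorm_sigma, size=n))
    if spec.min_area_mm2 > 0:
        areas = np.maximum(areas, spec.min_area_mm2)
    is_fibre = rng.random(n) < spec.fraction_fibres
    is_fluor = rng.random(n) < spec.fraction_fluorescent
    aspect = np.where(
        is_fibre, spec.fibre_aspect, rng.uniform(1.0, spec.particle_aspect_max, size=n)
    )
    a_mm = np.sqrt(areas * aspect / math.pi)  # major semi-axis
    b_mm = np.sqrt(areas / (math.pi * aspect))
    angles = rng.uniform(0.0, math.pi, size=n)

    # placement: rejection sampling, no mutual contact, fully inside the disc
    centers: list[Tuple[float, float]] = []
    order = np.argsort(-a_mm)  # place big ones first
    placed_r = []
    max_tries = 400
    for idx in order:
        a = a_mm[idx]
        if a >= disc_r_mm:
            raise PackingError(
                f"particle of area {areas[idx]:.3g} mm^2 does not fit on the disc"
            )
        ok = False
        for _ in range(max_tries):
            rho = disc_r_mm - a - 0.05
            if rho <= 0:
                break
            u = rng.random()
            theta = rng.uniform(0, 2 * math.pi)
            cx = center_mm + rho * math.sqrt(u) * math.cos(theta)
            cy = center_mm + rho * math.sqrt(u) * math.sin(theta)
            clear = True
            for (px, py), pr in zip(centers, placed_r):
                if math.hypot(cx - px, cy - py) < a + pr + spec.min_separation_mm:
                    clear = False
                    break
            if clear:
                centers.append((cx, cy))
                placed_r.append(a)
                ok = True
                break
        if not ok:
            raise PackingError(
                f"could not place {n} particles on a {spec.disc_diameter_mm} mm disc "
                f"(stuck after {len(centers)})"
            )
    # restore draw order
    centers_by_draw = [None] * n
    for slot, idx in enumerate(order):
        centers_by_draw[idx] = centers[slot]

    rows = []
    for i in range(n):
        cx, cy = centers_by_draw[i]
        a, b = a_mm[i], b_mm[i]
        rr, cc = draw_ellipse(
            cy / pitch_mm, cx / pitch_mm, max(a / pitch_mm, 0.5), max(b / pitch_mm, 0.5),
            shape=(n_px, n_px), rotation=angles[i],
        )
        if is_fluor[i]:
            fluor[rr, cc] = rng.uniform(180.0, 230.0)
            reflected[rr, cc] = rng.uniform(200.0, 235.0)  # bright orange on paper
        else:
            reflected[rr, cc] = rng.uniform(45.0, 75.0)  # dark plastic on paper
        perim = _ellipse_perimeter_mm(a, b)
        circ = min(1.0, 4 * math.pi * areas[i] / perim**2) if perim > 0 else 1.0
        rows.append(
            dict(
                id=i, x_mm=cx, y_mm=cy, area_mm2=float(areas[i]),
                circularity=float(circ),
                is_fluorescent=bool(is_fluor[i]), is_fibre=bool(is_fibre[i]),
            )
        )
    columns = ["id", "x_mm", "y_mm", "area_mm2", "circularity", "is_fluorescent", "is_fibre"]
    df = pd.DataFrame(rows, columns=columns)
    return SyntheticSample(
        fluorescence=fluor,
        reflected=reflected,
        pixel_pitch_um=pixel_pitch_um,
        ground_truth=GroundTruth(particles=df),
    )


# ---------------------------------------------------------------------------
# sensor chain
# ---------------------------------------------------------------------------

def vignette_profile(shape: Tuple[int, int], strength: float) -> np.ndarray:
    """cos^4-shaped vignette normalized to 1 at centre, 1-strength at corners."""
    if strength <= 0:
        return np.ones(shape, dtype=np.float64)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    r_corner = math.hypot(cy, cx)
    a = math.acos((1.0 - strength) ** 0.25)
    return np.cos(a * r / r_corner) ** 4


def pose_seed(pose: StagePose, base_seed: int = 0) -> int:
    """Stable per-pose noise seed (< 2^31) so scans replay in any order."""
    key = f"{base_seed}:{pose.x:.4f}:{pose.y:.4f}:{pose.z:.4f}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def _apply_sensor(
    img: np.ndarray, optics: OpticsModel, rng: Optional[np.random.Generator]
) -> np.ndarray:
    """Vignette, noise and quantization (blur/distortion handled upstream)."""
    out = img.astype(np.float64) * vignette_profile(img.shape, optics.vignette_strength)
    if optics.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        out = out + rng.normal(0.0, optics.noise_sd, size=out.shape)
    scale = optics.max_value / 255.0
    out = np.clip(np.rint(out * scale), 0, optics.max_value)
    return out.astype(optics.dtype)


def _distort(img: np.ndarray, k1: float) -> np.ndarray:
    """Apply single-coefficient radial distortion about the image centre.

    Forward model: a scene point at undistorted radius ``r_u`` (px) appears at
    ``r_d = r_u * (1 + k1 * r_u^2)``.  Rendering inverts this per output pixel
    by fixed-point iteration.
    """
    if k1 == 0:
        return img
    from scipy.ndimage import map_coordinates

    h, w = img.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    r_d = np.hypot(dy, dx)
    r_u = r_d.copy()
    for _ in range(5):
        r_u = r_d / (1.0 + k1 * r_u**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(r_d > 0, r_u / r_d, 1.0)
    src_y = cy + dy * ratio
    src_x = cx + dx * ratio
    return map_coordinates(img, [src_y, src_x], order=1, mode="nearest")


def render_tile(
    sample: SyntheticSample,
    pose: StagePose,
    optics: OpticsModel,
    modality: str = "fluorescence",
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render one camera frame centred at ``pose`` (sample-frame mm).

    The pose's x/y map to the sample canvas with (0, 0) at the canvas's
    top-left corner, x along columns and y along rows; the optics chain
    (distortion -> defocus blur -> vignette -> noise -> quantization) is then
    applied.  Raises :class:`CoverageError` if the field of view does not lie
    fully inside the canvas.
    """
    scene = sample.channel(modality)
    pitch = sample.pixel_pitch_um / 1000.0
    th, tw = optics.tile_shape
    top = int(round(pose.y / pitch - th / 2.0))
    left = int(round(pose.x / pitch - tw / 2.0))
    if top < 0 or left < 0 or top + th > scene.shape[0] or left + tw > scene.shape[1]:
        raise CoverageError(
            f"tile at ({pose.x:.2f}, {pose.y:.2f}) mm extends outside the sample canvas"
        )
    sigma = optics.blur_sigma_at(pose.z)
    margin = int(math.ceil(4 * sigma)) + 2 if (sigma > 0 or optics.radial_distortion_k1) else 0
    t0, l0 = max(0, top - margin), max(0, left - margin)
    t1, l1 = min(scene.shape[0], top + th + margin), min(scene.shape[1], left + tw + margin)
    crop = scene[t0:t1, l0:l1].astype(np.float64)
    if optics.radial_distortion_k1:
        crop = _distort(crop, optics.radial_distortion_k1)
    if sigma > 0:
        crop = gaussian_filter(crop, sigma)
    crop = crop[top - t0 : top - t0 + th, left - l0 : left - l0 + tw]
    if rng is None:
        rng = np.random.default_rng(pose_seed(pose, seed))
    return _apply_sensor(crop, optics, rng)


# ---------------------------------------------------------------------------
# QC targets
# ---------------------------------------------------------------------------

def render_slanted_edge(
    optics: OpticsModel,
    angle_deg: float = 5.0,
    shape: Tuple[int, int] = (256, 256),
    levels: Tuple[float, float] = (40.0, 210.0),
    seed: int = 0,
) -> np.ndarray:
    """Render a near-vertical slanted-edge target.

    The edge's blur is applied analytically (an erf edge-spread profile with
    the optics' in-focus sigma, point-sampled at pixel centres) so the target
    carries exactly the Gaussian transfer function of the optics, then passes
    through the vignette/noise/quantization chain.
    """
    if not (2.0 <= angle_deg <= 10.0):
        raise ValueError("slant angle must be in [2, 10] degrees")
    h, w = shape
    lo, hi = levels
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    d = (xx - (w - 1) / 2.0) - (yy - (h - 1) / 2.0) * math.tan(math.radians(angle_deg))
    sigma = optics.blur_sigma_in_focus_px
    if sigma > 0:
        esf = 0.5 * (1.0 + erf(d / (sigma * math.sqrt(2.0))))
    else:
        esf = (d >= 0).astype(np.float64)
    img = lo + (hi - lo) * esf
    return _apply_sensor(img, optics, np.random.default_rng(seed))


def render_wedge(
    optics: OpticsModel,
    layer_spacing_mm: float = 0.05,
    n_layers: int = 20,
    band_px: int = 24,
    width_px: int = 256,
    grating_period_px: float = 4.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render a printed wedge whose layers step through the focus band.

    Layer ``i`` sits at axial offset ``dz = -h + (i + 0.5) * spacing`` from
    best focus (the wedge starts at the lower edge of the focus band), so
    ``round(2h / spacing)`` layers fall inside the band.  Each layer carries a
    fine vertical grating (printed layer ridges) rendered with the defocus
    blur for its height; out-of-band layers lose grating contrast fast, which
    is what the Tenengrad-based DOF estimator keys on.

    Returns (image, per-layer dz in mm).
    """
    if layer_spacing_mm <= 0 or n_layers < 1:
        raise ValueError("layer spacing and count must be positive")
    h_mm = optics.dof_halfwidth_mm
    dz = -h_mm + (np.arange(n_layers) + 0.5) * layer_spacing_mm
    x = np.arange(width_px, dtype=np.float64)
    f = 1.0 / grating_period_px
    bands = []
    for i in range(n_layers):
        sigma = optics.blur_sigma_at(optics.focus_z_mm + dz[i])
        atten = math.exp(-2 * math.pi**2 * sigma**2 * f**2)
        row = 120.0 + 90.0 * atten * np.sin(2 * math.pi * f * x)
        bands.append(np.tile(row, (band_px, 1)))
    img = np.vstack(bands)
    return _apply_sensor(img, optics, np.random.default_rng(seed)), dz


def render_dot_field(
    shape: Tuple[int, int],
    centers_px: np.ndarray,
    optics: OpticsModel,
    dot_radius_px: float = 6.0,
    amplitude: float = 190.0,
    background: float = 25.0,
    blur_sigma_px: Optional[np.ndarray] = None,
    seed: int = 0,
) -> np.ndarray:
    """Render bright blurred-disc dots at ``centers_px`` (array of (x, y)).

    ``blur_sigma_px`` overrides the optics' in-focus sigma, either as a scalar
    or per-dot, which lets tests inject a spatial sharpness ramp.
    """
    h, w = shape
    img = np.full((h, w), background, dtype=np.float64)
    centers = np.atleast_2d(np.asarray(centers_px, dtype=float))
    if blur_sigma_px is None:
        sigmas = np.full(len(centers), optics.blur_sigma_in_focus_px)
    else:
        sigmas = np.broadcast_to(np.asarray(blur_sigma_px, dtype=float), (len(centers),))
    for (cx, cy), sig in zip(centers, sigmas):
        sig = max(sig, 1e-6)
        half = int(math.ceil(dot_radius_px + 5 * sig)) + 1
        y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
        x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
        rho = np.hypot(yy - cy, xx - cx)
        img[y0:y1, x0:x1] += amplitude * 0.5 * (
            1.0 + erf((dot_radius_px - rho) / (sig * math.sqrt(2.0)))
        )
    np.clip(img, 0.0, 255.0, out=img)
    return _apply_sensor(img, optics, np.random.default_rng(seed))


def render_dot_grid(
    optics: OpticsModel,
    grid: Tuple[int, int] = (9, 9),
    pitch_mm: float = 0.5,
    dot_radius_px: float = 6.0,
    shape: Optional[Tuple[int, int]] = None,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render a regular dot-grid target; returns (image, ideal centers).

    Ideal centers are the undistorted (x, y) pixel positions; when the optics
    carry a nonzero ``radial_distortion_k1`` the rendered dots are displaced
    by the forward radial model about the image centre.
    """
    if shape is None:
        shape = optics.tile_shape
    h, w = shape
    ny, nx = grid
    if ny < 1 or nx < 1:
        raise ValueError("grid must have at least one dot per axis")
    step_px = pitch_mm / optics.pitch_mm
    cx0 = (w - 1) / 2.0 - (nx - 1) / 2.0 * step_px
    cy0 = (h - 1) / 2.0 - (ny - 1) / 2.0 * step_px
    gx, gy = np.meshgrid(
        cx0 + np.arange(nx) * step_px, cy0 + np.arange(ny) * step_px
    )
    ideal = np.column_stack([gx.ravel(), gy.ravel()])
    k1 = optics.radial_distortion_k1
    if k1:
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        d = ideal - [cx, cy]
        r2 = (d**2).sum(axis=1, keepdims=True)
        rendered = [cx, cy] + d * (1.0 + k1 * r2)
    else:
        rendered = ideal
    img = render_dot_field(
        shape, rendered, optics, dot_radius_px=dot_radius_px, seed=seed
    )
    return img, ideal


def render_blank_field(
    optics: OpticsModel,
    shape: Optional[Tuple[int, int]] = None,
    level: float = 200.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a uniformly lit blank field (for relative-illumination QC)."""
    if shape is None:
        shape = optics.tile_shape
    img = np.full(shape, level, dtype=np.float64)
    return _apply_sensor(img, optics, np.random.default_rng(seed))
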