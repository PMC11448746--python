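"""Optical and mechanical QC metrics.

Implements the bench characterization suite for a scanning microscope:

- slanted-edge MTF (ISO-12233-style: subpixel edge localization, 4x
  oversampled edge-spread function, Hamming-windowed derivative, DFT),
- relative illumination along the sensor diagonal (vignetting),
- depth of field from a printed wedge via per-layer Tenengrad focus scores,
- grid distortion as residuals after a best-fit similarity transform,
- sharpness falloff along a line of dots (10-90% edge rise distance),
- positional repeatability from dot centroids over a repeated-move series.

All metrics run identically on real tile images and on the synthetic twins
from :mod:`gantryscope.simulate`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates, sobel
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.transform import SimilarityTransform

__all__ = [
    "MTFCurve",
    "IlluminationProfile",
    "DofEstimate",
    "DistortionReport",
    "RepeatabilityReport",
    "mtf_slanted_edge",
    "relative_illumination",
    "estimate_dof_wedge",
    "estimate_distortion",
    "sharpness_profile",
    "positional_repeatability",
    "tenengrad",
]


def tenengrad(image: np.ndarray) -> float:
    """Mean squared gradient magnitude (Sobel) — a standard focus score."""
    img = image.astype(np.float64)
    gx = sobel(img, axis=1)
    gy = sobel(img, axis=0)
    return float(np.mean(gx**2 + gy**2))


# ---------------------------------------------------------------------------
# slanted-edge MTF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MTFCurve:
    """Modulation transfer function of the imaging chain.

    ``frequency_cyc_px`` runs from 0 to Nyquist (0.5 cycles/px) with the
    modulation normalized to 1 at DC; ``frequency_lp_mm`` is populated when
    the sample-plane pixel pitch is known.
    """

    frequency_cyc_px: np.ndarray
    mtf: np.ndarray
    mtf50_cyc_px: float
    edge_angle_deg: float
    frequency_lp_mm: Optional[np.ndarray] = None
    mtf50_lp_mm: Optional[float] = None

    def at(self, freq_cyc_px: float) -> float:
        return float(np.interp(freq_cyc_px, self.frequency_cyc_px, self.mtf))


def _edge_positions(img: np.ndarray) -> np.ndarray:
    """Subpixel edge column per row by centroid of the row derivative."""
    d = np.abs(np.diff(img, axis=1))
    cols = np.arange(d.shape[1]) + 0.5
    w = d - d.min(axis=1, keepdims=True)
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pos = (w * cols).sum(axis=1) / wsum
    return pos


def mtf_slanted_edge(
    image: np.ndarray,
    pixel_pitch_um: Optional[float] = None,
    oversample: int = 4,
) -> MTFCurve:
    """Estimate the MTF from a single near-vertical slanted edge.

    The edge is located per row by the subpixel centroid of the gradient and
    its angle fitted by least squares (2-10 degrees from vertical required);
    pixels are projected along the edge into a 4x-oversampled ESF, which is
    differentiated to the LSF, Hamming-windowed and Fourier-transformed.  The
    magnitude is normalized to 1 at DC and MTF50 found by linear
    interpolation.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("mtf_slanted_edge expects a single-channel image")
    h, w = img.shape
    # use the central band to avoid corner vignetting dominating
    pos = _edge_positions(img)
    rows = np.arange(h)
    good = np.isfinite(pos) & (pos > 2) & (pos < w - 3)
    if good.sum() < h // 2:
        raise ValueError("no consistent edge found in the image")
    slope, intercept = np.polyfit(rows[good], pos[good], 1)
    angle = math.degrees(math.atan(abs(slope)))
    if not (1.0 <= angle <= 12.0):
        raise ValueError(
            f"edge angle {angle:.2f} deg outside the usable 2-10 degree slant range"
        )
    cos_t = math.cos(math.atan(slope))
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dist = (xx - (slope * yy + intercept)) * cos_t
    # bin into an oversampled ESF
    binned = np.round(dist * oversample).astype(int)
    lo = binned.min()
    binned -= lo
    nbins = binned.max() + 1
    sums = np.bincount(binned.ravel(), weights=img.ravel(), minlength=nbins)
    counts = np.bincount(binned.ravel(), minlength=nbins)
    esf = np.full(nbins, np.nan)
    nz = counts > 0
    esf[nz] = sums[nz] / counts[nz]
    if np.isnan(esf).any():
        idx = np.arange(nbins)
        esf = np.interp(idx, idx[nz], esf[nz])
    # trim to a window centred on the transition to limit edge effects
    lsf = np.gradient(esf)
    centre = int(np.argmax(np.abs(lsf)))
    half = min(centre, nbins - 1 - centre)
    half = min(half, 64 * oversample)
    lsf = lsf[centre - half : centre + half + 1]
    lsf = lsf * np.hamming(len(lsf))
    spec = np.abs(np.fft.rfft(lsf))
    if spec[0] == 0:
        raise ValueError("degenerate edge: zero DC response")
    mtf = spec / spec[0]
    freq = np.fft.rfftfreq(len(lsf), d=1.0 / oversample)
    keep = freq <= 0.5 + 1e-12
    freq, mtf = freq[keep], mtf[keep]

    # no crossing below Nyquist means resolution is sampling-limited;
    # report Nyquist itself as the (lower-bound) MTF50
    mtf50 = float(freq[-1])
    below = np.where(mtf < 0.5)[0]
    if below.size:
        i = below[0]
        if i == 0:
            mtf50 = freq[0]
        else:
            f0, f1 = freq[i - 1], freq[i]
            m0, m1 = mtf[i - 1], mtf[i]
            mtf50 = f0 + (0.5 - m0) * (f1 - f0) / (m1 - m0)
    freq_lp_mm = mtf50_lp_mm = None
    if pixel_pitch_um is not None:
        freq_lp_mm = freq * 1000.0 / pixel_pitch_um
        if math.isfinite(mtf50):
            mtf50_lp_mm = mtf50 * 1000.0 / pixel_pitch_um
    return MTFCurve(
        frequency_cyc_px=freq,
        mtf=mtf,
        mtf50_cyc_px=mtf50,
        edge_angle_deg=angle,
        frequency_lp_mm=freq_lp_mm,
        mtf50_lp_mm=mtf50_lp_mm,
    )


# ---------------------------------------------------------------------------
# relative illumination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IlluminationProfile:
    """Intensity along the sensor diagonal as % of the diagonal maximum."""

    position_px: np.ndarray
    relative_percent: np.ndarray

    @property
    def minimum_percent(self) -> float:
        return float(self.relative_percent.min())


def relative_illumination(
    image: np.ndarray, band_px: int = 5
) -> IlluminationProfile:
    """Mean grey value along the corner-to-corner diagonal, normalized to its
    maximum, in percent.  Sampled with bilinear interpolation and averaged
    over a ``band_px``-wide perpendicular band."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("relative_illumination expects a single-channel image")
    if img.max() <= 0:
        raise ValueError("zero image: relative illumination undefined")
    h, w = img.shape
    n = int(math.hypot(h - 1, w - 1)) + 1
    t = np.linspace(0.0, 1.0, n)
    ry, rx = t * (h - 1), t * (w - 1)
    # unit perpendicular to the diagonal
    norm = math.hypot(h - 1, w - 1)
    py, px = -(w - 1) / norm, (h - 1) / norm
    offsets = np.arange(band_px) - (band_px - 1) / 2.0
    acc = np.zeros(n)
    for o in offsets:
        yy = np.clip(ry + o * py, 0, h - 1)
        xx = np.clip(rx + o * px, 0, w - 1)
        acc += map_coordinates(img, [yy, xx], order=1)
    prof = acc / band_px
    rel = 100.0 * prof / prof.max()
    return IlluminationProfile(position_px=t * norm, relative_percent=rel)


# ---------------------------------------------------------------------------
# wedge depth of field
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DofEstimate:
    dof_mm: float
    n_in_focus: int
    n_layers: int
    layer_scores: np.ndarray
    saturated: bool  # every layer in focus: the wedge did not bracket the DOF


def estimate_dof_wedge(
    image: np.ndarray,
    layer_spacing_mm: float,
    n_layers: int,
    focus_fraction: float = 0.5,
) -> DofEstimate:
    """Depth of field from a wedge image: layers with Tenengrad score at or
    above ``focus_fraction`` of the best layer count as in focus and
    DOF = count x spacing.

    The image is split into ``n_layers`` equal horizontal bands (one per
    printed layer).  If every layer scores in focus the wedge did not bracket
    the focus range and the estimate is flagged ``saturated``.
    """
    if layer_spacing_mm <= 0:
        raise ValueError("layer spacing must be positive")
    if n_layers < 3:
        raise ValueError("need at least 3 wedge layers to estimate DOF")
    img = np.asarray(image, dtype=np.float64)
    bounds = np.linspace(0, img.shape[0], n_layers + 1).astype(int)
    trim = 2  # keep band-boundary gradients out of the scores
    scores = np.array(
        [
            tenengrad(img[max(b0 + trim, 0) : max(b1 - trim, b0 + trim + 1)])
            for b0, b1 in zip(bounds[:-1], bounds[1:])
        ]
    )
    n_in_focus = int((scores >= focus_fraction * scores.max()).sum())
    return DofEstimate(
        dof_mm=n_in_focus * layer_spacing_mm,
        n_in_focus=n_in_focus,
        n_layers=n_layers,
        layer_scores=scores,
        saturated=n_in_focus == n_layers,
    )


# ---------------------------------------------------------------------------
# dot detection (shared by distortion / sharpness / repeatability)
# ---------------------------------------------------------------------------

def _detect_dots(image: np.ndarray, min_area_px: int = 9) -> np.ndarray:
    """Bright-dot centers (x, y) by intensity-weighted centroid."""
    img = np.asarray(image, dtype=np.float64)
    if img.max() == img.min():
        return np.empty((0, 2))
    thr = threshold_otsu(img)
    labels = sk_label(img > thr, connectivity=2)
    centers = []
    for region in regionprops(labels, intensity_image=img):
        if region.area < min_area_px:
            continue
        cy, cx = region.centroid_weighted
        centers.append((cx, cy))
    return np.asarray(centers, dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class DistortionReport:
    deviations_px: np.ndarray  # per-dot residual after similarity fit
    max_deviation_px: float
    mean_deviation_px: float
    n_dots: int
    scale: float
    rotation_deg: float


def estimate_distortion(
    image: np.ndarray, ideal_centers: np.ndarray
) -> DistortionReport:
    """Residual dot deviations after the best-fit similarity transform.

    A similarity (rotation + isotropic scale + shift) fit maps the ideal grid
    onto the detected intensity centroids; true lens distortion survives as
    the residual.  Requires at least 9 detected dots and a one-to-one match.
    """
    ideal = np.asarray(ideal_centers, dtype=float)
    detected = _detect_dots(image)
    if len(detected) < 9:
        raise ValueError(f"only {len(detected)} dots detected; need at least 9")
    if len(detected) != len(ideal):
        raise ValueError(
            f"dot-count mismatch: {len(detected)} detected vs {len(ideal)} expected"
        )
    # one-to-one matching by minimum total distance; a coarse normalization
    # (centroid + RMS scale) plus match/fit iterations makes the pairing
    # robust to a global rotation/scale/shift of the supplied ideal grid
    from scipy.optimize import linear_sum_assignment
    from scipy.spatial.distance import cdist

    def _fit(src, dst):
        if hasattr(SimilarityTransform, "from_estimate"):
            tf = SimilarityTransform.from_estimate(src, dst)
            if not tf:
                raise ValueError("similarity transform estimation failed")
            return tf
        tf = SimilarityTransform()
        if not tf.estimate(src, dst):
            raise ValueError("similarity transform estimation failed")
        return tf

    def _normalized(pts):
        centred = pts - pts.mean(axis=0)
        return centred / np.sqrt((centred**2).sum(axis=1).mean())

    ri, ci = linear_sum_assignment(cdist(_normalized(ideal), _normalized(detected)))
    matched = detected[ci[np.argsort(ri)]]
    for _ in range(5):
        tf = _fit(ideal, matched)
        ri, ci = linear_sum_assignment(cdist(tf(ideal), detected))
        new_matched = detected[ci[np.argsort(ri)]]
        if np.array_equal(new_matched, matched):
            break
        matched = new_matched
    tf = _fit(ideal, matched)
    predicted = tf(ideal)
    dev = np.linalg.norm(matched - predicted, axis=1)
    return DistortionReport(
        deviations_px=dev,
        max_deviation_px=float(dev.max()),
        mean_deviation_px=float(dev.mean()),
        n_dots=len(dev),
        scale=float(tf.scale),
        rotation_deg=float(math.degrees(tf.rotation)),
    )


def sharpness_profile(
    image: np.ndarray,
    row: Optional[int] = None,
    band_px: int = 40,
) -> pd.DataFrame:
    """Per-dot edge steepness along a horizontal line through the image.

    Dots whose centroid lies within ``band_px`` of the line are profiled
    through their own centre row; steepness is the 10-90% rise distance of the
    left edge of the dot (smaller = sharper).  Returns a DataFrame with
    ``position_x_px``, ``rise_10_90_px`` and ``steepness`` (its reciprocal);
    empty (with a warning) when the line crosses no dots.
    """
    img = np.asarray(image, dtype=np.float64)
    if row is None:
        row = img.shape[0] // 2
    dots = _detect_dots(img)
    dots = dots[np.abs(dots[:, 1] - row) <= band_px] if len(dots) else dots
    records = []
    for cx, cy in dots:
        r = int(round(cy))
        prof = img[r]
        bg = np.percentile(prof, 10)
        peak = prof[int(round(cx))]
        if peak - bg < 1:
            continue
        lo_level = bg + 0.1 * (peak - bg)
        hi_level = bg + 0.9 * (peak - bg)
        # walk left from the centre: nearest drop below 10%, then the last
        # 90% crossing before it — keeps the measurement local to this dot
        x = int(round(cx))
        seg = prof[: x + 1]
        below_lo = np.where(seg <= lo_level)[0]
        if not below_lo.size:
            continue
        x_lo = below_lo[-1]
        above_hi = np.where(seg[x_lo:] >= hi_level)[0]
        if not above_hi.size:
            continue
        x_hi = x_lo + above_hi[0]

        def _cross(level: float, i0: int, i1: int) -> float:
            if seg[i1] == seg[i0]:
                return float(i1)
            return i0 + (level - seg[i0]) / (seg[i1] - seg[i0]) * (i1 - i0)

        lo_x = _cross(lo_level, x_lo, x_lo + 1)
        hi_x = _cross(hi_level, x_hi - 1, x_hi) if x_hi > 0 else float(x_hi)
        rise = max(hi_x - lo_x, 1e-6)
        records.append(
            {"position_x_px": cx, "rise_10_90_px": rise, "steepness": 1.0 / rise}
        )
    if not records:
        warnings.warn("no dots found on the profile line", stacklevel=2)
        return pd.DataFrame(columns=["position_x_px", "rise_10_90_px", "steepness"])
    df = pd.DataFrame.from_records(records).sort_values("position_x_px")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# positional repeatability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatabilityReport:
    """Per-frame dot-centroid deviations from the per-group mean, in um."""

    deviations_um: pd.DataFrame  # frame, group, dx_um, dy_um
    max_abs_deviation_um: float
    n_moves: int
    excluded_frames: List[int]


def positional_repeatability(
    images: Sequence[np.ndarray],
    pixel_pitch_um: float,
    groups: Optional[Sequence] = None,
) -> RepeatabilityReport:
    """Stage repeatability from a dot imaged over a repeated-move series.

    The dot nearest the image centre is localized in each frame by subpixel
    intensity centroid; frames are grouped by nominal pose (``groups``
    defaults to a single group) and each frame's deviation is its centre
    minus the group mean, scaled by the pixel pitch.  Frames where no dot is
    found are excluded and reported.
    """
    if pixel_pitch_um <= 0:
        raise ValueError("pixel pitch must be positive")
    images = list(images)
    if groups is None:
        groups = [0] * len(images)
    if len(groups) != len(images):
        raise ValueError("groups must match the number of images")
    rows = []
    excluded = []
    for i, img in enumerate(images):
        dots = _detect_dots(img)
        if len(dots) == 0:
            excluded.append(i)
            continue
        h, w = np.asarray(img).shape[:2]
        centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        cx, cy = dots[np.argmin(np.linalg.norm(dots - centre, axis=1))]
        rows.append({"frame": i, "group": groups[i], "cx_px": cx, "cy_px": cy})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no frame contained a detectable dot")
    for axis in ("cx_px", "cy_px"):
        df[axis.replace("c", "d").replace("_px", "_um")] = (
            df[axis] - df.groupby("group")[axis].transform("mean")
        ) * pixel_pitch_um
    dev = df[["frame", "group", "dx_um", "dy_um"]]
    max_abs = float(np.abs(dev[["dx_um", "dy_um"]].to_numpy()).max())
    return RepeatabilityReport(
        deviations_um=dev,
        max_abs_deviation_um=max_abs,
        n_moves=len(images),
        excluded_frames=excluded,
    )
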