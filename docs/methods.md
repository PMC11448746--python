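# Methods

## The instrument model

`gantryscope` targets scanning microscopes built on consumer 3D-printer
gantries: the printer's stepper-driven stage carries a camera + objective
over a stationary sample (typically a 90 mm filter paper bearing stained
microplastic particles), acquiring a grid of overlapping fields that are
later stitched and quantified.  The stage speaks Marlin-dialect G-code over
serial; the toolkit assumes absolute positioning (`G90` is issued on
connect), one `ok` acknowledgement per command, and an `M400` motion-complete
sync before every capture, followed by a configurable settle delay (default
0.5 s on real hardware, 0 on the simulator).  G-code coordinates are
formatted to 0.01 mm; since stage repeatability is on the micrometre scale,
positioning error is modelled in the *truth pose* of the virtual stage rather
than in the command stream.

### Stage error model

The virtual stage adds to every commanded move (a) independent Gaussian
jitter per axis, `jitter_sd_um` (default 0), and (b) backlash: when the last
move along an axis was in the negative direction, the truth position lags the
command by `backlash_um` (default 0).  A fixed seed replays an identical
error sequence.  Physical units of this class of stage show max deviations
within ±4 µm over repeated 6 mm moves, i.e. jitter on the order of 1–2 µm.

## Synthetic optics/sensor chain

Every rendered image passes, in order:

1. **Radial distortion**: one-coefficient model `r_d = r_u (1 + k1 r_u²)`
   about the image centre, inverted per output pixel by fixed-point
   iteration.  Default `k1 = 0` (measured systems show sub-2-px edge
   deviations).
2. **Defocus blur**: Gaussian with
   `σ(Δz) = σ₀ · (1 + s · max(0, |Δz|/h − 1))`, where `σ₀` is the in-focus
   blur (default 1 px), `h` the depth-of-field half-width (default 0.25 mm,
   i.e. a 0.5 mm focus band) and `s` the focus-falloff slope (default 8).
   Inside the band the blur is constant; beyond it, it grows linearly.  The
   slope is deliberately steep: a wedge layer one spacing beyond the band
   must lose most of its fine-texture contrast, as a visual "in focus"
   judgement implies.  This is a phenomenological model — no PSF physics is
   claimed, only a monotone, band-limited focus behaviour.
3. **Vignette**: `cos⁴(a·r̂)` with `a` chosen so the corner intensity is
   `1 − vignette_strength` of the centre (default strength 0.05; measured
   systems show relatively even illumination).
4. **Sensor noise**: additive Gaussian, `noise_sd` grey levels (default 2).
5. **Quantization** to `bit_depth` (default 8).

Noise streams are derived from the pose (`crc32` of the quantized
coordinates mixed with a base seed), so a scan is bit-reproducible in any
acquisition order, and a scanned tile is bit-identical to a direct
`render_tile` call at the same pose.

**Pixel pitch.** The default sample-plane pitch is 6.45 µm/px after 4×
sensor binning, a calibration default chosen for internal consistency: it
makes a 1014 × 760 binned frame span 6.54 × 4.90 mm, slightly more than the
6.2 × 4.5 mm steps used for whole-filter scans, giving the positive overlap
stitching requires.  Real instruments must calibrate this value; every
physical-unit output (mm², µm, lp/mm) scales through it, while MTF curves are
always also reported in cycles/px, which needs no calibration.

### Synthetic samples

`render_sample` draws particles as filled rotated ellipses (fibres are
high-aspect ellipses) on a filter disc, with log-normal areas (defaults
µ = −2.81, σ = 1.63 in mm², i.e. median ≈ 0.06 mm² and quartile ratio ≈ 3,
matching particle-size summaries from environmental filter scans), placed by
rejection sampling with no mutual contact.  Fluorescent particles are bright
(180–230) on a near-black (5) background in the fluorescence channel; in the
reflected channel all particles sit on textured bright paper (170 ± texture),
dark plastics darker and fluorescent-orange ones brighter.  Ground truth
(analytic per-particle area, Ramanujan-perimeter circularity, centroid,
fluorescence flag) is exact by construction; the rasterized particle differs
from the analytic area only by pixelation (a few per cent at ≥5 px
equivalent diameter).

What the generator does **not** emulate: fluorescence photometry and dye
chemistry, spectral illumination, organic debris and staining artefacts,
out-of-plane particles, illumination drift between tiles, and curved or
overlapping fibres.  Tests passing on the twin therefore demonstrate the
correctness of the *pipeline mechanics* (geometry, thresholding behaviour,
morphometrics, error propagation), not detection performance on real
environmental samples.

### QC targets

- **Slanted edge**: an erf edge profile with the optics' in-focus σ applied
  analytically at pixel centres (avoiding double pixel-aperture effects), so
  the target carries exactly the Gaussian transfer function — this is what
  lets the MTF estimator be validated against the closed form
  `exp(−2π²σ²f²)`.
- **Wedge**: `n` horizontal bands, one per printed layer, each carrying a
  fine vertical grating (period 4 px — the printed layer ridges) attenuated
  by the defocus blur at that layer's height.  Layer `i` sits at
  `Δz = −h + (i + 0.5)·spacing`: the wedge starts at the lower focus edge, so
  `round(2h/spacing)` layers fall inside the band (10 at 0.05 mm spacing and
  5 at 0.1 mm for the default 0.5 mm band — the spacing-invariance the DOF
  estimator must reproduce).
- **Dot grid / blank field**: blurred-disc dots (erf radial profile) at known
  centres, displaced by the forward radial model when `k1 ≠ 0`; a uniform
  field for illumination profiling.

## Estimators

**Slanted-edge MTF.**  Per-row subpixel edge localization by gradient
centroid; least-squares edge angle (2–10° slant required); projection of all
pixels onto the edge normal into a 4×-oversampled ESF; derivative to LSF,
trimmed to a window centred on the peak; Hamming window; `|rfft|` normalized
at DC; frequencies reported to Nyquist (0.5 cycles/px).  MTF50 by linear
interpolation; when the curve never crosses 0.5 below Nyquist the system is
sampling-limited and Nyquist is reported as a lower bound.

**Relative illumination.**  Mean grey value along the corner-to-corner
diagonal (bilinear sampling, 5 px perpendicular band), as % of the diagonal
maximum.

**Wedge DOF.**  The image is split into `n_layers` equal bands; per-band
sharpness is the Tenengrad score (mean squared Sobel gradient, 2 px band-edge
trim).  Layers scoring ≥ 50 % of the best layer count as in focus;
DOF = count × spacing.  The 50 % criterion is configurable
(`focus_fraction`); with the steep defocus slope the score gap between
in-band and out-of-band layers is large, so the estimate is insensitive to
the exact fraction.  If every layer is in focus the wedge did not bracket the
focus range and the result is flagged `saturated`.

**Distortion.**  Dots by Otsu threshold + intensity-weighted centroid;
one-to-one matching to the reference grid by minimum-cost assignment on
centroid-and-scale-normalized coordinates, refined by a few match/fit
iterations (robust to a few degrees of grid rotation and arbitrary
scale/shift); a similarity transform (not affine, so genuine lens distortion
is not absorbed) fitted to the matched pairs; residual per-dot deviations
reported.  On a zero-distortion grid with 2-grey-level noise the residual
ceiling is ≈ 0.1 px, far inside the 2 px bound expected of the physical
instrument.

**Sharpness profile.**  For each dot whose centroid lies near the probe
line, the 10–90 % rise distance of its left edge (locally: nearest 10 %
point, then the following 90 % crossing), with the erf relationship
`rise = 2.563 σ` used for validation.

**Repeatability.**  Dot nearest the frame centre per image by subpixel
intensity centroid; frames grouped by nominal pose; deviation = centroid −
group mean, scaled by the pixel pitch.  Centroid localization noise
contributes ≈ 0.3 µm at the default pitch — well below the ±4 µm bound a
healthy stage must meet — so the metric is limited by the stage, not the
estimator.  Frames without a detectable dot are excluded and reported.

## Quantification conventions

- **Threshold**: iterative intermeans / isodata (the fixed point
  `T = (mean(I<T) + mean(I≥T))/2`, the "Default" method of common
  image-analysis software), via `skimage.filters.threshold_isodata`, on the
  blurred image; optional fixed manual override.  Foreground is
  above-threshold for fluorescence, below-threshold (configurable polarity)
  for dark particles on bright paper.
- **Degenerate-image guards**: an automatic threshold is only accepted if the
  image's peak rises `min_dynamic_range` (default 8 grey levels) beyond its
  median *and* the resulting two classes differ by at least that much in
  mean; otherwise the mask is empty with a warning.  Without this, a blank
  noisy tile — or a tile containing only the blur penumbra of a particle just
  outside the field — would have half its noise called foreground by the
  per-tile threshold of the lightweight method.
- **Perimeter**: the crack-weighted boundary estimator of
  `skimage.regionprops` (straight 1, diagonal √2 weighting).  Bit-exact
  parity with any particular desktop software's measurements is explicitly
  not promised; circularity `4πA/P²` is clipped at 1.
- **Connectivity**: 8-connected components; sub-`min_particle_area` components
  dropped.
- **Quartiles**: linear interpolation (type 7).
- **Blur σ = 12 px** is interpreted at the 4×-binned acquisition resolution;
  coarser synthetic scenes scale it down proportionally.
- **Lightweight vs full**: the per-tile method crops each tile's trailing
  overlap (rightmost columns, top rows), thresholds independently, and sums
  foreground areas.  Border-spanning particles and per-tile thresholds make
  it systematically ≤ the stitched global analysis — the direction observed
  on real whole-filter scans — but the split between the two causes cannot be
  settled by the simulator alone.

## Stitching

Tiles are placed at `(pose − min pose)/pitch` rounded to whole pixels; no
sub-pixel resampling, so no intensity interpolation precedes thresholding.
Overlap policies: `last-wins` (default), `feather` (tent-weighted blend, for
display), `crop` (trailing-overlap trim, conserves area for quantification).
Optional refinement registers adjacent overlap strips (≥ 8 px) by phase
cross-correlation, clamped to `max_refine_shift` (featureless or out-of-range
strips keep the stage offset with a warning), propagating corrections along
rows then chaining row anchors.  On simulator output with exact pitch the
zero-overlap mosaic reconstructs the source scene pixel-exactly.

## Problem sizes and tolerances in the test suite

The suite runs entirely on the synthetic twin at desk scale: 10 mm discs at
20 µm/px (500–600 px canvases), 3 × 3 scan plans, 9 × 9 dot grids, 58-frame
repeatability series, and 100-seed recovery sweeps for the particle
count/area properties (exact count and ≤10 % total-area error required on
≥95 % of seeds, under the stated conditions: compact well-separated particles
of ≥ 5 px equivalent diameter at SNR ≥ 10).  MTF agreement with the Gaussian
closed form is required within 0.05 modulation over (0, 0.25] cycles/px for
σ ∈ {1, 2, 4} px.  Whole-pixel mosaic refinement is asserted to ±1 px.

## Known limitations

- The serial transport is written against pyserial's interface but is
  exercised only through the virtual stage; real-hardware timing (settle
  behaviour, firmware chatter) is untested here.
- Offset refinement is a chain propagation, not a global bundle adjustment;
  a failed link falls back to stage coordinates for that pair.
- Exposure and white-balance settings are pass-through metadata; the
  simulator does not model radiometry.
- `x_win`/`y_win` are interpreted as field *counts* (18 × 6.2 mm ≈ 112 mm
  spans a 90 mm filter, consistent with counts); a window-extent
  interpretation would require dividing by the step first.
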