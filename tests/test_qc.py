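"""Optical/mechanical QC metrics against closed forms and the simulator."""

import math
import warnings

import numpy as np
import pytest
from skimage.transform import SimilarityTransform

from gantryscope.motion import StagePose, StageErrorModel, VirtualStage
from gantryscope import motion
from gantryscope.qc import (
    estimate_distortion,
    estimate_dof_wedge,
    mtf_slanted_edge,
    positional_repeatability,
    relative_illumination,
    sharpness_profile,
)
from gantryscope.simulate import (
    OpticsModel,
    render_blank_field,
    render_dot_field,
    render_dot_grid,
    render_slanted_edge,
    render_wedge,
)


def clean_optics(**kw) -> OpticsModel:
    base = dict(vignette_strength=0.0, noise_sd=0.0, bit_depth=16)
    base.update(kw)
    return OpticsModel(**base)


class TestMTF:
    @pytest.mark.parametrize("sigma", [1.0, 2.0, 4.0])
    def test_gaussian_edge_matches_closed_form(self, sigma):
        """MTF of a Gaussian-blurred edge is exp(-2 pi^2 sigma^2 f^2)
        within 0.05 modulation over f in (0, 0.25] cycles/px."""
        img = render_slanted_edge(
            clean_optics(blur_sigma_in_focus_px=sigma), angle_deg=5.0, shape=(300, 300)
        )
        curve = mtf_slanted_edge(img)
        f = curve.frequency_cyc_px
        sel = (f > 0) & (f <= 0.25)
        ideal = np.exp(-2 * math.pi**2 * sigma**2 * f[sel] ** 2)
        assert np.abs(curve.mtf[sel] - ideal).max() <= 0.05

    def test_gaussian_sigma2_mtf50(self):
        """Closed form: MTF50 = sqrt(ln2/2)/(pi*sigma) ~ 0.094 cycles/px."""
        img = render_slanted_edge(
            clean_optics(blur_sigma_in_focus_px=2.0), angle_deg=5.0, shape=(300, 300)
        )
        curve = mtf_slanted_edge(img)
        assert curve.mtf50_cyc_px == pytest.approx(
            math.sqrt(math.log(2) / 2) / (math.pi * 2.0), rel=0.05
        )

    def test_hard_edge_is_sampling_limited(self):
        img = render_slanted_edge(
            clean_optics(blur_sigma_in_focus_px=0.0), angle_deg=5.0, shape=(300, 300)
        )
        curve = mtf_slanted_edge(img)
        assert curve.mtf50_cyc_px > 0.4

    def test_180_degree_rotation_invariance(self):
        img = render_slanted_edge(
            clean_optics(blur_sigma_in_focus_px=2.0, noise_sd=1.0), shape=(200, 200)
        )
        a = mtf_slanted_edge(img)
        b = mtf_slanted_edge(img[::-1, ::-1])
        assert np.allclose(a.mtf, b.mtf, atol=1e-6)

    def test_monotone_after_smoothing_for_gaussian_system(self):
        img = render_slanted_edge(
            clean_optics(blur_sigma_in_focus_px=2.0), shape=(300, 300)
        )
        curve = mtf_slanted_edge(img)
        m = curve.mtf
        smooth = np.convolve(m, np.ones(3) / 3, mode="valid")
        assert np.all(np.diff(smooth) <= 1e-3)

    def test_lp_mm_axis_requires_pitch(self):
        img = render_slanted_edge(clean_optics(blur_sigma_in_focus_px=1.0))
        assert mtf_slanted_edge(img).frequency_lp_mm is None
        withp = mtf_slanted_edge(img, pixel_pitch_um=6.45)
        assert withp.mtf50_lp_mm == pytest.approx(
            withp.mtf50_cyc_px * 1000 / 6.45
        )

    def test_featureless_image_rejected(self):
        with pytest.raises(ValueError):
            mtf_slanted_edge(np.full((100, 100), 80.0))


class TestRelativeIllumination:
    def test_uniform_image_is_100_everywhere(self):
        prof = relative_illumination(np.full((120, 160), 55.0))
        assert np.allclose(prof.relative_percent, 100.0)

    def test_vignette_strength_sets_corner_percentage(self):
        optics = OpticsModel(vignette_strength=0.2, noise_sd=0.0)
        blank = render_blank_field(optics, shape=(200, 300))
        prof = relative_illumination(blank)
        assert prof.relative_percent[0] == pytest.approx(80.0, abs=1.5)
        assert prof.relative_percent.max() == 100.0

    def test_rotation_reverses_profile(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(50, 200, (80, 120))
        a = relative_illumination(img).relative_percent
        b = relative_illumination(np.ascontiguousarray(img[::-1, ::-1])).relative_percent
        assert np.allclose(a, b[::-1], atol=1e-6)

    def test_zero_image_rejected(self):
        with pytest.raises(ValueError):
            relative_illumination(np.zeros((50, 50)))


class TestWedgeDOF:
    def test_replication_fixture_reports_half_millimetre(self):
        """0.05 mm layers, 0.25 mm focus half-width: 10 layers in focus."""
        optics = OpticsModel()  # defaults == replication fixture
        img, _ = render_wedge(optics, 0.05, 20, seed=2)
        est = estimate_dof_wedge(img, 0.05, 20)
        assert est.n_in_focus == 10
        assert est.dof_mm == pytest.approx(0.5)
        assert not est.saturated

    def test_dof_invariant_to_layer_spacing(self):
        """Same optics at 0.1 mm spacing: 5 layers, same 0.5 mm DOF."""
        optics = OpticsModel()
        img, _ = render_wedge(optics, 0.1, 20, seed=2)
        est = estimate_dof_wedge(img, 0.1, 20)
        assert est.n_in_focus == 5
        assert est.dof_mm == pytest.approx(0.5)

    def test_all_sharp_wedge_saturates(self):
        optics = OpticsModel(dof_halfwidth_mm=100.0)  # effectively infinite DOF
        img, _ = render_wedge(optics, 0.05, 12, seed=2)
        est = estimate_dof_wedge(img, 0.05, 12)
        assert est.saturated
        assert est.dof_mm == pytest.approx(12 * 0.05)

    def test_too_few_layers_rejected(self):
        with pytest.raises(ValueError):
            estimate_dof_wedge(np.zeros((60, 60)), 0.05, 2)


class TestDistortion:
    def test_zero_distortion_with_noise_stays_under_2px(self):
        img, ideal = render_dot_grid(
            OpticsModel(noise_sd=2.0, radial_distortion_k1=0.0), grid=(9, 9), seed=1
        )
        report = estimate_distortion(img, ideal)
        assert report.n_dots == 81
        assert report.max_deviation_px < 2.0

    def test_injected_barrel_model_recovered(self):
        """Residual pattern after the similarity fit matches the injected
        radial model's own post-fit residuals (corr > 0.95) and exceeds the
        zero-distortion noise floor."""
        k1 = 1e-7
        optics = OpticsModel(noise_sd=2.0, radial_distortion_k1=k1)
        img, ideal = render_dot_grid(optics, grid=(9, 9), seed=1)
        report = estimate_distortion(img, ideal)
        h, w = img.shape
        c = np.array([(w - 1) / 2, (h - 1) / 2])
        d = ideal - c
        exact = c + d * (1 + k1 * (d**2).sum(axis=1, keepdims=True))
        if hasattr(SimilarityTransform, "from_estimate"):
            tf = SimilarityTransform.from_estimate(ideal, exact)
        else:
            tf = SimilarityTransform()
            tf.estimate(ideal, exact)
        model_resid = np.linalg.norm(exact - tf(ideal), axis=1)
        corr = np.corrcoef(report.deviations_px, model_resid)[0, 1]
        assert corr > 0.95
        img0, ideal0 = render_dot_grid(
            OpticsModel(noise_sd=2.0, radial_distortion_k1=0.0), grid=(9, 9), seed=1
        )
        assert report.max_deviation_px > 2 * estimate_distortion(img0, ideal0).max_deviation_px

    def test_ideal_centers_as_detected_give_zero(self):
        """Identity: feeding a perfect noiseless grid leaves ~0 residual."""
        img, ideal = render_dot_grid(
            OpticsModel(noise_sd=0.0, vignette_strength=0.0), grid=(5, 5), seed=0
        )
        report = estimate_distortion(img, ideal)
        assert report.max_deviation_px < 0.05

    def test_residual_invariant_to_global_rotation_scale(self):
        """A global similarity applied to the reference grid (a few degrees
        of mounting rotation, arbitrary scale and shift) is absorbed by the
        fit and leaves the residuals unchanged."""
        img, ideal = render_dot_grid(OpticsModel(noise_sd=2.0), grid=(7, 7), seed=3)
        report = estimate_distortion(img, ideal)
        tf = SimilarityTransform(scale=1.3, rotation=0.05, translation=(5, -9))
        report_tf = estimate_distortion(img, tf(ideal))
        assert report_tf.max_deviation_px == pytest.approx(
            report.max_deviation_px, abs=0.05
        )

    def test_too_few_dots_rejected(self):
        img, ideal = render_dot_grid(OpticsModel(noise_sd=0.0), grid=(2, 2), seed=0)
        with pytest.raises(ValueError, match="dots"):
            estimate_distortion(img, ideal)


class TestSharpnessProfile:
    OPTICS = OpticsModel(noise_sd=1.0, vignette_strength=0.0)
    CENTERS = [(40 + 60 * i, 100) for i in range(5)]

    def test_uniform_blur_constant_steepness(self):
        img = render_dot_field(
            (200, 360), self.CENTERS, self.OPTICS, dot_radius_px=8,
            blur_sigma_px=2.0, seed=2,
        )
        df = sharpness_profile(img, row=100)
        assert len(df) == 5
        rise = df.rise_10_90_px.to_numpy()
        assert rise.max() / rise.min() <= 1.10

    def test_blur_ramp_orders_steepness(self):
        """Injected sharpness ramp: rise distance grows with the blur."""
        sigmas = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        img = render_dot_field(
            (200, 360), self.CENTERS, self.OPTICS, dot_radius_px=8,
            blur_sigma_px=sigmas, seed=2,
        )
        df = sharpness_profile(img, row=100)
        rise = df.sort_values("position_x_px").rise_10_90_px.to_numpy()
        assert np.all(np.diff(rise) > 0)
        # 10-90% rise of an erf edge is 2.563 sigma
        assert rise == pytest.approx(2.563 * sigmas, rel=0.15)

    def test_empty_line_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no dots"):
            df = sharpness_profile(np.full((60, 60), 12.0))
        assert df.empty


def dot_series_from_stage(jitter_sd_um, seed, n_moves=58, noise_sd=2.0):
    """Render a dot frame after each of n alternating 6 mm x-moves.

    The dot is fixed on the bed at each endpoint's nominal position, so the
    in-frame dot position reflects only the stage's positioning error."""
    optics = OpticsModel(noise_sd=noise_sd)
    stage = VirtualStage(
        error_model=StageErrorModel(jitter_sd_um=jitter_sd_um, seed=seed)
    )
    pitch = optics.pixel_pitch_sample_um
    frames, groups = [], []
    for i in range(n_moves):
        x = 16.0 if i % 2 == 0 else 10.0
        motion.send(f"G1 X{x:.2f} Y10.00 Z0.00", stage)
        truth = stage.truth_pose
        dx_px = (x - truth.x) * 1000.0 / pitch
        dy_px = (10.0 - truth.y) * 1000.0 / pitch
        frames.append(
            render_dot_field(
                (96, 96), [(48 + dx_px, 48 + dy_px)], optics,
                dot_radius_px=6, seed=seed * 1000 + i,
            )
        )
        groups.append(x)
    return frames, groups, pitch


class TestRepeatability:
    def test_zero_jitter_stays_within_4um(self):
        """Localization-noise ceiling: a perfectly repeatable stage reports
        max |deviation| well inside the +-4 um instrument bound."""
        frames, groups, pitch = dot_series_from_stage(0.0, seed=1)
        report = positional_repeatability(frames, pitch, groups)
        assert report.n_moves == 58
        assert report.max_abs_deviation_um <= 4.0

    def test_injected_jitter_recovered(self):
        """3 um Gaussian jitter: reported max lands in [2, 12] um (i.e.
        between ~0.7 and ~4 sd) for >= 90% of seeds — the estimator neither
        swallows the jitter nor inflates it."""
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            frames, groups, pitch = dot_series_from_stage(3.0, seed=seed)
            report = positional_repeatability(frames, pitch, groups)
            hits += 2.0 <= report.max_abs_deviation_um <= 12.0
        assert hits >= 0.9 * n_seeds

    def test_identical_frames_zero_deviation(self):
        optics = OpticsModel(noise_sd=2.0)
        frame = render_dot_field((64, 64), [(32, 32)], optics, seed=5)
        report = positional_repeatability([frame] * 10, 6.45, [0] * 10)
        assert report.max_abs_deviation_um == 0.0

    def test_dotless_frames_flagged_and_excluded(self):
        optics = OpticsModel(noise_sd=0.0, vignette_strength=0.0)
        good = render_dot_field((64, 64), [(32, 32)], optics, seed=5)
        blank = np.zeros((64, 64), np.uint8)
        report = positional_repeatability([good, blank, good], 6.45, [0, 0, 0])
        assert report.excluded_frames == [1]

    def test_unbiased_mean_deviation(self):
        frames, groups, pitch = dot_series_from_stage(0.0, seed=4)
        report = positional_repeatability(frames, pitch, groups)
        assert abs(report.deviations_um.dx_um.mean()) < 0.2
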