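"""Segmentation, morphometrics and the two quantification tiers."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk, ellipse

from gantryscope.acquire import Tile
from gantryscope.motion import StagePose
from gantryscope.particles import (
    AnalysisConfig,
    analyze_composite,
    label_and_measure,
    segment,
    summarize,
    total_area_lightweight,
)
from gantryscope.planner import ScanPlanSpec, plan_snake
from gantryscope.simulate import render_sample

from conftest import TEST_PITCH_UM, compact_sample_spec, tiles_for_plan

CFG = AnalysisConfig(pixel_pitch_um=TEST_PITCH_UM, blur_sigma=0.0)
CFG_BLUR = AnalysisConfig(pixel_pitch_um=TEST_PITCH_UM, blur_sigma=1.0)


def isodata_oracle(values):
    """Hand iteration of the intermeans fixed point T = (m_lo + m_hi)/2."""
    t = values.mean()
    for _ in range(200):
        lo, hi = values[values < t], values[values >= t]
        t_new = (lo.mean() + hi.mean()) / 2
        if abs(t_new - t) < 1e-6:
            break
        t = t_new
    return t


class TestSegment:
    def test_two_population_threshold_between_means(self):
        img = np.zeros((80, 80))
        img[:, :40] = 50.0
        img[:, 40:] = 200.0
        mask = segment(img, CFG)
        oracle = isodata_oracle(img.ravel())
        assert 50 < oracle < 200
        assert np.array_equal(mask, img > oracle)  # mask = bright population

    def test_constant_image_empty_mask_with_warning(self):
        with pytest.warns(UserWarning, match="dynamic range"):
            mask = segment(np.full((50, 50), 9.0), CFG)
        assert not mask.any()

    def test_dark_polarity_selects_dark_population(self):
        img = np.full((40, 40), 200.0)
        img[10:20, 10:20] = 30.0
        cfg = AnalysisConfig(pixel_pitch_um=TEST_PITCH_UM, blur_sigma=0.0,
                             polarity="dark")
        mask = segment(img, cfg)
        assert mask[15, 15] and not mask[0, 0]

    def test_fixed_threshold(self):
        img = np.tile(np.arange(100, dtype=float), (10, 1))
        cfg = AnalysisConfig(pixel_pitch_um=TEST_PITCH_UM, blur_sigma=0.0,
                             threshold_method="fixed", fixed_threshold=60.0)
        assert segment(img, cfg).sum() == 10 * 39

    def test_synthetic_sample_mask_covers_ground_truth(self):
        """High-SNR fluorescent scene: >=95% of particle pixels recovered,
        <=1% of background misclassified."""
        s = render_sample(compact_sample_spec(seed=7), TEST_PITCH_UM)
        rng = np.random.default_rng(7)
        img = np.clip(
            np.rint(s.fluorescence + rng.normal(0, 2.0, s.fluorescence.shape)),
            0, 255,
        ).astype(np.uint8)
        truth = s.fluorescence > 100
        mask = segment(img, CFG_BLUR)
        assert (mask & truth).sum() >= 0.95 * truth.sum()
        assert (mask & ~truth).sum() <= 0.01 * (~truth).sum()


class TestLabelAndMeasure:
    def test_digital_disc_morphometrics(self):
        mask = np.zeros((60, 60), bool)
        rr, cc = disk((30, 30), 21.5)
        mask[rr, cc] = True
        table = label_and_measure(mask, CFG)
        assert table.n == 1
        row = table.df.iloc[0]
        assert row.area_px == pytest.approx(math.pi * 21**2, rel=0.08)
        assert row.circularity >= 0.9
        assert row.area_mm2 == pytest.approx(row.area_px * (0.02) ** 2)
        assert row.centroid_x_mm == pytest.approx(30 * 0.02, abs=0.02)

    def test_empty_mask_empty_table(self):
        table = label_and_measure(np.zeros((10, 10), bool), CFG)
        assert table.n == 0

    def test_corner_touching_squares_are_one_particle(self):
        mask = np.zeros((20, 20), bool)
        mask[5:10, 5:10] = True
        mask[10:15, 10:15] = True  # touches at one corner: 8-connected
        assert label_and_measure(mask, CFG).n == 1

    def test_foreground_count_equals_mask_sum(self):
        rng = np.random.default_rng(3)
        mask = rng.random((64, 64)) > 0.7
        table = label_and_measure(mask, CFG)
        assert table.df.area_px.sum() == mask.sum()

    def test_min_area_filter(self):
        mask = np.zeros((40, 40), bool)
        mask[5:25, 5:25] = True  # 400 px
        mask[35, 35] = True  # 1 px speck
        cfg = AnalysisConfig(pixel_pitch_um=TEST_PITCH_UM, blur_sigma=0.0,
                             min_particle_area_mm2=0.01)
        assert label_and_measure(mask, cfg).n == 1

    def test_circularity_decreases_with_aspect_ratio(self):
        """Ellipses of fixed area: rounder shapes score higher."""
        circs = []
        for aspect in (1.0, 2.0, 4.0, 8.0):
            mask = np.zeros((300, 300), bool)
            a = 20 * math.sqrt(aspect)
            b = 20 / math.sqrt(aspect)
            rr, cc = ellipse(150, 150, a, b)
            mask[rr, cc] = True
            circs.append(label_and_measure(mask, CFG).df.circularity[0])
        assert all(x > y for x, y in zip(circs, circs[1:]))


class TestSummarize:
    def test_textbook_quartiles(self):
        df = pd.DataFrame({"area_mm2": [1.0, 2, 3, 4], "circularity": [1.0] * 4})
        s = summarize(df)
        assert s["n"] == 4
        assert s["area_mm2"] == {"median": 2.5, "q1": 1.75, "q3": 3.25}

    def test_single_row_collapses_quartiles(self):
        df = pd.DataFrame({"area_mm2": [0.7], "circularity": [0.9]})
        s = summarize(df)
        assert s["area_mm2"]["median"] == s["area_mm2"]["q1"] == s["area_mm2"]["q3"] == 0.7

    def test_empty_reports_absent_not_zero(self):
        s = summarize(pd.DataFrame(columns=["area_mm2", "circularity"]))
        assert s["n"] == 0
        assert s["area_mm2"]["median"] is None

    def test_lognormal_median_matches_closed_form(self):
        """Sample median of 1000 log-normal areas ~ e^mu within 10%."""
        rng = np.random.default_rng(12)
        areas = np.exp(rng.normal(-2.5, 1.0, 1000))
        s = summarize(pd.DataFrame({"area_mm2": areas}), columns=("area_mm2",))
        assert s["area_mm2"]["median"] == pytest.approx(math.exp(-2.5), rel=0.10)


class TestLightweight:
    def test_zero_overlap_noise_free_matches_ground_truth(
        self, small_sample, identity_optics, plan_3x3
    ):
        tiles = tiles_for_plan(small_sample, identity_optics, plan_3x3)
        total = total_area_lightweight(tiles, (0.0, 0.0), CFG_BLUR)
        gt = small_sample.ground_truth.total_fluorescent_area_mm2
        assert total == pytest.approx(gt, rel=0.05)

    def test_all_blank_tiles_give_zero(self):
        blank = np.zeros((100, 100), np.uint8)
        tiles = [
            Tile(image=blank, pose=StagePose(x, 0, 0), row=0, col=i)
            for i, x in enumerate((0.0, 2.0))
        ]
        assert total_area_lightweight(tiles, (0.1, 0.1), CFG_BLUR) == 0.0

    def test_lightweight_not_above_full_pipeline(self, noisy_optics):
        """Per-tile thresholds + border cropping lose area relative to the
        stitched global analysis — the documented direction of disagreement
        between the two tiers."""
        plan = plan_snake(ScanPlanSpec(3, 3, 2.4, 2.4, origin=StagePose(3.4, 3.4, 0)))
        wins = []
        for seed in range(1, 6):
            spec = compact_sample_spec(
                seed=seed, n_particles=15, area_lognorm_mu=-2.0,
                fraction_fibres=0.3, min_separation_mm=0.2,
            )
            s = render_sample(spec, TEST_PITCH_UM)
            tiles = tiles_for_plan(s, noisy_optics, plan)
            from gantryscope.mosaic import MosaicConfig, place_tiles

            comp, _ = place_tiles(tiles, MosaicConfig(pixel_pitch_um=TEST_PITCH_UM))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table, _ = analyze_composite(comp, CFG_BLUR)
            full = table.df.area_mm2.sum() if table.n else 0.0
            lite = total_area_lightweight(tiles, (0.2, 0.2), CFG_BLUR)
            wins.append(lite <= full)
        assert all(wins)

    def test_invalid_overlaps_rejected(self):
        with pytest.raises(ValueError):
            total_area_lightweight([], (1.5, 0.0), CFG)


class TestParticleRecovery:
    def test_count_and_area_recovered_across_seeds(self):
        """Well-separated compact particles (>= 5 px equivalent diameter,
        SNR >= 10): exact count and total area within 10% on >= 95% of
        seeds."""
        exact = 0
        area_ok = 0
        n_seeds = 40
        cfg = AnalysisConfig(pixel_pitch_um=TEST_PITCH_UM, blur_sigma=1.0,
                             min_particle_area_mm2=0.002)
        for seed in range(n_seeds):
            s = render_sample(compact_sample_spec(seed=seed), TEST_PITCH_UM)
            rng = np.random.default_rng(1000 + seed)
            img = np.clip(
                np.rint(s.fluorescence + rng.normal(0, 2.0, s.fluorescence.shape)),
                0, 255,
            ).astype(np.uint8)
            table, _ = analyze_composite(img, cfg)
            gt = s.ground_truth
            exact += table.n == gt.n
            total = table.df.area_mm2.sum() if table.n else 0.0
            area_ok += abs(total - gt.total_area_mm2) <= 0.10 * gt.total_area_mm2
        assert exact >= 0.95 * n_seeds
        assert area_ok >= 0.95 * n_seeds
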