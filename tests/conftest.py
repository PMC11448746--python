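"""Shared fixtures: a desk-scale synthetic instrument.

Scenes are rendered at 20 um/px with a 3 x 3 mm field of view — coarse enough
to keep the suite fast, fine enough that particles span many pixels.
"""

import numpy as np
import pytest

from gantryscope.acquire import CameraSettings, Tile
from gantryscope.motion import StagePose, VirtualStage
from gantryscope.planner import FieldOfView, ScanPlanSpec, plan_snake
from gantryscope.simulate import OpticsModel, SampleSpec, render_sample, render_tile

TEST_PITCH_UM = 20.0
TEST_FOV = FieldOfView(3.0, 3.0)


@pytest.fixture(scope="session")
def identity_optics() -> OpticsModel:
    """No blur, no vignette, no distortion, no noise: tiles are plain crops."""
    return OpticsModel(
        pixel_pitch_sample_um=TEST_PITCH_UM,
        fov=TEST_FOV,
        vignette_strength=0.0,
        noise_sd=0.0,
        blur_sigma_in_focus_px=0.0,
    )


@pytest.fixture(scope="session")
def noisy_optics() -> OpticsModel:
    """Realistic desk-scale optics: mild blur, vignette and sensor noise."""
    return OpticsModel(
        pixel_pitch_sample_um=TEST_PITCH_UM,
        fov=TEST_FOV,
        vignette_strength=0.05,
        noise_sd=2.0,
        blur_sigma_in_focus_px=1.0,
    )


def compact_sample_spec(seed: int, n_particles: int = 10, **overrides) -> SampleSpec:
    """A small fluorescent scene of compact, well-separated particles
    (>= 5 px equivalent diameter at the test pitch, SNR >> 10)."""
    kw = dict(
        disc_diameter_mm=10.0,
        n_particles=n_particles,
        area_lognorm_mu=-3.2,
        area_lognorm_sigma=0.5,
        min_area_mm2=0.012,
        fraction_fluorescent=1.0,
        fraction_fibres=0.0,
        particle_aspect_max=2.0,
        min_separation_mm=0.4,
        seed=seed,
    )
    kw.update(overrides)
    return SampleSpec(**kw)


@pytest.fixture(scope="session")
def small_sample():
    return render_sample(compact_sample_spec(seed=7, n_particles=12), TEST_PITCH_UM)


@pytest.fixture()
def plan_3x3() -> list:
    """3x3 abutting plan centred on the 12 mm sample canvas."""
    return plan_snake(
        ScanPlanSpec(3, 3, 3.0, 3.0, origin=StagePose(3.0, 3.0, 0.0))
    )


def tiles_for_plan(sample, optics, plan, seed: int = 0) -> list:
    """Render tiles directly at the planned poses (no stage in the loop)."""
    return [
        Tile(
            image=render_tile(sample, p.pose, optics, seed=seed),
            pose=p.pose,
            row=p.row,
            col=p.col,
        )
        for p in plan
    ]
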