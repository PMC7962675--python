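"""Shared fixtures: small rendered scenes and the standard benchmark run."""

from __future__ import annotations

import numpy as np
import pytest

from irisvel import (
    GazeEventSpec,
    PipelineConfig,
    SceneConfig,
    build_trajectory,
    render,
    run_pipeline,
)


@pytest.fixture(scope="session")
def benchmark_result():
    """Full standard-benchmark pipeline run (60 s, 20 microsaccades).

    96 fps, 40 px/deg, amplitudes uniform in [0.2, 0.5] deg on the main
    sequence (slope 47/s), fixational drift, default sensor noise,
    sinusoidal 12 px / 1 Hz head motion; fixed seed.  Session-scoped: this
    is the expensive end-to-end run shared by the acceptance tests.
    """
    return run_pipeline(PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def small_scene():
    """1.5 s single-eye scene with one 0.3 deg microsaccade, no head motion."""
    cfg = SceneConfig(n_eyes=1, frame_width=280, frame_height=260, eye_center_y=120)
    events = [GazeEventSpec("microsaccade", onset=0.7, amplitude=0.3, direction=25.0)]
    gaze, realized = build_trajectory(events, 1.5, cfg, drift_sigma=0.05, seed=21)
    frames, truth = render(cfg, gaze, seed=22, events=realized)
    return cfg, frames, truth


@pytest.fixture(scope="session")
def textured_image():
    """Band-pass noise texture image with dense corner features."""
    from scipy import ndimage as ndi

    rng = np.random.default_rng(3)
    raw = rng.standard_normal((220, 220))
    tex = ndi.gaussian_filter(raw, 0.8) - ndi.gaussian_filter(raw, 2.5)
    tex = 0.5 + 0.11 * tex / tex.std()
    return tex.astype(np.float32)
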