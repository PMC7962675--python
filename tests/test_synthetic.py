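"""The synthetic scene generator: textures, kinematics, rendering, head motion."""

import numpy as np
import pytest

from irisvel import (
    GazeEventSpec,
    SceneConfig,
    SimilarityTransform,
    build_trajectory,
    generate_iris_texture,
    make_head_motion,
    render,
)
from irisvel.features import count_keypoints_in_mask


class TestTexture:
    def test_same_seed_bit_identical(self):
        cfg = SceneConfig(texture_seed=5)
        assert np.array_equal(generate_iris_texture(cfg), generate_iris_texture(cfg))

    def test_different_seeds_differ(self):
        t1 = generate_iris_texture(SceneConfig(texture_seed=1))
        t2 = generate_iris_texture(SceneConfig(texture_seed=2))
        assert (t1 != t2).mean() >= 0.01

    def test_annulus_keypoint_density(self):
        """The default texture must feed the tracker >= 50 corner features."""
        cfg = SceneConfig()
        tex = generate_iris_texture(cfg)
        side = tex.shape[0]
        c = (side - 1) / 2
        yy, xx = np.mgrid[0:side, 0:side]
        r = np.hypot(yy - c, xx - c)
        annulus = (r > cfg.pupil_radius + 2) & (r < cfg.iris_radius - 2)
        assert count_keypoints_in_mask(tex, annulus) >= 50

    def test_degenerate_radii_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(iris_radius=10, pupil_radius=12)


class TestTrajectory:
    def test_no_events_no_drift_is_constant(self):
        cfg = SceneConfig()
        gaze, realized = build_trajectory([], 1.0, cfg, drift_sigma=0.0, seed=0)
        assert np.all(gaze == 0.0)
        assert realized == []

    def test_microsaccade_obeys_main_sequence(self):
        """0.3 deg at slope 47 -> peak 14.1 deg/s; displacement integrates exactly."""
        cfg = SceneConfig()
        ev = GazeEventSpec("microsaccade", onset=0.3, amplitude=0.3, direction=0.0)
        assert ev.peak_velocity == pytest.approx(47.0 * 0.3)
        gaze, realized = build_trajectory([ev], 1.0, cfg, drift_sigma=0.0, seed=0)
        increments = np.diff(gaze[:, 0, 0])
        assert abs(increments.sum() - 0.3) < 1e-9
        # discrete peak velocity cannot exceed the analytic peak
        assert increments.max() * cfg.fps <= ev.peak_velocity + 1e-9

    def test_raised_cosine_profile_integral(self):
        """Numerical integration of the velocity profile equals the amplitude."""
        ev = GazeEventSpec("saccade", onset=0.0, amplitude=1.0)
        assert ev.peak_velocity == pytest.approx(47.0)
        t = np.linspace(0.0, ev.duration, 20001)
        vp, td = ev.peak_velocity, ev.duration
        v = 0.5 * vp * (1 - np.cos(2 * np.pi * t / td))
        assert np.trapezoid(v, t) == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(np.gradient(ev.displacement_at(t), t)[2:-2], v[2:-2], atol=1e-3)

    def test_conjugacy_in_binocular_mode(self):
        cfg = SceneConfig(n_eyes=2)
        ev = [GazeEventSpec("microsaccade", onset=0.2, amplitude=0.4, direction=90.0)]
        gaze, _ = build_trajectory(ev, 1.0, cfg, drift_sigma=0.2, seed=4)
        assert np.array_equal(gaze[:, 0], gaze[:, 1])

    def test_eye_offsets_break_conjugacy(self):
        cfg = SceneConfig(n_eyes=2)
        gaze, _ = build_trajectory(
            [], 0.5, cfg, drift_sigma=0.0, seed=0, eye_offsets=np.array([[0.1, 0], [-0.1, 0]])
        )
        assert np.allclose(gaze[:, 0, 0] - gaze[:, 1, 0], 0.2)

    def test_overlapping_events_rejected_with_pairs(self):
        evs = [
            GazeEventSpec("microsaccade", onset=0.30, amplitude=0.3),
            GazeEventSpec("microsaccade", onset=0.31, amplitude=0.3),
        ]
        with pytest.raises(ValueError, match="overlap"):
            build_trajectory(evs, 1.0, SceneConfig(), seed=0)

    def test_event_past_duration_rejected(self):
        ev = [GazeEventSpec("microsaccade", onset=0.99, amplitude=0.3)]
        with pytest.raises(ValueError, match="duration"):
            build_trajectory(ev, 1.0, SceneConfig(), seed=0)


class TestRenderer:
    def _centroid(self, mask):
        ys, xs = np.nonzero(mask)
        return np.array([xs.mean(), ys.mean()])

    def test_static_noiseless_scene_is_constant(self):
        cfg = SceneConfig(n_eyes=1, sensor_noise_sigma=0.0, frame_width=280,
                          frame_height=260, eye_center_y=120)
        gaze = np.zeros((5, 1, 2))
        frames, _ = render(cfg, gaze, seed=0)
        for k in range(1, 5):
            assert np.array_equal(frames[k], frames[0])

    def test_head_translation_moves_iris_centroid(self):
        cfg = SceneConfig(n_eyes=1, sensor_noise_sigma=0.0, frame_width=280,
                          frame_height=260, eye_center_y=120)
        gaze = np.zeros((2, 1, 2))
        hm = [SimilarityTransform.identity(), SimilarityTransform(tx=5.0, ty=0.0)]
        frames, truth = render(cfg, gaze, hm, seed=0)
        d = self._centroid(truth.iris_mask(1, 0)) - self._centroid(truth.iris_mask(0, 0))
        assert np.allclose(d, [5.0, 0.0], atol=0.1)

    def test_gaze_step_converts_at_px_per_degree(self):
        cfg = SceneConfig(n_eyes=1, sensor_noise_sigma=0.0, frame_width=280,
                          frame_height=260, eye_center_y=120)
        gaze = np.zeros((2, 1, 2))
        gaze[1, 0, 0] = 0.25  # deg -> 10 px at 40 px/deg
        frames, truth = render(cfg, gaze, seed=0)
        d = self._centroid(truth.iris_mask(1, 0)) - self._centroid(truth.iris_mask(0, 0))
        assert np.allclose(d, [10.0, 0.0], atol=0.1)

    def test_renderer_linearity_in_px_per_degree(self):
        base = dict(n_eyes=1, sensor_noise_sigma=0.0, frame_width=280,
                    frame_height=260, eye_center_y=120)
        gaze = np.zeros((2, 1, 2))
        gaze[1, 0] = [0.2, 0.1]
        d = {}
        for ppd in (40.0, 80.0):
            cfg = SceneConfig(px_per_degree=ppd, **base)
            _, truth = render(cfg, gaze, seed=0)
            d[ppd] = self._centroid(truth.iris_mask(1, 0)) - self._centroid(
                truth.iris_mask(0, 0)
            )
        assert np.allclose(d[80.0], 2 * d[40.0], atol=0.2)

    def test_out_of_frame_eye_rejected(self):
        cfg = SceneConfig(n_eyes=1, frame_width=280, frame_height=260, eye_center_y=120)
        gaze = np.zeros((1, 1, 2))
        gaze[0, 0, 0] = 10.0  # 400 px off-center
        with pytest.raises(ValueError, match="outside frame"):
            render(cfg, gaze, seed=0)

    def test_ground_truth_lengths_match(self, small_scene):
        _, frames, truth = small_scene
        assert truth.n_frames == len(frames)
        assert len(truth.head_transforms) == len(frames)
        assert len(truth.masks) == len(frames)


class TestHeadMotion:
    def test_zero_amplitude_is_identity(self):
        hm = make_head_motion("sinusoid", 0.0, 1.0, 10, 96.0)
        for t in hm:
            assert np.allclose(t.parameters(), [1, 0, 0, 0], atol=1e-12)

    def test_sinusoid_peak_translation_equals_amplitude(self):
        hm = make_head_motion("sinusoid", 12.0, 1.0, 960, 96.0)
        mags = [np.hypot(t.tx, t.ty) for t in hm]
        assert max(mags) == pytest.approx(12.0, abs=1e-9)
        assert np.allclose(hm[0].parameters(), [1, 0, 0, 0], atol=1e-12)

    def test_random_walk_reproducible(self):
        a = make_head_motion("random_walk", 5.0, 0.0, 50, 96.0, seed=3)
        b = make_head_motion("random_walk", 5.0, 0.0, 50, 96.0, seed=3)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.parameters(), tb.parameters())

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            make_head_motion("sinusoid", -1.0, 1.0, 10, 96.0)
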