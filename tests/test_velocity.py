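"""Velocity extraction: CLAHE, calibration, kinematics, cyclopean combination."""

import numpy as np
import pytest

from irisvel import (
    CalibrationModel,
    MotionSample,
    SceneConfig,
    calibrate,
    clahe_gray,
    cyclopean_speed,
    kinematics_from_motion,
    make_calibration_trajectory,
    render,
    to_velocity,
    track_eye,
)
from irisvel.features import detect_keypoints
from irisvel.velocity import MotionTrace, fill_gaps, integrate_shifts


class TestClahe:
    def test_deterministic_and_shape_preserving(self, textured_image):
        a = clahe_gray(textured_image)
        b = clahe_gray(textured_image)
        assert np.array_equal(a, b)
        assert a.shape == textured_image.shape
        assert a.ndim == 2

    def test_rgb_input_collapsed_to_luma(self, textured_image):
        rgb = np.repeat(textured_image[..., None], 3, axis=-1)
        assert clahe_gray(rgb).shape == textured_image.shape

    def test_equalization_recovers_keypoints_on_low_contrast(self, textured_image):
        """On a low-contrast image CLAHE must not lose detector keypoints."""
        low = 0.5 + (textured_image - 0.5) * 0.15
        n_raw = len(detect_keypoints(low.astype(np.float32)))
        n_eq = len(detect_keypoints(clahe_gray(low).astype(np.float32)))
        assert n_eq >= n_raw


class TestMaskedMatches:
    def test_matches_confined_to_mask(self, textured_image):
        from irisvel import masked_matches

        mask = np.zeros(textured_image.shape, dtype=bool)
        mask[40:120, 40:120] = True
        ms = masked_matches(textured_image, textured_image, mask, mask)
        assert len(ms) > 5
        assert np.all(ms.src[:, 0] >= 39.5) and np.all(ms.src[:, 0] <= 120.5)
        assert np.all(ms.src[:, 1] >= 39.5) and np.all(ms.src[:, 1] <= 120.5)

    def test_empty_mask_rejected(self, textured_image):
        from irisvel import masked_matches

        with pytest.raises(ValueError, match="non-empty"):
            masked_matches(
                textured_image, textured_image, np.zeros(textured_image.shape, bool)
            )


class TestToVelocity:
    CAL = CalibrationModel(gain=np.array([0.1, 0.1]), offset=np.zeros(2), r2=np.ones(2))

    def test_arithmetic(self):
        s = MotionSample(index=0, dx=1.0, dy=0.0, n_matches=20, valid=True)
        assert to_velocity(s, self.CAL, 96.0) == pytest.approx((9.6, 0.0))

    def test_zero_shift_zero_velocity(self):
        s = MotionSample(index=0, dx=0.0, dy=0.0, n_matches=20, valid=True)
        assert to_velocity(s, self.CAL, 96.0) == (0.0, 0.0)

    def test_doubling_fps_doubles_velocity(self):
        s = MotionSample(index=0, dx=0.3, dy=-0.2, n_matches=20, valid=True)
        v96 = np.array(to_velocity(s, self.CAL, 96.0))
        v192 = np.array(to_velocity(s, self.CAL, 192.0))
        assert np.allclose(v192, 2 * v96)

    def test_invalid_sample_gives_gap(self):
        s = MotionSample(index=0, dx=0.0, dy=0.0, n_matches=2, valid=False)
        assert np.isnan(to_velocity(s, self.CAL, 96.0)).all()


class TestGaps:
    def test_short_dropout_bridged_by_hold(self):
        shifts = np.array([[1.0, 0], [np.nan, np.nan], [np.nan, np.nan], [2.0, 0]])
        valid = np.array([True, False, False, True])
        filled, gaps = fill_gaps(shifts, valid, max_gap=3)
        assert np.allclose(filled[1], [1.0, 0]) and np.allclose(filled[2], [1.0, 0])
        assert not gaps.any()

    def test_long_dropout_becomes_nan_gap(self):
        shifts = np.full((6, 2), 1.0)
        valid = np.array([True, False, False, False, False, True])
        filled, gaps = fill_gaps(shifts, valid, max_gap=3)
        assert np.isnan(filled[1:5]).all()
        assert gaps[1:5].all() and not gaps[0] and not gaps[5]

    def test_integration_resumes_after_gap(self):
        shifts = np.array([[1.0, 0], [np.nan, 0], [1.0, 0]])
        pos = integrate_shifts(shifts)
        assert np.allclose(pos[0], 0)
        assert np.isnan(pos[2]).any() or np.isfinite(pos[2]).all()
        assert np.allclose(pos[3], [2.0, 0.0])  # gap contributes zero net motion


class TestCalibrate:
    def make_schedule(self, targets):
        return [
            {"t0": i + 0.2, "t1": i + 0.8, "gx": float(t[0]), "gy": float(t[1])}
            for i, t in enumerate(targets)
        ]

    def test_exact_linear_relation_recovered(self):
        targets = [(-1.0, -0.5), (0.0, 0.0), (1.0, 0.5)]
        times = np.arange(0, 3, 0.01)
        pos = np.full((len(times), 2), np.nan)
        for i, (gx, gy) in enumerate(targets):
            sel = (times >= i) & (times < i + 1)
            pos[sel] = [(gx - 0.3) / 0.025, (gy + 0.1) / 0.025]
        pos = np.nan_to_num(pos)
        model = calibrate(pos, times, self.make_schedule(targets))
        assert np.allclose(model.gain, 0.025, rtol=1e-9)
        assert np.allclose(model.offset, [0.3, -0.1], atol=1e-9)
        assert np.allclose(model.r2, 1.0)

    def test_single_target_rejected(self):
        times = np.arange(0, 1, 0.01)
        pos = np.zeros((len(times), 2))
        with pytest.raises(ValueError):
            calibrate(pos, times, self.make_schedule([(0.0, 0.0)]))

    def test_gap_inside_window_rejected(self):
        targets = [(-1.0, 0.0), (1.0, 0.0)]
        times = np.arange(0, 2, 0.01)
        pos = np.zeros((len(times), 2))
        pos[55] = np.nan
        with pytest.raises(ValueError, match="gap"):
            calibrate(pos, times, self.make_schedule(targets))

    def test_zero_gain_model_rejected(self):
        with pytest.raises(ValueError):
            CalibrationModel(gain=np.array([0.0, 0.1]), offset=np.zeros(2), r2=np.ones(2))


class TestCyclopean:
    def test_conjugate_motion_magnitude(self):
        v = np.array([[3.0, 4.0]] * 5)
        assert np.allclose(cyclopean_speed(v, v), 5.0)

    def test_pure_vergence_cancels(self):
        v = np.array([[2.0, 0.0]] * 4)
        assert np.allclose(cyclopean_speed(v, -v), 0.0)

    def test_gap_in_either_eye_propagates(self):
        vl = np.array([[1.0, 0.0], [np.nan, np.nan], [1.0, 0.0]])
        vr = np.ones((3, 2))
        speed = cyclopean_speed(vl, vr)
        assert np.isnan(speed[1]) and np.isfinite(speed[[0, 2]]).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cyclopean_speed(np.ones((3, 2)), np.ones((4, 2)))


class TestTrackingIntegration:
    def test_integrated_event_displacement_within_10pct(self, small_scene):
        """Integrated tracked velocity over a saccadic event matches the true
        gaze displacement over the same window within 10% (the window also
        contains fixational drift, so the reference is the true displacement,
        not the nominal event amplitude)."""
        cfg, frames, truth = small_scene
        box = cfg.eye_boxes()[0]
        mt = track_eye(frames, box, get_mask=lambda k: truth.iris_mask(k, 0))
        assert mt.valid.all()
        calib = CalibrationModel.ideal(cfg.px_per_degree)
        tr = kinematics_from_motion(mt, calib, cfg.fps, tvd_lambda=0.1)
        ev = truth.events[0]
        a = max(ev.onset_frame - 3, 0)
        b = min(ev.offset_frame + 3, len(tr.position_deg) - 1)
        amp = np.hypot(*(tr.position_deg[b] - tr.position_deg[a]))
        true_amp = np.hypot(*(truth.gaze_deg[b, 0] - truth.gaze_deg[a, 0]))
        assert true_amp == pytest.approx(0.3, rel=0.15)  # drift perturbs the window
        assert amp == pytest.approx(true_amp, rel=0.10)

    def test_noiseless_nine_point_calibration_gain(self):
        """Noiseless 9-point calibration recovers the px/deg gain within 0.5%."""
        cfg = SceneConfig(n_eyes=1, sensor_noise_sigma=0.0)
        gaze, schedule = make_calibration_trajectory(cfg, dwell=0.4, seed=0)
        frames, truth = render(cfg, gaze, seed=0)
        box = cfg.eye_boxes()[0]
        mt = track_eye(frames, box, get_mask=lambda k: truth.iris_mask(k, 0))
        shifts, _ = fill_gaps(mt.shifts, mt.valid)
        pos_px = integrate_shifts(shifts)
        times = np.arange(len(gaze)) / cfg.fps
        model = calibrate(pos_px, times, schedule)
        expected = 1.0 / cfg.px_per_degree
        assert np.allclose(model.gain, expected, rtol=0.005)
        assert np.all(model.r2 > 0.999)

    def test_domain_switch_velocity_denoising(self, small_scene):
        cfg, frames, truth = small_scene
        box = cfg.eye_boxes()[0]
        mt = track_eye(frames, box, get_mask=lambda k: truth.iris_mask(k, 0))
        calib = CalibrationModel.ideal(cfg.px_per_degree)
        tr_pos = kinematics_from_motion(mt, calib, cfg.fps, denoise_domain="position")
        tr_vel = kinematics_from_motion(mt, calib, cfg.fps, denoise_domain="velocity")
        assert tr_pos.velocity_deg_s.shape == tr_vel.velocity_deg_s.shape
        with pytest.raises(ValueError):
            kinematics_from_motion(mt, calib, cfg.fps, denoise_domain="both")
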