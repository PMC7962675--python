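"""Iris segmentation: labels, IoU, the NumPy U-Net, and the fallback path."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irisvel.segmentation import (
    EllipseParams,
    UNetConfig,
    clip_eyelids,
    fallback_segment,
    fit_ellipse_lsq,
    iou,
    train_unet,
)


def ellipse_points(center, a, b, angle, n):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    c, s = np.cos(angle), np.sin(angle)
    return np.column_stack(
        [center[0] + c * x - s * y, center[1] + s * x + c * y]
    )


class TestEllipseFit:
    def test_circle_recovered_exactly(self):
        pts = ellipse_points((100, 100), 30, 30, 0.0, 6)
        e = fit_ellipse_lsq(pts)
        assert np.allclose(e.center, (100, 100), atol=1e-6)
        assert e.a == pytest.approx(30, abs=1e-6)
        assert e.b == pytest.approx(30, abs=1e-6)

    def test_rotated_ellipse_recovered(self):
        ang = np.deg2rad(30)
        pts = ellipse_points((50, 70), 40, 25, ang, 8)
        e = fit_ellipse_lsq(pts)
        assert np.allclose(e.center, (50, 70), atol=1e-6)
        assert e.a == pytest.approx(40, abs=1e-6)
        assert e.b == pytest.approx(25, abs=1e-6)
        assert e.angle == pytest.approx(ang, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_ellipse_lsq(ellipse_points((0, 0), 10, 5, 0, 4))

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ValueError):
            fit_ellipse_lsq(pts)


class TestClipEyelids:
    E = EllipseParams(center=(60.0, 60.0), a=40.0, b=30.0, angle=0.0)

    def test_distant_lids_keep_full_ellipse(self):
        bare = clip_eyelids(self.E, (120, 120))
        clipped = clip_eyelids(
            self.E,
            (120, 120),
            upper_pts=[(0, 1), (60, 2), (119, 1)],
            lower_pts=[(0, 118), (60, 119), (119, 118)],
        )
        assert np.array_equal(bare, clipped)
        assert bare.sum() == pytest.approx(self.E.area, rel=0.02)

    def test_horizontal_lid_through_center_halves_area(self):
        half = clip_eyelids(
            self.E, (120, 120), upper_pts=[(0, 60.0), (60, 60.0), (119, 60.0)]
        )
        full = clip_eyelids(self.E, (120, 120))
        assert half.sum() / full.sum() == pytest.approx(0.5, abs=0.02)

    def test_no_lids_returns_ellipse_interior(self):
        mask = clip_eyelids(self.E, (120, 120))
        yy, xx = np.mgrid[0:120, 0:120]
        assert np.array_equal(mask, self.E.contains(xx, yy))

    def test_too_few_lid_points_rejected(self):
        with pytest.raises(ValueError):
            clip_eyelids(self.E, (120, 120), upper_pts=[(0, 0), (1, 1)])

    def test_clipping_never_increases_area(self):
        rng = np.random.default_rng(0)
        full = clip_eyelids(self.E, (120, 120)).sum()
        for _ in range(5):
            up = np.column_stack([rng.uniform(0, 119, 4), rng.uniform(0, 119, 4)])
            lo = np.column_stack([rng.uniform(0, 119, 4), rng.uniform(0, 119, 4)])
            clipped = clip_eyelids(self.E, (120, 120), upper_pts=up, lower_pts=lo)
            assert clipped.sum() <= full


class TestIoU:
    def test_identical_masks(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 2:5] = True
        assert iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0:2, 0:2] = True
        b[5:7, 5:7] = True
        assert iou(a, b) == 0.0

    def test_hand_counted_overlap(self):
        # two 2x2 squares overlapping in a 1x2 strip: 2 / 6
        a = np.zeros((5, 5), bool)
        b = np.zeros((5, 5), bool)
        a[1:3, 1:3] = True
        b[1:3, 2:4] = True
        assert iou(a, b) == pytest.approx(2.0 / 6.0)

    def test_both_empty_is_one(self):
        assert iou(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iou(np.zeros((4, 4), bool), np.zeros((4, 5), bool))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    def test_symmetry(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(16)], bool).reshape(4, 4)
        b = np.array([(bits_b >> i) & 1 for i in range(16)], bool).reshape(4, 4)
        assert iou(a, b) == iou(b, a)


@pytest.fixture(scope="module")
def training_pairs(small_scene):
    cfg, frames, truth = small_scene
    box = cfg.eye_boxes()[0]
    x0, y0, w, h = box
    imgs = np.stack([frames[k][y0 : y0 + h, x0 : x0 + w] for k in range(16)])
    msks = np.stack(
        [truth.iris_mask(k, 0)[y0 : y0 + h, x0 : x0 + w] for k in range(16)]
    )
    return imgs, msks


class TestUNet:
    def test_smoke_training_loss_decreases(self, training_pairs):
        """16 pairs, 3 epochs: pixelwise cross-entropy drops every epoch."""
        imgs, msks = training_pairs
        cfg = UNetConfig(input_size=64, depth=2, base_channels=8, epochs=3)
        _, losses = train_unet(imgs, msks, cfg, seed=0)
        assert len(losses) == 3
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_training_is_deterministic(self, training_pairs):
        imgs, msks = training_pairs
        cfg = UNetConfig(input_size=32, depth=2, base_channels=4, epochs=2)
        _, l1 = train_unet(imgs[:8], msks[:8], cfg, seed=3)
        _, l2 = train_unet(imgs[:8], msks[:8], cfg, seed=3)
        assert l1 == l2

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_unet(np.empty((0, 8, 8)), np.empty((0, 8, 8)))

    def test_shape_mismatch_rejected(self, training_pairs):
        imgs, msks = training_pairs
        with pytest.raises(ValueError):
            train_unet(imgs[:4], msks[:4, :10, :10])

    def test_untrained_predictor_rejected(self):
        from irisvel.segmentation import UNetSegmenter

        model = UNetSegmenter(UNetConfig(input_size=32, depth=2, base_channels=4))
        with pytest.raises(RuntimeError):
            model.predict_mask(np.zeros((32, 32)))

    def test_input_size_must_match_depth(self):
        with pytest.raises(ValueError):
            UNetConfig(input_size=100, depth=3)


class TestFallback:
    def test_iou_against_ground_truth_on_synthetic_eyes(self, small_scene):
        """Classical segmenter reaches IoU >= 0.85 on unoccluded eyes."""
        cfg, frames, truth = small_scene
        box = cfg.eye_boxes()[0]
        for k in range(0, len(frames), 30):
            mask = fallback_segment(frames[k], box)
            assert iou(mask, truth.iris_mask(k, 0)) >= 0.85

    def test_blank_frame_warns_and_returns_empty(self):
        frame = np.full((60, 60), 0.5, dtype=np.float32)
        with pytest.warns(UserWarning):
            mask = fallback_segment(frame, (10, 10, 40, 40))
        assert not mask.any()
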