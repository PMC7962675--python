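"""Head-motion compensation by cascaded similarity transforms.

Every frame is aligned to a global reference frame using a 4-DOF similarity
transform estimated from four rectangular face patches: each patch
contributes one correspondence — the geometric median of its matched
feature points in the source and destination frames — and the four
correspondences determine the transform by closed-form least squares.
Restricting each patch to a single robust point keeps texture-rich patches
from dominating the fit, which is what makes the similarity model stable
where a free homography accumulates skew.

Frame-to-frame transforms are cascaded within blocks of
``keyframe_interval`` frames (default 480, i.e. 5 s at 96 fps); each new
keyframe is matched *directly* to the previous keyframe so that drift in
the pairwise cascade cannot accumulate beyond one block.  The price is a
small parameter discontinuity ("jitter") at every keyframe switch, which
the report logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureConfig, MatchSet, detect_and_describe, match_images
from .geometry import geometric_median
from .transforms import SimilarityTransform, estimate_similarity, warp_image

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PatchRegion:
    """Axis-aligned rectangle ``(x, y, w, h)`` in reference-frame pixels."""

    x: int
    y: int
    w: int
    h: int
    region_id: int = 0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("patch width and height must be positive")

    def crop(self, frame: np.ndarray, margin: int = 0) -> tuple[np.ndarray, tuple[int, int]]:
        """Crop the patch (optionally expanded by ``margin``) from a frame.

        Returns the crop and the (x0, y0) offset of its origin.
        """
        h, w = frame.shape[:2]
        x0 = max(self.x - margin, 0)
        y0 = max(self.y - margin, 0)
        x1 = min(self.x + self.w + margin, w)
        y1 = min(self.y + self.h + margin, h)
        return frame[y0:y1, x0:x1], (x0, y0)


def validate_patches(patches: list[PatchRegion], eye_boxes=None) -> None:
    """Check patches are pairwise disjoint and clear of the eye regions."""
    rects = [(p.x, p.y, p.w, p.h) for p in patches]
    if eye_boxes:
        rects_eyes = list(eye_boxes)
    else:
        rects_eyes = []

    def overlaps(a, b):
        ax, ay, aw, ah = a
        bx, by, bw, bh = b
        return ax < bx + bw and bx < ax + aw and ay < by + bh and by < ay + ah

    for i in range(len(rects)):
        for j in range(i + 1, len(rects)):
            if overlaps(rects[i], rects[j]):
                raise ValueError(f"patches {i} and {j} overlap")
        for eb in rects_eyes:
            if overlaps(rects[i], eb):
                raise ValueError(f"patch {i} overlaps an eye region")


@dataclass
class StabilizationReport:
    """Per-frame alignment transforms and bookkeeping of a cascade run."""

    transforms: list[SimilarityTransform]
    keyframes: list[int]
    fallback_frames: list[int] = field(default_factory=list)
    jitter: list[tuple[int, float]] = field(default_factory=list)  # (frame, |dt| px)

    @property
    def n_frames(self) -> int:
        return len(self.transforms)


# ----------------------------------------------------------------------
def match_patch(
    patch_a: np.ndarray,
    patch_b: np.ndarray,
    config: FeatureConfig | None = None,
    offset: tuple[float, float] = (0.0, 0.0),
    features_a=None,
    features_b=None,
) -> MatchSet:
    """Feature matching between a patch at frame n and at frame n+1.

    Runs detection, brute-force descriptor matching with Lowe's ratio test,
    and RANSAC under a local translation model; returns the inlier match
    set, flagged low-confidence when fewer than ``config.min_matches``
    inliers survive (blank or occluded patches end up there).
    """
    if patch_a.size == 0 or patch_b.size == 0:
        raise ValueError("patches must be non-empty")
    return match_images(
        patch_a, patch_b, config, offset=offset, features_a=features_a, features_b=features_b
    )


def patch_correspondence(matches: MatchSet) -> tuple[np.ndarray, np.ndarray]:
    """One robust (source, destination) point pair for a patch.

    The geometric median of the matched source points and of the matched
    destination points, computed independently — the single best summary of
    where the patch is in each frame.
    """
    if len(matches) == 0:
        raise ValueError("empty match set")
    return geometric_median(matches.src), geometric_median(matches.dst)


def _frames_as_float(frame: np.ndarray) -> np.ndarray:
    if frame.dtype == np.uint8:
        return frame.astype(np.float32) / 255.0
    return np.asarray(frame, dtype=np.float32)


def _pairwise_transform(
    feats_a: list,
    feats_b: list,
    crops_a: list,
    crops_b: list,
    offsets: list,
    config: FeatureConfig,
) -> tuple[SimilarityTransform | None, int]:
    """Similarity mapping frame-a coordinates to frame-b coordinates.

    Returns (transform, n_low_confidence_patches); transform is None when
    fewer than two patches produced usable correspondences.
    """
    src_pts, dst_pts = [], []
    n_low = 0
    for fa, fb, ca, cb, off in zip(feats_a, feats_b, crops_a, crops_b, offsets):
        ms = match_patch(ca, cb, config, offset=off, features_a=fa, features_b=fb)
        if ms.low_confidence:
            n_low += 1
            continue
        s, d = patch_correspondence(ms)
        src_pts.append(s)
        dst_pts.append(d)
    if n_low >= 2 or len(src_pts) < 2:
        return None, n_low
    return estimate_similarity(np.array(src_pts), np.array(dst_pts)), n_low


def cascade_align(
    frames: np.ndarray,
    patches: list[PatchRegion],
    keyframe_interval: int = 480,
    config: FeatureConfig | None = None,
    search_margin: int = 28,
    return_frames: bool = True,
) -> tuple[StabilizationReport, np.ndarray | None]:
    """Align every frame to frame 0 through cascaded similarity transforms.

    Within a keyframe block, frame k's transform to the block keyframe is
    the composition of consecutive pairwise transforms; keyframes are
    matched directly to the immediately preceding keyframe.  When two or
    more patches are low-confidence in a frame pair, the previous pairwise
    transform is reused and the frame is logged as a fallback.

    Returns the report (``transforms[k]`` maps frame-k coordinates to
    reference coordinates) and, if ``return_frames``, the stabilized frame
    stack (float32 in [0, 1], sub-pixel warped).
    """
    if keyframe_interval < 2:
        raise ValueError("keyframe_interval must be >= 2")
    config = config or FeatureConfig()
    n = len(frames)
    if n == 0:
        raise ValueError("no frames")

    def patch_features(frame_f):
        feats, crops, offs = [], [], []
        for p in patches:
            crop, (x0, y0) = p.crop(frame_f, margin=search_margin)
            feats.append(detect_and_describe(crop, config))
            crops.append(crop)
            offs.append((float(x0), float(y0)))
        return feats, crops, offs

    transforms: list[SimilarityTransform] = [SimilarityTransform.identity()]
    keyframes = [0]
    fallback: list[int] = []
    jitter: list[tuple[int, float]] = []

    chain = SimilarityTransform.identity()  # keyframe -> reference
    rel = SimilarityTransform.identity()  # current frame -> keyframe
    prev_pairwise: SimilarityTransform | None = None

    f_prev = _frames_as_float(frames[0])
    feats_prev, crops_prev, offs_prev = patch_features(f_prev)
    key_feats, key_crops, key_offs = feats_prev, crops_prev, offs_prev

    for k in range(1, n):
        f_cur = _frames_as_float(frames[k])
        feats_cur, crops_cur, offs_cur = patch_features(f_cur)
        m, n_low = _pairwise_transform(
            feats_prev, feats_cur, crops_prev, crops_cur, offs_prev, config
        )
        if m is None:
            if prev_pairwise is None:
                logger.warning("frame %d: no confident patches and no prior transform; "
                               "assuming identity", k)
                m = SimilarityTransform.identity()
            else:
                logger.warning(
                    "frame %d: %d low-confidence patches; reusing previous pairwise transform",
                    k, n_low,
                )
                m = prev_pairwise
            fallback.append(k)
        prev_pairwise = m
        rel = rel.compose(m.inverse())  # frame k -> current keyframe

        if k % keyframe_interval == 0:
            cascaded = chain.compose(rel)
            # realign: direct match from the previous keyframe to this frame
            mk, n_low_k = _pairwise_transform(
                key_feats, feats_cur, key_crops, crops_cur, key_offs, config
            )
            if mk is None:
                logger.warning("keyframe %d: direct match failed; keeping cascaded estimate", k)
                direct = cascaded
            else:
                direct = chain.compose(mk.inverse())
            dt = float(
                np.hypot(direct.tx - cascaded.tx, direct.ty - cascaded.ty)
            )
            jitter.append((k, dt))
            chain = direct
            rel = SimilarityTransform.identity()
            keyframes.append(k)
            key_feats, key_crops, key_offs = feats_cur, crops_cur, offs_cur
            transforms.append(chain)
        else:
            transforms.append(chain.compose(rel))

        f_prev = f_cur
        feats_prev, crops_prev, offs_prev = feats_cur, crops_cur, offs_cur

    report = StabilizationReport(
        transforms=transforms, keyframes=keyframes, fallback_frames=fallback, jitter=jitter
    )
    stabilized = None
    if return_frames:
        stabilized = np.empty((n,) + frames[0].shape[:2], dtype=np.float32)
        for k in range(n):
            stabilized[k] = warp_image(
                _frames_as_float(frames[k]), transforms[k], order=1, cval=0.0
            )
    return report, stabilized


# ----------------------------------------------------------------------
def track_marker(
    frames: np.ndarray, start: tuple[float, float], window: int = 12
) -> np.ndarray:
    """Track a bright spot through a frame stack, sub-pixel.

    In each frame the brightest pixel is found in a window around the
    previous position, then refined by the intensity-weighted centroid of
    its 5x5 neighbourhood.  Returns (n, 2) (x, y) positions.
    """
    n = len(frames)
    out = np.empty((n, 2))
    pos = np.asarray(start, dtype=float)
    for k in range(n):
        f = _frames_as_float(frames[k])
        x0 = int(round(pos[0])) - window
        y0 = int(round(pos[1])) - window
        x0 = max(x0, 0)
        y0 = max(y0, 0)
        sub = f[y0 : y0 + 2 * window + 1, x0 : x0 + 2 * window + 1]
        iy, ix = np.unravel_index(np.argmax(sub), sub.shape)
        py0 = max(y0 + iy - 2, 0)
        px0 = max(x0 + ix - 2, 0)
        patch = f[py0 : py0 + 5, px0 : px0 + 5].astype(float)
        wgt = patch - patch.min()
        tot = wgt.sum()
        yy, xx = np.mgrid[py0 : py0 + patch.shape[0], px0 : px0 + patch.shape[1]]
        if tot > 0:
            pos = np.array([(wgt * xx).sum() / tot, (wgt * yy).sum() / tot])
        else:
            pos = np.array([x0 + ix, y0 + iy], dtype=float)
        out[k] = pos
    return out


def stabilization_metrics(
    tracks_before: np.ndarray,
    tracks_after: np.ndarray,
    reference_index: int = 0,
) -> dict:
    """Per-axis MSE/STD of marker displacement from the reference frame.

    ``tracks_*`` are ``(n_frames, n_points, 2)`` position arrays.  MSE is
    the mean squared displacement from each point's position in the
    reference frame; STD the population standard deviation of the positions
    (n-denominator).  ``mpc_*`` entries aggregate over points and axes
    (mean per class).
    """
    tb = np.atleast_3d(np.asarray(tracks_before, dtype=float))
    ta = np.atleast_3d(np.asarray(tracks_after, dtype=float))
    if tb.shape != ta.shape:
        raise ValueError("before/after tracks must have equal shape")

    def per_axis(tracks):
        ref = tracks[reference_index]
        mse = ((tracks - ref) ** 2).mean(axis=0)  # (n_points, 2)
        std = tracks.std(axis=0, ddof=0)
        return mse, std

    mse_b, std_b = per_axis(tb)
    mse_a, std_a = per_axis(ta)
    return {
        "mse_before": mse_b,
        "std_before": std_b,
        "mse_after": mse_a,
        "std_after": std_a,
        "mpc_mse_before": float(mse_b.mean()),
        "mpc_std_before": float(std_b.mean()),
        "mpc_mse_after": float(mse_a.mean()),
        "mpc_std_after": float(std_a.mean()),
    }
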