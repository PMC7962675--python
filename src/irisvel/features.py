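"""Local feature detection, description and robust matching.

The motion signals in this package are all built from populations of local
texture features: corners detected on a Harris response surface, localized
to sub-pixel precision by quadratic interpolation of the response peak, and
described by mean-removed, L2-normalized intensity patches sampled at the
refined location.  Matching is brute-force in descriptor space (L2 norm)
with Lowe's ratio test, followed by RANSAC outlier removal under a local
2-D translation model — per patch or per iris, frame-to-frame motion is
locally a pure shift, and only displacement statistics (their geometric
median) are consumed downstream.

Sub-pixel keypoint localization matters here: the eye moves by fractions of
a pixel between frames during fixational drift, and the median of many
sub-pixel displacement estimates resolves shifts of a few hundredths of a
pixel that integer-located keypoints would quantize away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist


@dataclass
class FeatureConfig:
    """Detector/matcher parameters.

    Defaults are tuned for the synthetic scenes (96 fps, band-pass iris
    texture) but are deliberately generic Harris-corner settings.
    """

    sigma_d: float = 0.8          # derivative (differentiation) scale, px
    sigma_i: float = 1.2          # integration scale of the structure tensor, px
    harris_k: float = 0.05
    min_distance: int = 2         # non-max suppression radius, px
    response_threshold: float = 1e-7   # absolute Harris response floor (image in [0,1])
    max_keypoints: int = 200
    border: int = 4               # keep keypoints this far from the image edge, px
    descriptor_radius: int = 5    # patch descriptor half-width -> (2r+1)^2 samples
    lowe_ratio: float = 0.75
    ransac_inlier_radius: float = 1.5   # px, translation-model consensus radius
    ransac_iterations: int = 50
    min_matches: int = 3          # below this the match set is low-confidence


@dataclass
class MatchSet:
    """Paired keypoints between a source and destination image.

    ``src`` and ``dst`` are ``(n, 2)`` arrays of (x, y) pixel coordinates;
    ``distances`` the descriptor distances of the accepted matches.
    ``low_confidence`` is set when fewer than ``min_matches`` inliers
    survive the full pipeline (callers fall back or flag a gap).
    """

    src: np.ndarray
    dst: np.ndarray
    distances: np.ndarray = field(default_factory=lambda: np.empty(0))
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if len(self.src) != len(self.dst):
            raise ValueError("src and dst must have equal length")

    def __len__(self) -> int:
        return len(self.src)

    @property
    def displacements(self) -> np.ndarray:
        return self.dst - self.src


def harris_response(image: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Harris corner response of a single-channel float image."""
    img = np.asarray(image, dtype=np.float32)
    gy = ndi.gaussian_filter(img, config.sigma_d, order=(1, 0))
    gx = ndi.gaussian_filter(img, config.sigma_d, order=(0, 1))
    axx = ndi.gaussian_filter(gx * gx, config.sigma_i)
    ayy = ndi.gaussian_filter(gy * gy, config.sigma_i)
    axy = ndi.gaussian_filter(gx * gy, config.sigma_i)
    det = axx * ayy - axy * axy
    tr = axx + ayy
    return det - config.harris_k * tr * tr


def detect_keypoints(
    image: np.ndarray,
    config: FeatureConfig | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Sub-pixel Harris corners of ``image`` as an ``(n, 2)`` (x, y) array.

    Non-maximum suppression over ``min_distance`` followed by 1-D quadratic
    interpolation of the response surface along each axis (the standard
    three-point peak refinement), clipped to half a pixel.
    """
    config = config or FeatureConfig()
    r = harris_response(image, config)
    size = 2 * config.min_distance + 1
    mx = ndi.maximum_filter(r, size=size, mode="constant")
    peaks = (r == mx) & (r > config.response_threshold)
    b = config.border
    if b > 0:
        peaks[:b] = peaks[-b:] = False
        peaks[:, :b] = peaks[:, -b:] = False
    if mask is not None:
        peaks &= mask.astype(bool)
    ys, xs = np.nonzero(peaks)
    if len(ys) == 0:
        return np.empty((0, 2))
    if len(ys) > config.max_keypoints:
        order = np.argsort(r[ys, xs])[::-1][: config.max_keypoints]
        ys, xs = ys[order], xs[order]
    c = r[ys, xs]
    denom_x = np.maximum(2 * c - r[ys, xs + 1] - r[ys, xs - 1], 1e-12)
    denom_y = np.maximum(2 * c - r[ys + 1, xs] - r[ys - 1, xs], 1e-12)
    dx = np.clip(0.5 * (r[ys, xs + 1] - r[ys, xs - 1]) / denom_x, -0.5, 0.5)
    dy = np.clip(0.5 * (r[ys + 1, xs] - r[ys - 1, xs]) / denom_y, -0.5, 0.5)
    return np.column_stack([xs + dx, ys + dy])


def describe_keypoints(
    image: np.ndarray, keypoints: np.ndarray, config: FeatureConfig | None = None
) -> np.ndarray:
    """Normalized intensity-patch descriptors sampled at sub-pixel centers."""
    config = config or FeatureConfig()
    if len(keypoints) == 0:
        return np.empty((0, (2 * config.descriptor_radius + 1) ** 2))
    img = np.asarray(image, dtype=np.float32)
    r = config.descriptor_radius
    off = np.mgrid[-r : r + 1, -r : r + 1].reshape(2, -1).astype(np.float32)  # (row, col)
    centers_rc = keypoints[:, ::-1].T  # (2, n) in (row, col)
    coords = centers_rc[:, :, None] + off[:, None, :]
    vals = ndi.map_coordinates(img, coords.reshape(2, -1), order=1, mode="nearest")
    d = vals.reshape(len(keypoints), -1).astype(float)
    d -= d.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    return d / np.maximum(norms, 1e-12)


def detect_and_describe(
    image: np.ndarray,
    config: FeatureConfig | None = None,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    config = config or FeatureConfig()
    kps = detect_keypoints(image, config, mask=mask)
    return kps, describe_keypoints(image, kps, config)


def ratio_test_matches(
    desc_a: np.ndarray, desc_b: np.ndarray, lowe_ratio: float = 0.75
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force L2 matching with Lowe's ratio test.

    Returns (indices into a, indices into b) of accepted matches.  A match
    is kept only when the best distance is below ``lowe_ratio`` times the
    second best, i.e. when the correspondence is unambiguous.
    """
    if len(desc_a) == 0 or len(desc_b) < 2:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    dist = cdist(desc_a, desc_b)
    idx2 = np.argpartition(dist, 1, axis=1)[:, :2]
    rows = np.arange(len(desc_a))
    d2 = dist[rows[:, None], idx2]
    order = np.argsort(d2, axis=1)
    best = idx2[rows, order[:, 0]]
    best_d = d2[rows, order[:, 0]]
    second_d = d2[rows, order[:, 1]]
    keep = best_d < lowe_ratio * second_d
    return rows[keep], best[keep]


def ransac_translation(
    src: np.ndarray,
    dst: np.ndarray,
    inlier_radius: float = 1.5,
    iterations: int = 50,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """RANSAC inlier mask under a 2-D translation model.

    One match determines a translation hypothesis, so consensus is simply
    the set of displacements within ``inlier_radius`` of the hypothesis;
    the final mask is re-estimated around the median of the best consensus
    set.  Deterministic when ``rng`` is seeded (and exhaustive for small
    match sets).
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    n = len(src)
    if n == 0:
        return np.zeros(0, dtype=bool)
    disp = dst - src
    if n <= iterations:
        cand_idx = np.arange(n)
    else:
        rng = rng or np.random.default_rng(0)
        cand_idx = rng.choice(n, size=iterations, replace=False)
    # vectorized consensus counting over all hypotheses
    d2 = ((disp[None, :, :] - disp[cand_idx, None, :]) ** 2).sum(axis=2)
    within = d2 <= inlier_radius**2
    best = int(np.argmax(within.sum(axis=1)))
    mask = within[best]
    # refinement pass around the consensus median displacement
    center = np.median(disp[mask], axis=0)
    return ((disp - center) ** 2).sum(axis=1) <= inlier_radius**2


def match_images(
    image_a: np.ndarray,
    image_b: np.ndarray,
    config: FeatureConfig | None = None,
    mask_a: np.ndarray | None = None,
    mask_b: np.ndarray | None = None,
    offset: tuple[float, float] = (0.0, 0.0),
    features_a: tuple[np.ndarray, np.ndarray] | None = None,
    features_b: tuple[np.ndarray, np.ndarray] | None = None,
) -> MatchSet:
    """Full matching pipeline between two single-channel images.

    Detection -> description -> brute-force L2 + ratio test -> RANSAC
    (translation model).  ``offset`` is added to all keypoint coordinates so
    crops can report frame coordinates.  Pre-computed ``(keypoints,
    descriptors)`` pairs may be passed to avoid re-detection when sliding
    along a frame sequence.
    """
    config = config or FeatureConfig()
    kps_a, desc_a = (
        features_a if features_a is not None else detect_and_describe(image_a, config, mask_a)
    )
    kps_b, desc_b = (
        features_b if features_b is not None else detect_and_describe(image_b, config, mask_b)
    )
    ia, ib = ratio_test_matches(desc_a, desc_b, config.lowe_ratio)
    if len(ia) == 0:
        return MatchSet(
            src=np.empty((0, 2)), dst=np.empty((0, 2)), low_confidence=True
        )
    src, dst = kps_a[ia], kps_b[ib]
    inliers = ransac_translation(
        src, dst, config.ransac_inlier_radius, config.ransac_iterations
    )
    src, dst = src[inliers], dst[inliers]
    dists = np.linalg.norm(desc_a[ia][inliers] - desc_b[ib][inliers], axis=1)
    off = np.asarray(offset, dtype=float)
    return MatchSet(
        src=src + off,
        dst=dst + off,
        distances=dists,
        low_confidence=len(src) < config.min_matches,
    )


def count_keypoints_in_mask(
    image: np.ndarray, mask: np.ndarray, config: FeatureConfig | None = None
) -> int:
    """Number of detected keypoints whose (rounded) location lies in ``mask``."""
    kps = detect_keypoints(image, config or FeatureConfig())
    if len(kps) == 0:
        return 0
    xs = np.clip(np.round(kps[:, 0]).astype(int), 0, mask.shape[1] - 1)
    ys = np.clip(np.round(kps[:, 1]).astype(int), 0, mask.shape[0] - 1)
    return int(mask.astype(bool)[ys, xs].sum())
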