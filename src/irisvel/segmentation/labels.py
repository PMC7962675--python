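"""Ground-truth iris label construction and the IoU metric.

Training labels for the segmentation model are built the way a human
annotator would: a handful of clicked points on the iris border determine
an ellipse (direct least-squares conic fit constrained to ellipses), and
points clicked along the eyelid margins determine second-degree
polynomials that clip away the occluded part of the ellipse.  Segmentation
quality is measured by intersection-over-union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import EllipseModel


@dataclass(frozen=True)
class EllipseParams:
    """Ellipse with center (x, y), semi-axes a >= b and orientation angle (rad)."""

    center: tuple[float, float]
    a: float
    b: float
    angle: float

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError(f"need a >= b > 0, got a={self.a}, b={self.b}")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean membership test for (x, y) arrays."""
        cx, cy = self.center
        c, s = np.cos(self.angle), np.sin(self.angle)
        u = (np.asarray(x) - cx) * c + (np.asarray(y) - cy) * s
        v = -(np.asarray(x) - cx) * s + (np.asarray(y) - cy) * c
        return (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0

    @property
    def area(self) -> float:
        return float(np.pi * self.a * self.b)


def fit_ellipse_lsq(points: np.ndarray) -> EllipseParams:
    """Algebraic least-squares ellipse fit to >= 5 boundary points.

    Uses the direct ellipse-constrained conic fit; exact (to numerical
    precision) when the points lie on a true ellipse.  Fewer than five
    points, or degenerate (e.g. collinear) configurations, raise
    ``ValueError``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y)")
    if len(pts) < 5:
        raise ValueError(f"ellipse fit requires >= 5 points, got {len(pts)}")
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise ValueError("degenerate point configuration; ellipse fit failed")
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = model.theta
    if not np.isfinite([xc, yc, a, b, theta]).all():
        raise ValueError("degenerate point configuration; ellipse fit failed")
    if a <= 0 or b <= 0:
        raise ValueError("ellipse fit collapsed to a degenerate conic")
    if b > a:
        a, b = b, a
        theta = theta + np.pi / 2
    theta = (theta + np.pi / 2) % np.pi - np.pi / 2  # wrap to (-pi/2, pi/2]
    return EllipseParams(center=(float(xc), float(yc)), a=float(a), b=float(b), angle=float(theta))


def _quadratic(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("eyelid fit requires >= 3 (x, y) points")
    return np.polyfit(pts[:, 0], pts[:, 1], 2)


def clip_eyelids(
    ellipse: EllipseParams,
    shape: tuple[int, int],
    upper_pts: np.ndarray | None = None,
    lower_pts: np.ndarray | None = None,
) -> np.ndarray:
    """Rasterize the ellipse interior clipped by eyelid quadratics.

    The mask keeps pixels inside the ellipse that lie *below* the
    upper-eyelid curve and *above* the lower-eyelid curve, in image
    coordinates (y grows downward).  Either lid is optional; each provided
    lid needs at least three points.  The result can only lose area
    relative to the bare ellipse.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ellipse.contains(xx + 0.0, yy + 0.0)
    if upper_pts is not None:
        cu = _quadratic(upper_pts)
        mask &= yy >= np.polyval(cu, xx)
    if lower_pts is not None:
        cl = _quadratic(lower_pts)
        mask &= yy <= np.polyval(cl, xx)
    return mask


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union of two binary masks, in [0, 1].

    Defined as 1.0 when both masks are empty (perfect agreement on
    absence).  Shape mismatch is an error.
    """
    p = np.asarray(pred).astype(bool)
    g = np.asarray(truth).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {g.shape}")
    union = np.logical_or(p, g).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, g).sum() / union)
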