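"""Robust point statistics: the geometric median.

The geometric median (the point minimizing the summed Euclidean distance to
a point set) is the robust central estimate used throughout the tracker:
one median per face patch summarizes its feature matches, and one median per
iris summarizes the matched keypoint shifts between consecutive frames.
Unlike the mean it has a 50% breakdown point, so a minority of bad matches
cannot drag the motion estimate.
"""

from __future__ import annotations

import numpy as np


def geometric_median(
    points: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 200,
) -> np.ndarray:
    """Geometric median of an ``(n, d)`` point set by Weiszfeld iteration.

    Parameters
    ----------
    points:
        ``(n, d)`` array; a single point is its own median.
    tol:
        Convergence tolerance on the iterate displacement, in the same units
        as the coordinates (pixels here).
    max_iter:
        Iteration cap; the update is a contraction for non-collinear data
        and in practice converges in a few dozen steps.

    Notes
    -----
    When an iterate lands exactly on a data point the Weiszfeld weights
    diverge; the iterate is then perturbed slightly and iteration resumes
    (the optimum is attained at a data point only in degenerate
    configurations, which the restart handles).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, d) array")
    if len(pts) == 1:
        return pts[0].copy()
    if len(pts) == 2:
        return pts.mean(axis=0)

    y = pts.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(pts - y, axis=1)
        on_point = d < 1e-12
        if on_point.any():
            # perturbation restart off the coincident data point
            y = y + 10 * tol * (1.0 + np.arange(pts.shape[1]))
            d = np.linalg.norm(pts - y, axis=1)
        w = 1.0 / d
        y_new = (pts * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def geometric_median_bruteforce(
    points: np.ndarray, resolution: float = 0.01, margin: float = 1.0
) -> np.ndarray:
    """Grid-search geometric median (independent oracle, 2-D only).

    Exhaustively evaluates the Weiszfeld objective on a grid of the given
    ``resolution`` covering the data bounding box, then refines once at a
    tenth of the resolution around the best grid node.  O(n * grid) — for
    small test sets only.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")

    def objective(cands: np.ndarray) -> np.ndarray:
        # cands: (m, 2) -> summed distance to all points, in bounded-memory chunks
        out = np.empty(len(cands))
        chunk = 100_000
        for i in range(0, len(cands), chunk):
            diff = cands[i : i + chunk, None, :] - pts[None, :, :]
            out[i : i + chunk] = np.linalg.norm(diff, axis=2).sum(axis=1)
        return out

    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    best = None
    step = resolution
    for refine in range(2):
        xs = np.arange(lo[0], hi[0] + step, step)
        ys = np.arange(lo[1], hi[1] + step, step)
        gx, gy = np.meshgrid(xs, ys)
        cands = np.column_stack([gx.ravel(), gy.ravel()])
        vals = objective(cands)
        best = cands[int(np.argmin(vals))]
        lo = best - 2 * step
        hi = best + 2 * step
        step = step / 10.0
    return best
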