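"""Planar similarity transforms (4 DOF: uniform scale, rotation, translation).

A similarity map acts on image points ``p`` (given as ``(x, y)`` pixel
coordinates) as ``p' = s * R(theta) @ p + t``.  It is the motion model used
for head compensation: less expressive than affine or homography maps, which
makes it far more stable when estimated from a handful of noisy
correspondences, at the price of ignoring keystone/shear components that a
quasi-planar rigid face does not produce anyway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi


@dataclass(frozen=True)
class SimilarityTransform:
    """4-DOF planar transform ``p' = scale * R(rotation) @ p + (tx, ty)``."""

    scale: float = 1.0
    rotation: float = 0.0  # radians, counter-clockwise in (x, y) coords
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.scale, self.rotation, self.tx, self.ty]).all():
            raise ValueError("transform parameters must be finite")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    # ------------------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (x, y, 1) column vectors."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        m = np.array(
            [
                [self.scale * c, -self.scale * s, self.tx],
                [self.scale * s, self.scale * c, self.ty],
                [0.0, 0.0, 1.0],
            ]
        )
        return m

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "SimilarityTransform":
        m = np.asarray(m, dtype=float)
        scale = float(np.hypot(m[0, 0], m[1, 0]))
        rotation = float(np.arctan2(m[1, 0], m[0, 0]))
        return cls(scale=scale, rotation=rotation, tx=float(m[0, 2]), ty=float(m[1, 2]))

    # ------------------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an ``(n, 2)`` array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        out = np.empty_like(pts)
        out[:, 0] = self.scale * (c * pts[:, 0] - s * pts[:, 1]) + self.tx
        out[:, 1] = self.scale * (s * pts[:, 0] + c * pts[:, 1]) + self.ty
        return out if np.asarray(points).ndim == 2 else out[0]

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        scale = self.scale * other.scale
        rotation = self.rotation + other.rotation
        t = self.apply(np.array([other.tx, other.ty]))
        return SimilarityTransform(scale=scale, rotation=rotation, tx=float(t[0]), ty=float(t[1]))

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        c, s = np.cos(-self.rotation), np.sin(-self.rotation)
        tx = -inv_scale * (c * self.tx - s * self.ty)
        ty = -inv_scale * (s * self.tx + c * self.ty)
        return SimilarityTransform(scale=inv_scale, rotation=-self.rotation, tx=tx, ty=ty)

    def parameters(self) -> np.ndarray:
        return np.array([self.scale, self.rotation, self.tx, self.ty])

    def is_close(self, other: "SimilarityTransform", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.parameters(), other.parameters(), atol=atol))


def estimate_similarity(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity transform mapping ``src`` points onto ``dst``.

    Closed-form Procrustes/Umeyama solution; exact (to machine precision)
    when the correspondences are generated by a true similarity.  Requires at
    least two non-coincident source points.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be (n, 2) arrays of equal shape")
    if len(src) < 2:
        raise ValueError("at least 2 correspondences are required")

    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    xs = src - mu_s
    xd = dst - mu_d
    var_s = (xs**2).sum() / len(src)
    if var_s < 1e-24:
        raise ValueError("source points are (nearly) coincident")

    cov = xd.T @ xs / len(src)
    u, d, vt = np.linalg.svd(cov)
    sgn = np.sign(np.linalg.det(u @ vt))
    # restrict to rotations (no reflection)
    e = np.diag([1.0, sgn])
    rot = u @ e @ vt
    scale = float(np.trace(np.diag(d) @ e) / var_s)
    t = mu_d - scale * rot @ mu_s
    return SimilarityTransform(
        scale=scale,
        rotation=float(np.arctan2(rot[1, 0], rot[0, 0])),
        tx=float(t[0]),
        ty=float(t[1]),
    )


def warp_image(
    image: np.ndarray,
    transform: SimilarityTransform,
    output_shape: tuple[int, int] | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Warp ``image`` so that a point at ``transform(p)`` moves to ``p``.

    ``transform`` maps input-image coordinates to output (reference)
    coordinates; the warp samples the input at ``transform^{-1}(q)`` for each
    output pixel ``q`` (inverse warping with sub-pixel interpolation).
    ``origin`` shifts the output window: output pixel (row r, col c)
    corresponds to reference coordinate ``(x, y) = (c + origin[0], r + origin[1])``,
    which lets callers warp a small crop of the reference plane cheaply.
    """
    inv = transform.inverse()
    m = inv.matrix
    # ndi.affine_transform works in (row, col) = (y, x) index space:
    # in_idx = A @ out_idx + off
    a = np.array([[m[1, 1], m[1, 0]], [m[0, 1], m[0, 0]]])
    ox, oy = origin
    off = np.array(
        [m[1, 0] * ox + m[1, 1] * oy + m[1, 2], m[0, 0] * ox + m[0, 1] * oy + m[0, 2]]
    )
    shape = output_shape if output_shape is not None else image.shape[:2]
    return ndi.affine_transform(
        image, a, offset=off, output_shape=tuple(shape), order=order, cval=cval, mode="constant"
    )
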