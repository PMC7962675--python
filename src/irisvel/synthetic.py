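"""Synthetic eye-video renderer with ground truth.

Renders a face-like scene — two textured iris disks, sclera, skin, and four
high-texture "cheek" patches — under scripted gaze trajectories and injected
planar head motion, and returns every frame together with the ground truth
(per-frame gaze, head transform, iris masks, event log).  It exists so that
every stage of the tracking pipeline can be exercised and scored against
known answers at desk scale, without any recorded data.

Model choices (and what they deliberately omit):

* Eye movement is rendered as pure 2-D translation of the iris disk at
  ``px_per_degree`` pixels per degree.  The tracker itself treats
  frame-to-frame iris motion as a 2-D shift, so a 3-D eyeball model would
  add realism the measurement model cannot distinguish.  Torsion, corneal
  refraction and pupil dynamics are not modelled.
* Saccadic events follow a raised-cosine velocity profile whose peak
  velocity equals ``main_sequence_slope * amplitude`` (the main-sequence
  relation, slope 47 s^-1 by default) and whose integral equals the
  amplitude exactly; the displacement curve is evaluated analytically so
  ground-truth increments sum to the amplitude to machine precision.
* Fixational drift is a low-pass filtered random walk.
* Head motion is a similarity transform of the whole frame (translation
  dominant, optional small rotation/scale), emulating the few-millimetre
  residual motion a chin rest leaves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .transforms import SimilarityTransform, warp_image

SACCADIC_KINDS = ("microsaccade", "saccade")
SEGMENT_KINDS = ("drift_segment", "pursuit_segment")


# ----------------------------------------------------------------------
@dataclass
class SceneConfig:
    """Geometry, optics and noise of the synthetic scene.

    Pixel scale and frame rate default to 40 px/deg and 96 Hz; one degree of
    gaze rotation translates the iris by ``px_per_degree`` pixels.
    ``sensor_noise_sigma`` is additive Gaussian noise in 8-bit grey levels.
    ``eyelid_occlusion`` covers the stated fraction of the iris height from
    the top with skin.
    """

    frame_width: int = 512
    frame_height: int = 288
    fps: float = 96.0
    px_per_degree: float = 40.0
    iris_radius: float = 42.0
    pupil_radius: float = 14.0
    texture_seed: int = 0
    texture_band: tuple[float, float] = (0.8, 2.5)  # DoG sigmas, px
    texture_contrast: float = 1.0  # scales iris texture amplitude
    sensor_noise_sigma: float = 2.0
    eyelid_occlusion: float = 0.0
    n_eyes: int = 2
    interocular_px: float = 200.0
    eye_center_y: float = 110.0
    eye_box_half: int = 75  # half-size of the per-eye analysis box, px

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.px_per_degree <= 0:
            raise ValueError("fps and px_per_degree must be positive")
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.pupil_radius >= self.iris_radius:
            raise ValueError(
                f"pupil_radius ({self.pupil_radius}) must be smaller than "
                f"iris_radius ({self.iris_radius})"
            )
        if self.n_eyes not in (1, 2):
            raise ValueError("n_eyes must be 1 or 2")
        if not 0.0 <= self.eyelid_occlusion <= 0.4:
            raise ValueError("eyelid_occlusion must lie in [0, 0.4]")

    @property
    def eye_centers(self) -> np.ndarray:
        """(n_eyes, 2) iris rest positions (x, y) in frame pixels."""
        cx = self.frame_width / 2.0
        if self.n_eyes == 1:
            return np.array([[cx, self.eye_center_y]])
        half = self.interocular_px / 2.0
        return np.array(
            [[cx - half, self.eye_center_y], [cx + half, self.eye_center_y]]
        )

    def eye_boxes(self) -> list[tuple[int, int, int, int]]:
        """Per-eye static analysis boxes ``(x0, y0, w, h)`` in frame px."""
        h = self.eye_box_half
        boxes = []
        for cx, cy in self.eye_centers:
            boxes.append((int(round(cx)) - h, int(round(cy)) - h, 2 * h, 2 * h))
        return boxes

    def patch_regions(self) -> list[tuple[int, int, int, int]]:
        """Four textured stabilization patches ``(x0, y0, w, h)``, below the eyes."""
        w, h = 64, 48
        y0 = int(self.eye_center_y + self.eye_box_half + 20)
        y0 = min(y0, self.frame_height - h - 8)
        n = 4
        gap = (self.frame_width - n * w) / (n + 1)
        return [(int(round(gap + i * (w + gap))), y0, w, h) for i in range(n)]


# ----------------------------------------------------------------------
@dataclass
class GazeEventSpec:
    """A scripted gaze event.

    For saccadic kinds (``microsaccade``, ``saccade``) the duration is
    derived from the main-sequence relation: peak velocity
    ``Vp = main_sequence_slope * amplitude`` and a raised-cosine profile
    give ``duration = 2 * amplitude / Vp = 2 / main_sequence_slope`` s.
    ``pursuit_segment`` moves at constant velocity covering ``amplitude``
    degrees over an explicit ``duration``; ``drift_segment`` adds extra
    random drift of RMS ``amplitude`` deg/sqrt(s) over ``duration``.
    """

    kind: str
    onset: float  # s
    amplitude: float  # deg
    direction: float = 0.0  # deg, polar angle of the displacement
    main_sequence_slope: float = 47.0  # 1/s
    duration: float | None = None  # s; derived for saccadic kinds

    def __post_init__(self) -> None:
        if self.kind not in SACCADIC_KINDS + SEGMENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.amplitude < 0 or self.onset < 0:
            raise ValueError("amplitude and onset must be non-negative")
        if self.kind in SACCADIC_KINDS:
            if self.main_sequence_slope <= 0:
                raise ValueError("main_sequence_slope must be positive")
            if self.duration is None:
                # raised cosine: A = Vp * T / 2 with Vp = slope * A
                object.__setattr__(self, "duration", 2.0 / self.main_sequence_slope)
        elif self.duration is None or self.duration <= 0:
            raise ValueError(f"{self.kind} requires an explicit positive duration")

    @property
    def peak_velocity(self) -> float:
        """Peak instantaneous speed in deg/s (main sequence for saccadic kinds)."""
        if self.kind in SACCADIC_KINDS:
            return self.main_sequence_slope * self.amplitude
        return self.amplitude / self.duration

    @property
    def offset(self) -> float:
        return self.onset + float(self.duration)

    def displacement_at(self, t: np.ndarray) -> np.ndarray:
        """Analytic scalar displacement (deg) along the event direction at time t."""
        t = np.asarray(t, dtype=float)
        tau = np.clip(t - self.onset, 0.0, self.duration)
        if self.kind in SACCADIC_KINDS:
            vp = self.peak_velocity
            td = float(self.duration)
            s = 0.5 * vp * (tau - td / (2 * np.pi) * np.sin(2 * np.pi * tau / td))
        elif self.kind == "pursuit_segment":
            s = self.amplitude * tau / self.duration
        else:  # drift_segment handled stochastically in build_trajectory
            s = np.zeros_like(tau)
        return s


@dataclass
class RealizedEvent:
    """An event with its realized frame indices in a rendered trajectory."""

    spec: GazeEventSpec
    onset_frame: int
    offset_frame: int

    @property
    def onset_s(self) -> float:
        return self.spec.onset

    @property
    def amplitude(self) -> float:
        return self.spec.amplitude


@dataclass
class GroundTruthScene:
    """Per-frame ground truth emitted by the renderer.

    Iris masks are not stored per frame (that would be hundreds of MB for a
    minute of video); they are reconstructed analytically on demand from
    the gaze trace, the head transforms, and the scene geometry — the exact
    same equations the renderer drew them with.
    """

    gaze_deg: np.ndarray  # (n_frames, n_eyes, 2)
    head_transforms: list[SimilarityTransform]
    mask_boxes: list[tuple[int, int, int, int]]  # per eye, (x0, y0, w, h)
    events: list[RealizedEvent]
    fps: float
    px_per_degree: float
    frame_shape: tuple[int, int]
    eye_centers: np.ndarray  # (n_eyes, 2), rest positions in canvas coords
    iris_radius: float
    eyelid_occlusion: float = 0.0

    def __post_init__(self) -> None:
        if len(self.head_transforms) != len(self.gaze_deg):
            raise ValueError("gaze and head_transform must have n_frames entries")

    @property
    def n_frames(self) -> int:
        return len(self.gaze_deg)

    def iris_center(self, frame: int, eye: int = 0) -> np.ndarray:
        """Iris center in frame coordinates (after the head transform)."""
        gx, gy = self.gaze_deg[frame, eye]
        c = self.eye_centers[eye] + np.array([gx, gy]) * self.px_per_degree
        return self.head_transforms[frame].apply(c)

    def iris_mask(self, frame: int, eye: int = 0) -> np.ndarray:
        """Full-frame boolean mask of the visible iris for one frame/eye."""
        full = np.zeros(self.frame_shape, dtype=bool)
        fh, fw = self.frame_shape
        x0, y0, w, h = self.mask_boxes[eye]
        xs = slice(max(x0, 0), min(x0 + w, fw))
        ys = slice(max(y0, 0), min(y0 + h, fh))
        yy, xx = np.mgrid[ys, xs]
        inv = self.head_transforms[frame].inverse()
        c, s = np.cos(inv.rotation), np.sin(inv.rotation)
        px = inv.scale * (c * xx - s * yy) + inv.tx
        py = inv.scale * (s * xx + c * yy) + inv.ty
        gx, gy = self.gaze_deg[frame, eye]
        cx = self.eye_centers[eye, 0] + gx * self.px_per_degree
        cy = self.eye_centers[eye, 1] + gy * self.px_per_degree
        m = np.hypot(px - cx, py - cy) <= self.iris_radius
        if self.eyelid_occlusion > 0:
            lid_cut = cy - self.iris_radius + self.eyelid_occlusion * 2 * self.iris_radius
            m &= py >= lid_cut
        full[ys, xs] = m
        return full

    @property
    def masks(self) -> np.ndarray:
        """Dense ``(n_frames, n_eyes, H, W)`` mask stack (small scenes only)."""
        n_eyes = self.gaze_deg.shape[1]
        out = np.zeros((self.n_frames, n_eyes) + self.frame_shape, dtype=bool)
        for k in range(self.n_frames):
            for e in range(n_eyes):
                out[k, e] = self.iris_mask(k, e)
        return out


# ----------------------------------------------------------------------
def _bandpass_noise(shape: tuple[int, int], band: tuple[float, float], rng) -> np.ndarray:
    """Zero-mean unit-RMS difference-of-Gaussians noise field."""
    raw = rng.standard_normal(shape)
    lo, hi = band
    tex = ndi.gaussian_filter(raw, lo) - ndi.gaussian_filter(raw, hi)
    tex /= max(tex.std(), 1e-12)
    return tex


def generate_iris_texture(config: SceneConfig) -> np.ndarray:
    """Grey-level iris texture, square of side ``2 * iris_radius`` (rounded up).

    Band-pass filtered noise modulated by radial streaks (crypts and furrows
    of a real iris are radially organized), with enough local contrast that
    a corner detector finds a dense keypoint population inside the annulus
    between pupil and limbus.  Deterministic given ``texture_seed``.
    """
    side = int(np.ceil(2 * config.iris_radius)) + 1
    rng = np.random.default_rng(config.texture_seed)
    noise = _bandpass_noise((side, side), config.texture_band, rng)

    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    theta = np.arctan2(yy - c, xx - c)
    r = np.hypot(yy - c, xx - c)
    streaks = np.zeros_like(theta)
    for _ in range(12):
        m = rng.integers(6, 22)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.4, 1.0)
        streaks += amp * np.cos(m * theta + phase)
    streaks /= max(streaks.std(), 1e-12)
    radial_window = np.clip((r - config.pupil_radius) / 4.0, 0, 1) * np.clip(
        (config.iris_radius - r) / 4.0, 0, 1
    )
    tex = 0.35 + config.texture_contrast * (
        0.11 * noise + 0.06 * streaks * radial_window
    )
    return np.clip(tex, 0.02, 0.95).astype(np.float32)


# ----------------------------------------------------------------------
def _check_overlaps(events: list[GazeEventSpec]) -> None:
    spans = [(e.onset, e.offset, i) for i, e in enumerate(events)]
    spans.sort()
    colliding = []
    for (a0, a1, i), (b0, b1, j) in zip(spans, spans[1:]):
        if b0 < a1 - 1e-12:
            colliding.append((i, j))
    if colliding:
        raise ValueError(f"overlapping events (index pairs): {colliding}")


def build_trajectory(
    events: list[GazeEventSpec],
    duration: float,
    config: SceneConfig,
    drift_sigma: float = 0.0,
    seed: int | None = 0,
    eye_offsets: np.ndarray | None = None,
) -> tuple[np.ndarray, list[RealizedEvent]]:
    """Per-frame gaze angles for each eye plus the realized event log.

    Fixational drift is a mean-reverting (Ornstein-Uhlenbeck) random walk
    with diffusion ``drift_sigma`` deg/sqrt(s) and a ~1 s relaxation time —
    drift wanders but stays inside the fixation zone, as physiological
    drift does — low-pass filtered at about 30 ms for smoothness.  Both
    eyes receive identical (conjugate) trajectories unless ``eye_offsets``
    (n_eyes, 2) static offsets are given.

    Returns ``(gaze, realized)`` with ``gaze`` of shape
    ``(n_frames, n_eyes, 2)`` in degrees.
    """
    _check_overlaps(events)
    n_frames = int(round(duration * config.fps))
    t = np.arange(n_frames) / config.fps
    gaze = np.zeros((n_frames, 2))

    for ev in events:
        if ev.offset > duration + 1e-9:
            raise ValueError(f"event {ev} extends past trajectory duration {duration}")
        ang = np.deg2rad(ev.direction)
        s = ev.displacement_at(t)
        gaze[:, 0] += s * np.cos(ang)
        gaze[:, 1] += s * np.sin(ang)

    rng = np.random.default_rng(seed)
    if drift_sigma > 0:
        dt = 1.0 / config.fps
        tau = 1.0  # s, drift relaxation toward the fixation point
        walk = np.zeros((n_frames, 2))
        noise = rng.normal(0.0, drift_sigma * np.sqrt(dt), size=(n_frames, 2))
        for k in range(1, n_frames):
            walk[k] = walk[k - 1] * (1.0 - dt / tau) + noise[k]
        walk = ndi.gaussian_filter1d(walk, sigma=max(config.fps * 0.03, 1.0), axis=0)
        walk -= walk[0]
        gaze = gaze + walk
    for ev in events:
        if ev.kind == "drift_segment":
            sel = (t >= ev.onset) & (t < ev.offset)
            extra = rng.normal(0.0, ev.amplitude / np.sqrt(config.fps), size=(sel.sum(), 2))
            seg = np.cumsum(extra, axis=0)
            seg = ndi.gaussian_filter1d(seg, sigma=max(config.fps * 0.03, 1.0), axis=0)
            gaze[sel] += seg - seg[0]

    per_eye = np.repeat(gaze[:, None, :], config.n_eyes, axis=1)
    if eye_offsets is not None:
        per_eye = per_eye + np.asarray(eye_offsets, dtype=float)[None, :, :]

    realized = [
        RealizedEvent(
            spec=ev,
            onset_frame=int(np.floor(ev.onset * config.fps)),
            offset_frame=min(int(np.ceil(ev.offset * config.fps)), n_frames - 1),
        )
        for ev in events
        if ev.kind in SACCADIC_KINDS
    ]
    realized.sort(key=lambda r: r.onset_frame)
    return per_eye, realized


# ----------------------------------------------------------------------
def similarity_about(
    center: tuple[float, float],
    scale: float = 1.0,
    rotation: float = 0.0,
    translation: tuple[float, float] = (0.0, 0.0),
) -> SimilarityTransform:
    """Similarity with rotation/scaling taken about ``center`` plus a translation."""
    cx, cy = center
    c, s = np.cos(rotation), np.sin(rotation)
    tx = translation[0] + cx - scale * (c * cx - s * cy)
    ty = translation[1] + cy - scale * (s * cx + c * cy)
    return SimilarityTransform(scale=scale, rotation=rotation, tx=tx, ty=ty)


def make_head_motion(
    kind: str,
    amplitude: float,
    frequency: float,
    n_frames: int,
    fps: float,
    seed: int | None = 0,
    direction: tuple[float, float] = (0.8, 0.6),
    rotation_amplitude: float = 0.0,
    scale_amplitude: float = 0.0,
    center: tuple[float, float] = (256.0, 144.0),
) -> list[SimilarityTransform]:
    """Translation-dominant planar head motion, identity at frame 0.

    ``sinusoid`` emulates the rigid-model experiment: oscillation of peak
    displacement ``amplitude`` px along ``direction`` at ``frequency`` Hz,
    with optional small sinusoidal rotation/scale components about
    ``center``.  ``random_walk`` is a low-pass random walk scaled so its
    maximum excursion is ``amplitude`` px.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    t = np.arange(n_frames) / fps
    d = np.asarray(direction, dtype=float)
    d = d / max(np.linalg.norm(d), 1e-12)
    if kind == "sinusoid":
        mod = np.sin(2 * np.pi * frequency * t)
        trans = amplitude * mod[:, None] * d[None, :]
        rots = rotation_amplitude * mod
        scales = 1.0 + scale_amplitude * mod
    elif kind == "random_walk":
        rng = np.random.default_rng(seed)
        walk = np.cumsum(rng.standard_normal((n_frames, 2)), axis=0)
        walk = ndi.gaussian_filter1d(walk, sigma=max(fps * 0.05, 1.0), axis=0)
        walk -= walk[0]
        peak = np.abs(walk).max()
        trans = walk * (amplitude / peak if peak > 0 else 0.0)
        rots = np.zeros(n_frames)
        scales = np.ones(n_frames)
    else:
        raise ValueError(f"unknown head motion kind {kind!r}")
    return [
        similarity_about(center, scale=float(scales[k]), rotation=float(rots[k]),
                         translation=(float(trans[k, 0]), float(trans[k, 1])))
        for k in range(n_frames)
    ]


# ----------------------------------------------------------------------
def _build_canvas(config: SceneConfig, seed: int,
                  markers: list[tuple[float, float]] | None) -> np.ndarray:
    """Static scene background: skin, weak global texture, four cheek patches."""
    h, w = config.frame_height, config.frame_width
    rng = np.random.default_rng(seed)
    canvas = np.full((h, w), 0.65, dtype=np.float32)
    canvas += 0.015 * _bandpass_noise((h, w), (1.5, 5.0), rng).astype(np.float32)
    patch_tex = _bandpass_noise((h, w), (1.0, 3.0), rng).astype(np.float32)
    margin = 16
    for x0, y0, pw, ph in config.patch_regions():
        ys = slice(max(y0 - margin, 0), min(y0 + ph + margin, h))
        xs = slice(max(x0 - margin, 0), min(x0 + pw + margin, w))
        canvas[ys, xs] = 0.60 + 0.11 * patch_tex[ys, xs]
    if markers:
        yy, xx = np.mgrid[0:h, 0:w]
        for mx, my in markers:
            canvas += 0.30 * np.exp(-((xx - mx) ** 2 + (yy - my) ** 2) / (2 * 1.8**2)).astype(
                np.float32
            )
    return np.clip(canvas, 0, 1)


def render(
    config: SceneConfig,
    gaze_deg: np.ndarray,
    head_motion: list[SimilarityTransform] | None = None,
    seed: int | None = 0,
    events: list[RealizedEvent] | None = None,
    markers: list[tuple[float, float]] | None = None,
) -> tuple[np.ndarray, GroundTruthScene]:
    """Render the scene to an 8-bit grey frame stack plus ground truth.

    The eye is placed at ``eye_center + gaze_deg * px_per_degree`` with
    sub-pixel (bilinear) texture sampling, the head transform is applied to
    the fully composited frame, and Gaussian sensor noise is added last.
    """
    gaze_deg = np.asarray(gaze_deg, dtype=float)
    if gaze_deg.ndim == 2:
        gaze_deg = np.repeat(gaze_deg[:, None, :], config.n_eyes, axis=1)
    n_frames = len(gaze_deg)
    if head_motion is None:
        head_motion = [SimilarityTransform.identity()] * n_frames
    if len(head_motion) != n_frames:
        raise ValueError("trajectory and head_motion must have equal length")

    h, w = config.frame_height, config.frame_width
    centers = config.eye_centers
    tex = generate_iris_texture(config)
    tex_c = (tex.shape[0] - 1) / 2.0
    canvas0 = _build_canvas(config, seed=(config.texture_seed + 1), markers=markers)
    rng = np.random.default_rng(seed)

    # static eye aperture (sclera disk) around each rest position
    sclera_r = config.iris_radius + 24.0
    boxes = config.eye_boxes()
    pad = 26  # accommodates head motion in the ground-truth mask crops
    mask_boxes = [
        (x0 - pad, y0 - pad, bw + 2 * pad, bh + 2 * pad) for (x0, y0, bw, bh) in boxes
    ]

    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    identity = SimilarityTransform.identity()

    # per-eye-box sampling grids (frame coords)
    grids = []
    for x0, y0, bw, bh in boxes:
        yy, xx = np.mgrid[y0 : y0 + bh, x0 : x0 + bw].astype(np.float32)
        grids.append((xx, yy))

    for k in range(n_frames):
        frame = canvas0.copy()
        for e in range(config.n_eyes):
            cx0, cy0 = centers[e]
            gx, gy = gaze_deg[k, e]
            cx = cx0 + gx * config.px_per_degree
            cy = cy0 + gy * config.px_per_degree
            x0, y0, bw, bh = boxes[e]
            if (
                cx - config.iris_radius < 1
                or cx + config.iris_radius > w - 1
                or cy - config.iris_radius < 1
                or cy + config.iris_radius > h - 1
            ):
                raise ValueError(f"eye {e} rendered outside frame bounds at frame {k}")
            xx, yy = grids[e]
            sub = frame[y0 : y0 + bh, x0 : x0 + bw]
            r_ap = np.hypot(xx - cx0, yy - cy0)
            w_scl = np.clip(sclera_r - r_ap + 0.5, 0, 1)
            sub[:] = sub * (1 - w_scl) + 0.88 * w_scl
            r = np.hypot(xx - cx, yy - cy)
            w_iris = np.clip(config.iris_radius - r + 0.5, 0, 1)
            tex_vals = ndi.map_coordinates(
                tex,
                np.stack([(yy - cy) + tex_c, (xx - cx) + tex_c]).reshape(2, -1),
                order=1,
                mode="nearest",
            ).reshape(bh, bw)
            sub[:] = sub * (1 - w_iris) + tex_vals * w_iris
            w_pup = np.clip(config.pupil_radius - r + 0.5, 0, 1)
            sub[:] = sub * (1 - w_pup) + 0.08 * w_pup
            lid_cut = cy - config.iris_radius + config.eyelid_occlusion * 2 * config.iris_radius
            if config.eyelid_occlusion > 0:
                w_lid = np.clip(lid_cut - yy + 0.5, 0, 1)
                sub[:] = sub * (1 - w_lid) + 0.65 * w_lid

        hm = head_motion[k]
        if hm.is_close(identity, atol=1e-12):
            out = frame
        else:
            out = warp_image(frame, hm, order=1, cval=0.65)

        if config.sensor_noise_sigma > 0:
            noisy = out * 255.0 + rng.normal(0.0, config.sensor_noise_sigma, size=out.shape)
        else:
            noisy = out * 255.0
        frames[k] = np.clip(np.round(noisy), 0, 255).astype(np.uint8)

    truth = GroundTruthScene(
        gaze_deg=gaze_deg,
        head_transforms=list(head_motion),
        mask_boxes=mask_boxes,
        events=list(events or []),
        fps=config.fps,
        px_per_degree=config.px_per_degree,
        frame_shape=(h, w),
        eye_centers=centers,
        iris_radius=config.iris_radius,
        eyelid_occlusion=config.eyelid_occlusion,
    )
    return frames, truth


# ----------------------------------------------------------------------
def make_calibration_trajectory(
    config: SceneConfig,
    targets: np.ndarray | None = None,
    dwell: float = 0.5,
    seed: int | None = 0,
    drift_sigma: float = 0.0,
) -> tuple[np.ndarray, list[dict]]:
    """Gaze trajectory visiting a target grid, plus its known-gaze schedule.

    Default targets are the 9-point grid at x, y in {-0.75, 0, +0.75} deg.
    Each target is fixated for ``dwell`` seconds with saccadic transitions
    on the main sequence.  The schedule lists, per target, the central 60%
    of its fixation window (transition settled) and the commanded gaze.
    """
    if targets is None:
        g = np.array([-0.75, 0.0, 0.75])
        targets = np.array([(x, y) for y in g for x in g])
    targets = np.asarray(targets, dtype=float)
    if len(targets) < 2:
        raise ValueError("at least two calibration targets are required")

    events = []
    # jump to target 0 at time 0.1 s, then between targets every `dwell`
    duration = 0.2 + dwell * len(targets)
    schedule = []
    t_arrive = 0.1
    prev = np.array([0.0, 0.0])
    for i, tgt in enumerate(targets):
        delta = tgt - prev
        amp = float(np.hypot(*delta))
        if amp > 1e-9:
            events.append(
                GazeEventSpec(
                    kind="saccade" if amp >= 0.5 else "microsaccade",
                    onset=t_arrive,
                    amplitude=amp,
                    direction=float(np.rad2deg(np.arctan2(delta[1], delta[0]))),
                )
            )
        window = (t_arrive + 0.1, t_arrive + dwell - 0.05)
        w0 = window[0] + 0.2 * (window[1] - window[0])
        w1 = window[1] - 0.2 * (window[1] - window[0])
        schedule.append({"t0": w0, "t1": w1, "gx": float(tgt[0]), "gy": float(tgt[1])})
        prev = tgt
        t_arrive += dwell
    gaze, _ = build_trajectory(events, duration, config, drift_sigma=drift_sigma, seed=seed)
    return gaze, schedule
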