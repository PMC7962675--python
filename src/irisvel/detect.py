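"""Microsaccade detection with an adaptive velocity threshold.

A velocity-threshold classifier (I-VT) on the absolute cyclopean speed
trace, with the threshold adapted per trial: a two-component Gaussian
mixture is fitted to all speed samples below 20 deg/s (the two components
model tracker noise and microsaccades), and the threshold is the noise
component's mean plus three standard deviations — covering 99.7% of the
noise distribution — floored at 3.84 deg/s, an empirical noise-floor bound
that keeps false alarms down when a trial is unusually clean.  Excursions
peaking at or above 50 deg/s are classified as ordinary saccades and
excluded from microsaccade outputs; velocity peaks closer than 5 frames
(52 ms at 96 fps) are merged into a single event so post-saccadic
oscillations and overshoot corrections are not double-counted.

Event amplitude is the displacement of the (per-eye and cyclopean) position
between the two local minima of the speed trace flanking the event — the
same landmarks that define the event span in all outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture


@dataclass
class DetectionConfig:
    """Fixed cuts of the detector (all velocities in deg/s)."""

    gmm_input_cut: float = 20.0     # only speeds below this reach the mixture fit
    threshold_floor: float = 3.84   # empirical noise-floor lower bound
    saccade_cut: float = 50.0       # peak speed at/above this => saccade
    min_separation: int = 5         # frames between distinct velocity peaks
    sigma_mult: float = 3.0         # "99.7%" of the noise distribution
    min_run_length: int = 1         # supra-threshold frames needed to seed an event
    min_gmm_samples: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.threshold_floor < self.gmm_input_cut < self.saccade_cut:
            raise ValueError(
                "need 0 < threshold_floor < gmm_input_cut < saccade_cut, got "
                f"{self.threshold_floor}, {self.gmm_input_cut}, {self.saccade_cut}"
            )
        if self.min_separation < 1 or self.min_run_length < 1:
            raise ValueError("min_separation and min_run_length must be >= 1")


@dataclass
class VelocityGMM:
    """Two-component 1-D Gaussian mixture over sub-20 deg/s speeds."""

    means: np.ndarray    # (2,) deg/s, sorted ascending
    stds: np.ndarray     # (2,) deg/s
    weights: np.ndarray  # (2,), sum to 1

    def __post_init__(self) -> None:
        if not np.all(self.stds > 0):
            raise ValueError("component stds must be positive")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")

    @property
    def noise_mean(self) -> float:
        """Mean of the lower-mean (noise) component."""
        return float(self.means[0])

    @property
    def noise_std(self) -> float:
        return float(self.stds[0])


class InsufficientSamplesError(ValueError):
    """Raised when too few sub-cut samples exist to fit the mixture.

    Callers should fall back to floor-only thresholding."""


def fit_velocity_gmm(
    speed: np.ndarray,
    config: DetectionConfig | None = None,
    seed: int = 0,
) -> VelocityGMM:
    """EM fit of the two-velocity mixture on samples below the input cut.

    Deterministic given ``seed`` (k-means initialization).  Raises
    :class:`InsufficientSamplesError` below ``min_gmm_samples`` valid
    samples and ``ValueError`` on degenerate (zero-spread) input.
    """
    config = config or DetectionConfig()
    s = np.asarray(speed, dtype=float).ravel()
    s = s[np.isfinite(s)]
    s = s[s < config.gmm_input_cut]
    if len(s) < config.min_gmm_samples:
        raise InsufficientSamplesError(
            f"only {len(s)} speed samples below {config.gmm_input_cut} deg/s "
            f"(need {config.min_gmm_samples}); use floor-only thresholding"
        )
    if np.ptp(s) < 1e-12:
        raise ValueError("all speed samples are identical; mixture fit is degenerate")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        random_state=seed,
        n_init=1,
        max_iter=300,
        reg_covar=1e-8,
    )
    gm.fit(s[:, None])
    means = gm.means_.ravel()
    stds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    return VelocityGMM(means=means[order], stds=stds[order], weights=weights[order])


def adaptive_threshold(gmm: VelocityGMM, config: DetectionConfig | None = None) -> float:
    """Detection threshold: ``max(noise_mean + 3 * noise_std, 3.84)`` deg/s."""
    config = config or DetectionConfig()
    candidate = gmm.noise_mean + config.sigma_mult * gmm.noise_std
    return float(max(candidate, config.threshold_floor))


# ----------------------------------------------------------------------
@dataclass
class EventRecord:
    """A classified eye-movement event on the cyclopean speed trace.

    Frame indices refer to the *speed* trace (sample k spans video frames
    k and k+1).  ``left_min``/``right_min`` are the flanking speed minima
    that define the event span and the amplitude baseline.
    """

    onset: int
    offset: int
    peak_frame: int
    peak_speed: float
    amplitude: float = np.nan
    label: str = "microsaccade"
    left_min: int = -1
    right_min: int = -1
    eye_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    amplitude_approximate: bool = False

    def __post_init__(self) -> None:
        if self.onset > self.offset:
            raise ValueError("onset must not exceed offset")


def _local_min_left(speed: np.ndarray, i: int) -> int:
    while i > 0 and np.isfinite(speed[i - 1]) and speed[i - 1] <= speed[i]:
        i -= 1
    return i


def _local_min_right(speed: np.ndarray, i: int) -> int:
    n = len(speed)
    while i < n - 1 and np.isfinite(speed[i + 1]) and speed[i + 1] <= speed[i]:
        i += 1
    return i


def detect_events(
    speed: np.ndarray,
    threshold: float,
    config: DetectionConfig | None = None,
    positions: dict[str, np.ndarray] | None = None,
) -> list[EventRecord]:
    """I-VT event extraction from the cyclopean speed trace.

    Maximal runs of samples with ``speed > threshold`` (of at least
    ``min_run_length`` samples) seed candidate events; events whose peaks
    are closer than ``min_separation`` frames are merged; each surviving
    event is extended to the flanking local minima of the speed trace,
    labelled saccade iff its peak reaches ``saccade_cut``, and — when
    ``positions`` are supplied — assigned its amplitude.  Events that
    overlap gap (NaN) samples are dropped with a warning.
    """
    config = config or DetectionConfig()
    if threshold < config.threshold_floor - 1e-12:
        raise ValueError(
            f"threshold {threshold} below the configured floor {config.threshold_floor}"
        )
    s = np.asarray(speed, dtype=float).ravel()
    finite = np.isfinite(s)
    if not finite.any():
        warnings.warn("speed trace contains no valid samples")
        return []

    above = finite & (s > threshold)
    runs = []
    i = 0
    n = len(s)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        if j - i >= config.min_run_length:
            runs.append([i, j - 1])
        i = j
    if not runs:
        return []

    # merge runs whose peaks are closer than min_separation frames
    def run_peak(run):
        a, b = run
        return a + int(np.nanargmax(s[a : b + 1]))

    merged = [runs[0]]
    for run in runs[1:]:
        if run_peak(run) - run_peak(merged[-1]) < config.min_separation:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    events: list[EventRecord] = []
    for a, b in merged:
        peak = a + int(np.nanargmax(s[a : b + 1]))
        left = _local_min_left(s, a)
        right = _local_min_right(s, b)
        if np.isnan(s[left : right + 1]).any():
            warnings.warn(f"event at frames {a}-{b} overlaps a gap; dropped")
            continue
        ev = EventRecord(
            onset=left,
            offset=right,
            peak_frame=peak,
            peak_speed=float(s[peak]),
            label="saccade" if s[peak] >= config.saccade_cut else "microsaccade",
            left_min=left,
            right_min=right,
        )
        if positions is not None:
            event_amplitude(ev, positions)
        events.append(ev)
    return events


def event_amplitude(event: EventRecord, positions: dict[str, np.ndarray]) -> float:
    """Displacement between the flanking speed minima, cyclopean and per eye.

    ``positions`` maps eye labels to (n_frames, 2) degree position traces.
    Speed sample k sits between position samples k and k+1, so the
    amplitude baseline runs from position index ``left_min`` to
    ``right_min + 1``.  Minima at the trace boundary make the amplitude
    approximate (flagged, not dropped).
    """
    traces = list(positions.values())
    n_pos = len(traces[0])
    i0 = event.left_min
    i1 = min(event.right_min + 1, n_pos - 1)
    event.amplitude_approximate = event.left_min == 0 or event.right_min >= n_pos - 2
    per_eye = []
    for tr in traces:
        d = np.asarray(tr, dtype=float)[i1] - np.asarray(tr, dtype=float)[i0]
        per_eye.append(float(np.hypot(*d)))
    event.eye_amplitudes = np.array(per_eye)
    mean_pos = np.mean([np.asarray(tr, dtype=float) for tr in traces], axis=0)
    d = mean_pos[i1] - mean_pos[i0]
    event.amplitude = float(np.hypot(*d))
    return event.amplitude


def main_sequence(events: list[EventRecord]) -> tuple[float, dict]:
    """Main-sequence slope: least squares of peak speed vs amplitude through 0.

    Returns the slope (s^-1) and diagnostics (R^2, n used).  Events with
    zero or undefined amplitude are excluded with a warning; fewer than
    three usable events is an error.
    """
    amps = np.array([e.amplitude for e in events], dtype=float)
    peaks = np.array([e.peak_speed for e in events], dtype=float)
    bad = ~np.isfinite(amps) | (amps <= 0)
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} events with zero/undefined amplitude")
    amps, peaks = amps[~bad], peaks[~bad]
    if len(amps) < 3:
        raise ValueError("main-sequence fit requires at least 3 events with amplitude > 0")
    slope = float((peaks @ amps) / (amps @ amps))
    resid = peaks - slope * amps
    ss_tot = float((peaks**2).sum())
    diagnostics = {
        "n": int(len(amps)),
        "r2": 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0,
        "residual_rms": float(np.sqrt((resid**2).mean())),
    }
    return slope, diagnostics


# ----------------------------------------------------------------------
@dataclass
class DetectionScore:
    hits: int
    misses: int
    false_alarms: int
    rate_per_s: float
    matched_pairs: list[tuple[int, int]] = field(default_factory=list)


def score_detection(
    detected_onsets_s: np.ndarray,
    true_onsets_s: np.ndarray,
    tolerance_s: float = 0.05,
    valid_duration_s: float | None = None,
) -> DetectionScore:
    """Greedy one-to-one matching of detections to ground-truth events.

    Both onset lists must be sorted.  Each detection is matched to the
    nearest unmatched true event within ``tolerance_s``; unmatched
    detections are false alarms, unmatched true events misses.  The rate is
    detections per second of valid (non-gap) recording when
    ``valid_duration_s`` is given.
    """
    det = np.asarray(detected_onsets_s, dtype=float)
    tru = np.asarray(true_onsets_s, dtype=float)
    if np.any(np.diff(det) < 0) or np.any(np.diff(tru) < 0):
        raise ValueError("onset lists must be sorted")
    used = np.zeros(len(tru), dtype=bool)
    pairs = []
    for i, t in enumerate(det):
        if len(tru) == 0:
            break
        d = np.abs(tru - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tolerance_s:
            used[j] = True
            pairs.append((i, j))
    hits = len(pairs)
    rate = np.nan
    if valid_duration_s is not None and valid_duration_s > 0:
        rate = len(det) / valid_duration_s
    return DetectionScore(
        hits=hits,
        misses=int(len(tru) - hits),
        false_alarms=int(len(det) - hits),
        rate_per_s=float(rate),
        matched_pairs=pairs,
    )


def deduplicate_by_interval(
    events: list[EventRecord], fps: float, interval_s: float
) -> list[EventRecord]:
    """Keep one event (largest amplitude) per consecutive time interval.

    Optional filter mirroring protocols where exactly one voluntary
    movement is expected per target interval; all other events inside the
    interval are regarded as non-target movements.
    """
    if interval_s <= 0:
        raise ValueError("interval must be positive")
    by_bin: dict[int, EventRecord] = {}
    for ev in events:
        b = int((ev.peak_frame / fps) // interval_s)
        cur = by_bin.get(b)
        if cur is None or (np.nan_to_num(ev.amplitude) > np.nan_to_num(cur.amplitude)):
            by_bin[b] = ev
    return [by_bin[b] for b in sorted(by_bin)]
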