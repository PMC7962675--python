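"""Adaptive-threshold event detection: GMM, thresholding, events, scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irisvel import (
    DetectionConfig,
    VelocityGMM,
    adaptive_threshold,
    detect_events,
    event_amplitude,
    fit_velocity_gmm,
    main_sequence,
    score_detection,
)
from irisvel.detect import InsufficientSamplesError, deduplicate_by_interval


class TestGMMFit:
    def test_component_means_recovered(self):
        """0.6 N(1.5, 0.5^2) + 0.4 N(8, 2^2), n=5000: means within 0.2 deg/s."""
        rng = np.random.default_rng(123)
        n = 5000
        z = rng.random(n) < 0.6
        s = np.where(z, rng.normal(1.5, 0.5, n), rng.normal(8.0, 2.0, n))
        s = np.abs(s)
        gmm = fit_velocity_gmm(s, seed=0)
        assert abs(gmm.means[0] - 1.5) < 0.2
        assert abs(gmm.means[1] - 8.0) < 0.2

    def test_identical_samples_degenerate(self):
        with pytest.raises(ValueError):
            fit_velocity_gmm(np.full(200, 2.0), seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        s = np.abs(rng.normal(3, 2, 500))
        a = fit_velocity_gmm(s, seed=5)
        b = fit_velocity_gmm(s, seed=5)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.stds, b.stds)

    def test_too_few_samples_advises_floor(self):
        with pytest.raises(InsufficientSamplesError, match="floor"):
            fit_velocity_gmm(np.linspace(0, 10, 20), seed=0)

    def test_samples_above_cut_excluded(self):
        rng = np.random.default_rng(1)
        s = np.r_[np.abs(rng.normal(1, 0.3, 500)), np.full(100, 500.0)]
        gmm = fit_velocity_gmm(s, seed=0)
        assert gmm.means.max() < 20.0


class TestAdaptiveThreshold:
    def make(self, mean, std):
        return VelocityGMM(
            means=np.array([mean, 10.0]),
            stds=np.array([std, 2.0]),
            weights=np.array([0.7, 0.3]),
        )

    def test_floor_applies_when_candidate_low(self):
        assert adaptive_threshold(self.make(1.0, 0.5)) == 3.84

    def test_mean_plus_three_sigma(self):
        assert adaptive_threshold(self.make(2.0, 2.0)) == pytest.approx(8.0)

    def test_boundary_candidate_equals_floor(self):
        assert adaptive_threshold(self.make(1.5, 0.78)) == 3.84

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.floats(0.0, 10.0, allow_nan=False),
        st.floats(0.01, 5.0, allow_nan=False),
        st.floats(0.0, 2.0, allow_nan=False),
        st.floats(0.0, 2.0, allow_nan=False),
    )
    def test_monotone_in_noise_parameters_and_floored(self, m, s, dm, ds):
        t0 = adaptive_threshold(self.make(m, s))
        t1 = adaptive_threshold(self.make(m + dm, s + ds))
        assert t1 >= t0
        assert t0 >= 3.84


def bump(center, width, peak, n=200):
    """Speed trace with one smooth supra-threshold excursion."""
    s = np.abs(np.random.default_rng(0).normal(0.5, 0.2, n))
    k = np.arange(n)
    s += peak * np.exp(-0.5 * ((k - center) / width) ** 2)
    return s


class TestDetectEvents:
    def test_all_subthreshold_yields_nothing(self):
        s = np.full(100, 1.0)
        assert detect_events(s, 3.84) == []

    def test_single_excursion_is_one_microsaccade(self):
        s = bump(100, 2.0, 10.0)
        evs = detect_events(s, 3.84)
        assert len(evs) == 1
        assert evs[0].label == "microsaccade"
        assert evs[0].onset <= 100 <= evs[0].offset
        assert evs[0].peak_speed == pytest.approx(s.max(), rel=1e-6)

    def test_peaks_three_frames_apart_are_merged(self):
        s = np.full(60, 0.5)
        s[[20, 23]] = 10.0  # two peaks, 3 frames apart (< 5)
        evs = detect_events(s, 3.84)
        assert len(evs) == 1

    def test_peaks_beyond_min_separation_stay_distinct(self):
        s = np.full(60, 0.5)
        s[[20, 30]] = 10.0
        evs = detect_events(s, 3.84)
        assert len(evs) == 2

    def test_fast_excursion_labelled_saccade(self):
        s = bump(100, 2.0, 60.0)
        evs = detect_events(s, 3.84)
        assert len(evs) == 1
        assert evs[0].label == "saccade"
        micro = [e for e in evs if e.label == "microsaccade"]
        assert micro == []

    def test_event_over_gap_dropped_with_warning(self):
        s = bump(100, 2.0, 10.0)
        s[99] = np.nan
        with pytest.warns(UserWarning, match="gap"):
            evs = detect_events(s, 3.84)
        assert evs == []

    def test_all_gap_trace_warns_empty(self):
        with pytest.warns(UserWarning):
            assert detect_events(np.full(50, np.nan), 3.84) == []

    def test_threshold_below_floor_rejected(self):
        with pytest.raises(ValueError):
            detect_events(np.ones(50), 1.0)

    def test_merging_property_no_close_peaks(self):
        rng = np.random.default_rng(4)
        s = np.abs(rng.normal(1, 1.5, 400))
        s[rng.integers(0, 400, 25)] += 10
        cfg = DetectionConfig()
        evs = detect_events(s, 3.84, cfg)
        peaks = sorted(e.peak_frame for e in evs)
        assert all(b - a >= cfg.min_separation for a, b in zip(peaks, peaks[1:]))


class TestAmplitude:
    def make_event(self, left, right):
        from irisvel.detect import EventRecord

        return EventRecord(
            onset=left, offset=right, peak_frame=(left + right) // 2, peak_speed=10.0,
            left_min=left, right_min=right,
        )

    def test_zero_net_oscillation_zero_amplitude(self):
        pos = np.zeros((30, 2))
        pos[10:15, 0] = 0.2  # excursion that returns exactly
        ev = self.make_event(5, 19)  # position indices 5 .. 20 are both 0
        assert event_amplitude(ev, {"L": pos}) == pytest.approx(0.0)

    def test_horizontal_event_amplitude_is_abs_dx(self):
        pos = np.zeros((30, 2))
        pos[15:, 0] = -0.42
        ev = self.make_event(10, 20)
        assert event_amplitude(ev, {"L": pos}) == pytest.approx(0.42)

    def test_cyclopean_amplitude_averages_eyes(self):
        pl = np.zeros((30, 2))
        pr = np.zeros((30, 2))
        pl[15:, 0] = 0.2
        pr[15:, 0] = 0.4
        ev = self.make_event(10, 20)
        amp = event_amplitude(ev, {"L": pl, "R": pr})
        assert amp == pytest.approx(0.3)
        assert np.allclose(sorted(ev.eye_amplitudes), [0.2, 0.4])

    def test_boundary_minima_flagged_approximate(self):
        pos = np.zeros((10, 2))
        ev = self.make_event(0, 8)
        event_amplitude(ev, {"L": pos})
        assert ev.amplitude_approximate


class TestMainSequence:
    def make_events(self, amps, peaks):
        from irisvel.detect import EventRecord

        return [
            EventRecord(onset=i * 10, offset=i * 10 + 3, peak_frame=i * 10 + 1,
                        peak_speed=p, amplitude=a)
            for i, (a, p) in enumerate(zip(amps, peaks))
        ]

    def test_identical_events_exact_ratio(self):
        evs = self.make_events([0.3] * 4, [14.1] * 4)
        slope, diag = main_sequence(evs)
        assert slope == pytest.approx(47.0)
        assert diag["n"] == 4

    def test_zero_amplitude_event_excluded_with_warning(self):
        evs = self.make_events([0.3, 0.0, 0.4, 0.5], [14.1, 5.0, 18.8, 23.5])
        with pytest.warns(UserWarning, match="exclud"):
            slope, diag = main_sequence(evs)
        assert diag["n"] == 3
        assert slope == pytest.approx(47.0)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            main_sequence(self.make_events([0.3, 0.4], [14.0, 19.0]))

    def test_generated_slope_recovered(self):
        rng = np.random.default_rng(0)
        amps = rng.uniform(0.1, 1.0, 30)
        peaks = 47.0 * amps * rng.normal(1.0, 0.03, 30)
        slope, _ = main_sequence(self.make_events(amps, peaks))
        assert slope == pytest.approx(47.0, rel=0.05)


class TestScoring:
    def test_identical_lists_all_hits(self):
        t = np.array([1.0, 2.0, 3.0])
        s = score_detection(t, t, 0.05, valid_duration_s=10.0)
        assert (s.hits, s.misses, s.false_alarms) == (3, 0, 0)
        assert s.rate_per_s == pytest.approx(0.3)

    def test_empty_detections_all_misses(self):
        s = score_detection(np.array([]), np.array([1.0, 2.0]), 0.05)
        assert (s.hits, s.misses, s.false_alarms) == (0, 2, 0)

    def test_offset_beyond_tolerance_is_miss_plus_false_alarm(self):
        s = score_detection(np.array([1.2]), np.array([1.0]), 0.05)
        assert (s.hits, s.misses, s.false_alarms) == (0, 1, 1)

    def test_matching_is_one_to_one(self):
        s = score_detection(np.array([1.0, 1.01]), np.array([1.0]), 0.05)
        assert s.hits == 1 and s.false_alarms == 1

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            score_detection(np.array([2.0, 1.0]), np.array([1.0]), 0.05)

    def test_interval_deduplication_keeps_largest(self):
        from irisvel.detect import EventRecord

        evs = [
            EventRecord(onset=0, offset=2, peak_frame=10, peak_speed=10, amplitude=0.2),
            EventRecord(onset=20, offset=22, peak_frame=21, peak_speed=12, amplitude=0.4),
            EventRecord(onset=200, offset=202, peak_frame=201, peak_speed=9, amplitude=0.3),
        ]
        kept = deduplicate_by_interval(evs, fps=96.0, interval_s=1.0)
        assert len(kept) == 2
        assert kept[0].amplitude == 0.4
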