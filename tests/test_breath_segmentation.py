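import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import imubreath as ib
from imubreath.breath_segmentation import (
    EXHALE,
    INHALE,
    BreathSegment,
    Phase,
    SegmentSummary,
    _alternating_extrema,
    _one_runs,
)


class TestEulerNormSq:
    @pytest.mark.parametrize("xyz,expected", [((0, 0, 0), 0.0), ((3, 4, 0), 25.0), ((1, 2, 2), 9.0)])
    def test_values(self, xyz, expected):
        assert ib.euler_norm_sq(*xyz) == expected

    def test_vectorized(self):
        x = np.array([1.0, 3.0])
        out = ib.euler_norm_sq(x, 2 * x, 2 * x)
        np.testing.assert_allclose(out, 9 * x**2)


class TestSmoothDecisions:
    def test_all_high_probabilities(self):
        assert np.all(ib.smooth_decisions(np.full(20, 0.9)) == 1)

    def test_isolated_activation_suppressed(self):
        out = ib.smooth_decisions(np.array([0.1, 0.1, 0.9, 0.1, 0.1, 0.1, 0.1]))
        assert np.all(out == 0)

    def test_long_run_not_fragmented(self):
        probs = np.concatenate([np.full(5, 0.1), np.full(10, 0.9), np.full(5, 0.1)])
        out = ib.smooth_decisions(probs)
        runs = _one_runs(out)
        assert len(runs) == 1
        start, stop = runs[0]
        assert stop - start >= 8  # the ten activations survive as one block

    def test_tie_rounds_to_breathing(self):
        # probability exactly at the threshold counts as breathing
        out = ib.smooth_decisions(np.full(6, 0.5), threshold=0.5)
        assert np.all(out == 1)

    def test_empty_input(self):
        assert ib.smooth_decisions(np.array([])).size == 0

    @settings(deadline=None, max_examples=150)
    @given(
        probs=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60),
        min_run=st.integers(1, 5),
    )
    def test_output_binary_with_no_short_runs(self, probs, min_run):
        out = ib.smooth_decisions(np.array(probs), min_run=min_run)
        assert set(np.unique(out)) <= {0, 1}
        for start, stop in _one_runs(out):
            assert stop - start >= min_run


class TestMergeSegments:
    def test_single_full_run(self):
        starts = np.arange(0.0, 11.0)  # 0..10 s
        segs = ib.merge_segments(np.ones(11, dtype=int), starts, window_size_s=6.06)
        assert len(segs) == 1
        assert segs[0].onset_s == 0.0
        assert segs[0].offset_s == pytest.approx(16.06)

    def test_no_activations(self):
        assert ib.merge_segments(np.zeros(5, dtype=int), np.arange(5.0), 2.0) == []

    def test_two_separated_runs(self):
        decisions = np.array([1, 1, 0, 1, 1, 1])
        segs = ib.merge_segments(decisions, np.arange(6.0), 2.0)
        assert [(s.onset_s, s.offset_s) for s in segs] == [(0.0, 3.0), (3.0, 7.0)]

    def test_gap_in_start_times_splits_run(self):
        # stride 1 s, but a 10 s jump between the 3rd and 4th window (a gap)
        starts = np.array([0.0, 1.0, 2.0, 12.0, 13.0])
        segs = ib.merge_segments(np.ones(5, dtype=int), starts, 2.0, step_s=1.0)
        assert [(s.onset_s, s.offset_s) for s in segs] == [(0.0, 4.0), (12.0, 15.0)]


def _breathing_rec(period=4.0, ie=0.6, duration=40.0, fs=33.0, noise=0.0, seed=0):
    spec = ib.SyntheticSpec(
        duration_s=duration, sampling_rate_hz=fs,
        breath_period_mean_s=period, breath_period_sd_s=0.0, ie_ratio=ie,
        breathing_spans=[(0.0, duration)], noise_episodes=[],
        sensor_noise_sd=noise, seed=seed,
    )
    return ib.simulate_recording(spec)


class TestDetectPhases:
    def test_asymmetric_cycle_durations_recovered(self):
        rec, gt = _breathing_rec(period=4.0, ie=0.6)
        seg = ib.detect_phases(rec, BreathSegment(0.0, 40.0))
        inhales = [p.duration_s for p in seg.phases if p.kind == INHALE]
        exhales = [p.duration_s for p in seg.phases if p.kind == EXHALE]
        grid = 2.0 / rec.sampling_rate_hz
        assert np.mean(inhales) == pytest.approx(2.4, abs=0.1 + grid)
        assert np.mean(exhales) == pytest.approx(1.6, abs=0.1 + grid)

    def test_phases_alternate_and_tile(self):
        rec, _ = _breathing_rec(noise=0.02, seed=3)
        seg = ib.detect_phases(rec, BreathSegment(0.0, 40.0))
        kinds = [p.kind for p in seg.phases]
        for a, b in zip(kinds, kinds[1:]):
            assert a != b
        for p, q in zip(seg.phases, seg.phases[1:]):
            assert p.end_s == pytest.approx(q.start_s)

    def test_monotone_signal_has_no_phases(self):
        n = 400
        euler = np.zeros((n, 3))
        euler[:, 0] = np.linspace(10.0, 20.0, n)
        rec = ib.ImuRecording("M", 33.0, euler, np.zeros((n, 3)), np.ones(n, dtype=bool))
        seg = ib.detect_phases(rec, BreathSegment(0.0, n / 33.0))
        assert seg.phases == []
        assert seg.breath_count == 0

    def test_peak_timing_invariant_under_square(self):
        rec, _ = _breathing_rec(noise=0.01, seed=5)
        sig_sq = ib.euler_norm_sq(rec.euler[:, 0], rec.euler[:, 1], rec.euler[:, 2])
        idx_sq, kind_sq = _alternating_extrema(sig_sq, rec.sampling_rate_hz)
        idx_rt, kind_rt = _alternating_extrema(np.sqrt(sig_sq), rec.sampling_rate_hz)
        np.testing.assert_array_equal(idx_sq, idx_rt)
        np.testing.assert_array_equal(kind_sq, kind_rt)

    def test_polarity_flag_swaps_phase_kinds(self):
        rec, _ = _breathing_rec()
        std = ib.detect_phases(rec, BreathSegment(0.0, 40.0), polarity="standard")
        inv = ib.detect_phases(rec, BreathSegment(0.0, 40.0), polarity="inverted")
        assert [p.kind for p in std.phases] == [
            INHALE if p.kind == EXHALE else EXHALE for p in inv.phases
        ]
        with pytest.raises(ValueError):
            ib.detect_phases(rec, BreathSegment(0.0, 40.0), polarity="upside-down")


class TestSummarize:
    def _segment(self, inhale_s, exhale_s, n=10):
        phases, t = [], 0.0
        for _ in range(n):
            phases.append(Phase(INHALE, t, t + inhale_s))
            t += inhale_s
            phases.append(Phase(EXHALE, t, t + exhale_s))
            t += exhale_s
        return BreathSegment(0.0, t, phases)

    def test_mean_cycle_is_sum_of_phase_means(self):
        # the two published case-study segments
        report = ib.summarize(
            [self._segment(3.974, 1.589, n=10), self._segment(2.402, 1.802, n=18)]
        )
        df = report.to_frame()
        assert df.loc[0, "breaths"] == 10
        assert df.loc[0, "breathing_duration_s"] == pytest.approx(5.563)
        assert df.loc[1, "breaths"] == 18
        assert df.loc[1, "breathing_duration_s"] == pytest.approx(4.204)
        for s in report.summaries:
            assert s.mean_cycle_s == s.mean_inhale_s + s.mean_exhale_s  # exact

    def test_zero_breath_segments_counted_not_listed(self):
        empty = BreathSegment(0.0, 5.0, [])
        report = ib.summarize([self._segment(2.0, 1.5, n=3), empty])
        assert len(report.summaries) == 1
        assert report.n_zero_breath_segments == 1

    def test_breath_count_pairs_only(self):
        # exhale-first segment: leading exhale does not form a breath
        phases = [Phase(EXHALE, 0, 1), Phase(INHALE, 1, 3), Phase(EXHALE, 3, 4)]
        assert BreathSegment(0, 4, phases).breath_count == 1


class TestEndToEnd:
    def test_recording_shorter_than_window_gives_empty_track(self, trained_small_model, small_cfg):
        rec, _ = _breathing_rec(duration=2.0)
        track = ib.classify_recording(trained_small_model, rec, small_cfg)
        assert track.probabilities.size == 0
        _, segments, report = ib.segment_recording(trained_small_model, rec, small_cfg)
        assert segments == []
        assert report.to_frame().empty

    def test_segments_never_span_gaps(self, trained_small_model, small_cfg):
        spec = ib.SyntheticSpec(
            duration_s=90.0, sampling_rate_hz=33.0,
            breathing_spans=[(0.0, 40.0), (50.0, 90.0)],
            noise_episodes=[], gap_spans=[(42.0, 48.0)], seed=23,
        )
        rec, _ = ib.simulate_recording(spec)
        _, segments, _ = ib.segment_recording(trained_small_model, rec, small_cfg)
        assert segments, "breathing should be detected on both sides of the gap"
        for seg in segments:
            assert not (seg.onset_s < 42.0 and seg.offset_s > 48.0)

    def test_sixty_second_span_recovered(self, trained_small_model, small_cfg):
        spec = ib.SyntheticSpec(
            duration_s=90.0, sampling_rate_hz=33.0,
            breath_period_mean_s=4.0, breath_period_sd_s=0.0,
            breathing_spans=[(10.0, 70.0)],
            noise_episodes=[(0.0, 8.0), (72.0, 90.0)],
            seed=42,
        )
        rec, _ = ib.simulate_recording(spec)
        _, segments, report = ib.segment_recording(trained_small_model, rec, small_cfg)
        best = max(
            segments,
            key=lambda s: min(s.offset_s, 70.0) - max(s.onset_s, 10.0),
        )
        inter = max(0.0, min(best.offset_s, 70.0) - max(best.onset_s, 10.0))
        union = max(best.offset_s, 70.0) - min(best.onset_s, 10.0)
        assert inter / union >= 0.8
        # one 60 s span at a 4 s cycle holds 15 breaths
        assert best.breath_count == pytest.approx(15, abs=3)
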