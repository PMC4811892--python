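"""Ocular preprocessing: blinks, screening, baselines, %ERPD, epoching."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tests.conftest import make_trace, make_trial
from vocogaze.ocular import (
    InsufficientContextError,
    compute_baseline,
    count_fixations,
    detect_blinks,
    epoch,
    erpd,
    interpolate_blink,
    read_trace_tsv,
    read_trials_tsv,
    screen_participant,
    screen_trial,
    write_trace_tsv,
    write_trials_tsv,
)


def trace_with_gap(n=2000, gap_start=1000, gap_len=50, level=1000.0):
    pupil = np.full(n, level)
    pupil[gap_start:gap_start + gap_len] = 0.0
    return make_trace(pupil)


class TestDetectBlinks:
    def test_clean_trace_no_blinks(self):
        assert detect_blinks(make_trace(np.full(500, 900.0))) == []

    def test_single_gap_duration(self):
        events = detect_blinks(trace_with_gap(gap_len=50))  # 50 samples @250 Hz
        assert len(events) == 1
        assert events[0].duration_ms == pytest.approx(200.0)

    def test_two_gaps_in_time_order(self):
        pupil = np.full(2000, 800.0)
        pupil[100:120] = 0.0
        pupil[500:560] = 0.0
        events = detect_blinks(make_trace(pupil))
        assert len(events) == 2
        assert events[0].start_ms < events[1].start_ms


class TestInterpolateBlink:
    def test_constant_trace_restored_exactly(self):
        trace = trace_with_gap(level=1000.0)
        ev = detect_blinks(trace)[0]
        repaired = interpolate_blink(trace, ev)
        assert np.all(repaired.pupil == 1000.0)
        assert repaired.valid.all()

    def test_linear_ramp_between_median_anchors(self):
        pupil = np.concatenate([np.full(100, 900.0), np.zeros(5), np.full(100, 1000.0)])
        trace = make_trace(pupil)
        ev = detect_blinks(trace)[0]
        repaired = interpolate_blink(trace, ev)
        # line joins the sample before the gap (900) to the one after (1000)
        expected = 900.0 + (np.arange(1, 6) / 6.0) * 100.0
        assert repaired.pupil[100:105] == pytest.approx(expected)

    def test_median_anchor_robust_to_outlier(self):
        pupil = np.concatenate([np.full(100, 900.0), np.zeros(5), np.full(100, 900.0)])
        pupil[95] = 5000.0  # spike inside the 25-sample context
        trace = make_trace(pupil, valid=pupil > 0)
        ev = detect_blinks(trace)[0]
        repaired = interpolate_blink(trace, ev)
        assert np.all(repaired.pupil[100:105] == 900.0)
        # a mean-anchored repair would have shifted the gap upward
        mean_anchor = np.mean(pupil[75:100])
        assert mean_anchor > 900.0

    def test_insufficient_context_flagged(self):
        pupil = np.concatenate([np.full(10, 900.0), np.zeros(5), np.full(100, 900.0)])
        trace = make_trace(pupil)
        ev = detect_blinks(trace)[0]
        with pytest.raises(InsufficientContextError):
            interpolate_blink(trace, ev)

    def test_only_gap_samples_touched(self):
        trace = trace_with_gap()
        ev = detect_blinks(trace)[0]
        repaired = interpolate_blink(trace, ev)
        outside = np.ones(len(trace), dtype=bool)
        outside[ev.start_idx:ev.end_idx] = False
        assert np.array_equal(repaired.pupil[outside], trace.pupil[outside])
        assert len(repaired) == len(trace)


def trial_trace_with_blink(blink_ms, word_onset=2000.0, n=1500, level=1000.0):
    """Correct-response trial with one blink of given duration after onset."""
    pupil = np.full(n, level)
    start = int((word_onset + 500.0) / 4.0)
    pupil[start:start + int(round(blink_ms / 4.0))] = 0.0
    return make_trial(word_onset), make_trace(pupil)


class TestScreenTrial:
    def test_short_blink_kept_and_repaired(self):
        trial, trace = trial_trace_with_blink(120.0)
        res = screen_trial(trial, trace)
        assert res.keep and res.trace.valid.all()

    def test_long_blink_excluded(self):
        trial, trace = trial_trace_with_blink(400.0)
        res = screen_trial(trial, trace)
        assert not res.keep and res.reason == "long_blink"

    def test_wrong_click_excluded(self):
        trial = make_trial(clicked="competitor", correct=False)
        trace = make_trace(np.full(1500, 1000.0))
        res = screen_trial(trial, trace)
        assert not res.keep and res.reason == "incorrect_click"

    @pytest.mark.parametrize("blink_ms,kept", [(296.0, True), (300.0, False),
                                               (304.0, False)])
    def test_exclusion_boundary_at_300_ms(self, blink_ms, kept):
        trial, trace = trial_trace_with_blink(blink_ms)
        assert screen_trial(trial, trace).keep is kept

    def test_screening_idempotent(self):
        trial, trace = trial_trace_with_blink(120.0)
        first = screen_trial(trial, trace)
        second = screen_trial(trial, first.trace)
        assert second.keep
        assert np.array_equal(first.trace.pupil, second.trace.pupil)


class TestScreenParticipant:
    @pytest.mark.parametrize("n_bad,kept", [(0, True), (30, True), (31, False)])
    def test_half_bad_rule(self, n_bad, kept):
        from vocogaze.ocular import ScreenResult

        results = ([ScreenResult(False, "incorrect_click")] * n_bad
                   + [ScreenResult(True)] * (62 - n_bad))
        assert screen_participant(results) is kept


class TestBaselines:
    def test_constant_trace_either_kind(self):
        trace = make_trace(np.full(2000, 800.0))
        trial = make_trial(4000.0)
        assert compute_baseline(trace, trial, kind=1) == 800.0
        assert compute_baseline(trace, kind=2, first_sentence_onset_ms=3000.0) == 800.0

    def test_linear_ramp_gives_window_midpoint_mean(self):
        pupil = np.linspace(0.0, 1999.0 * 4, 2000)  # 4 units per sample
        trace = make_trace(pupil, valid=np.ones(2000, bool))
        trial = make_trial(4000.0)
        # window [3800, 4000) = samples 950..999, mean of a linear function
        expected = np.mean(pupil[950:1000])
        assert compute_baseline(trace, trial, kind=1) == pytest.approx(expected)

    def test_window_is_50_samples_at_250hz(self):
        pupil = np.full(2000, 500.0)
        pupil[950:1000] = 700.0  # exactly the 200 ms before word onset
        trace = make_trace(pupil)
        assert compute_baseline(trace, make_trial(4000.0), kind=1) == 700.0

    def test_unrepaired_gap_in_window_rejected(self):
        pupil = np.full(2000, 500.0)
        pupil[960:970] = 0.0
        trace = make_trace(pupil)
        with pytest.raises(ValueError, match="gap"):
            compute_baseline(trace, make_trial(4000.0), kind=1)


class TestErpd:
    @pytest.mark.parametrize("obs,base,expected", [(1000.0, 1000.0, 0.0),
                                                   (1100.0, 1000.0, 10.0),
                                                   (900.0, 1000.0, -10.0)])
    def test_formula(self, obs, base, expected):
        assert erpd(obs, base) == pytest.approx(expected)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            erpd(1000.0, 0.0)

    @given(st.floats(min_value=0.01, max_value=100.0),
           st.floats(min_value=100.0, max_value=5000.0),
           st.floats(min_value=100.0, max_value=5000.0))
    def test_scale_invariance(self, c, obs, base):
        assert erpd(c * obs, c * base) == pytest.approx(erpd(obs, base), abs=1e-8)


class TestEpoch:
    def test_450_samples_start_200_step_4ms(self):
        trace = make_trace(np.full(2000, 1000.0))
        ep = epoch(trace, make_trial(4000.0))
        assert len(ep) == 450
        assert ep.time_ms[0] == pytest.approx(200.0)
        assert np.allclose(np.diff(ep.time_ms), 4.0)

    def test_truncated_trial_rejected(self):
        trace = make_trace(np.full(500, 1000.0))
        with pytest.raises(ValueError, match="truncated"):
            epoch(trace, make_trial(1500.0))


class TestCountFixations:
    def test_single_aoi_is_one_fixation(self):
        assert count_fixations(["target"] * 450) == 1

    def test_alternating_samples_count_zero(self):
        labels = ["target", "competitor"] * 225
        assert count_fixations(labels) == 0

    def test_three_constructed_dwells(self):
        labels = (["target"] * 75 + ["competitor"] * 75 + ["center"] * 75)
        assert count_fixations(labels) == 3  # three 300-ms dwells

    def test_off_grid_samples_never_fixations(self):
        assert count_fixations([None] * 450) == 0


class TestTsvRoundtrip:
    def test_trace_roundtrip(self, tmp_path):
        trace = trace_with_gap()
        path = tmp_path / "trace.tsv"
        write_trace_tsv(path, trace)
        back = read_trace_tsv(path)
        assert back.rate == pytest.approx(trace.rate)
        assert np.allclose(back.pupil, trace.pupil)
        assert np.array_equal(back.valid, trace.valid)

    def test_trials_roundtrip(self, tmp_path):
        trials = [make_trial(2000.0, trial_id=0), make_trial(6000.0, trial_id=1)]
        path = tmp_path / "trials.tsv"
        write_trials_tsv(path, trials)
        back = read_trials_tsv(path)
        assert back == trials
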