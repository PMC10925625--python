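"""Blink-offset estimator: per-signal ops, aggregation, end-to-end recovery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vrsync.blink_sync import (
    BlinkEvent,
    BlinkOffsetModel,
    BlinkSyncConfig,
    BlinkSyncError,
    aggregate_offsets,
    closure_from_openness,
    emg_peak_index,
    estimate_offset,
    filter_emg,
    find_blink_onsets,
    select_trimming,
    single_blink_offset,
)
from vrsync.streams import TimedStream
from vrsync.synth import BlinkSimParams, simulate_blink_recording

RATE = 250.0


class TestFilterEmg:
    def test_dc_rejected(self):
        out = filter_emg(np.full(2500, 5.0), RATE)
        mid = out[500:-500]
        assert np.max(np.abs(mid)) < 1e-3 * 5.0

    def test_in_band_2hz_preserved(self):
        t = np.arange(2500) / RATE
        out = filter_emg(np.sin(2 * np.pi * 2.0 * t), RATE)
        mid_amp = np.max(np.abs(out[500:-500]))
        assert 0.95 < mid_amp < 1.05

    def test_50hz_attenuated_40db(self):
        t = np.arange(2500) / RATE
        out = filter_emg(np.sin(2 * np.pi * 50.0 * t), RATE)
        assert np.max(np.abs(out[500:-500])) < 10 ** (-40 / 20)

    def test_nan_rejected(self):
        x = np.zeros(100)
        x[3] = np.nan
        with pytest.raises(BlinkSyncError, match="non-finite"):
            filter_emg(x, RATE)

    def test_too_short_rejected(self):
        with pytest.raises(BlinkSyncError, match="short"):
            filter_emg(np.zeros(10), RATE)


class TestFindBlinkOnsets:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([0, 0, 1, 1, 0, 0, 1, 0], [2, 6]),
            ([0] * 6, []),
            ([1, 1, 0], [0]),
            ([1], [0]),
        ],
    )
    def test_examples(self, series, expected):
        assert find_blink_onsets(np.array(series, float)).tolist() == expected

    def test_non_binary_rejected(self):
        with pytest.raises(BlinkSyncError, match="binary"):
            find_blink_onsets(np.array([0.0, 0.5, 1.0]))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
    def test_matches_run_length_oracle(self, bits):
        # independent oracle: group consecutive equal values
        pos, expected = 0, []
        for val, grp in itertools.groupby(bits):
            n = len(list(grp))
            if val == 1:
                expected.append(pos)
            pos += n
        got = find_blink_onsets(np.array(bits, float)).tolist()
        assert got == expected
        assert got == sorted(got)


class TestClosureFromOpenness:
    def test_threshold_is_strict(self):
        out = closure_from_openness(np.array([1.0, 0.5, 0.05, 0.0, 0.3]), 0.1)
        assert out.tolist() == [0, 0, 1, 1, 0]
        assert closure_from_openness(np.array([0.1]), 0.1).tolist() == [0]

    def test_fully_open(self):
        assert closure_from_openness(np.ones(5)).sum() == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(BlinkSyncError, match=r"\[0, 1\]"):
            closure_from_openness(np.array([0.5, 1.2]))


class TestEmgPeakIndex:
    def test_triangle_90pct_crossing(self):
        # ramp 0..1 over indices 0..50, back down to 0 at 100:
        # value i/50 reaches 0.9 exactly at index 45
        w = np.concatenate([np.linspace(0, 1, 51), np.linspace(1, 0, 51)[1:]])
        assert emg_peak_index(w, 0.9) == 45

    def test_fraction_one_is_argmax(self):
        w = np.concatenate([np.linspace(0, 1, 51), np.linspace(1, 0, 51)[1:]])
        assert emg_peak_index(w, 1.0) == 50

    def test_flat_window_rejected(self):
        with pytest.raises(BlinkSyncError, match="no EMG peak"):
            emg_peak_index(np.zeros(100))


def _windows(onset_idx, crossing_idx, n=250):
    """Aligned eye/EMG windows with landmarks at the given indices."""
    eye = np.zeros(n)
    eye[onset_idx: onset_idx + 10] = 1.0
    emg = np.zeros(n)
    # rise 0..1 over 10 samples: value (i)/10 first reaches 0.9 one sample
    # before the maximum, i.e. at crossing_idx
    lo = crossing_idx - 9
    emg[lo: lo + 11] = np.linspace(0, 1, 11)
    emg[lo + 11: lo + 51] = np.linspace(1, 0, 41)[1:]
    return eye, emg


class TestSingleBlinkOffset:
    def test_nine_samples_is_36ms(self):
        eye, emg = _windows(30, 39)
        ev = single_blink_offset(eye, emg, emg_prefiltered=True)
        assert ev.valid
        assert ev.offset_ms == pytest.approx(36.0)
        assert ev.emg_peak_index - ev.eye_onset_index == 9

    def test_coincident_landmarks_zero_offset(self):
        eye, emg = _windows(60, 60)
        ev = single_blink_offset(eye, emg, emg_prefiltered=True)
        assert ev.offset_ms == pytest.approx(0.0)

    def test_emg_leading_gives_negative(self):
        eye, emg = _windows(75, 66)
        ev = single_blink_offset(eye, emg, emg_prefiltered=True)
        assert ev.offset_ms == pytest.approx(-36.0)

    def test_no_closure_rejected(self):
        _, emg = _windows(30, 39)
        with pytest.raises(BlinkSyncError, match="no closure"):
            single_blink_offset(np.zeros(250), emg, emg_prefiltered=True)

    def test_double_peak_flagged_distorted(self):
        eye, emg = _windows(30, 39)
        emg = emg + np.roll(emg, 80) * 0.9  # second comparable peak 320 ms later
        ev = single_blink_offset(eye, emg, emg_prefiltered=True)
        assert not ev.valid
        assert ev.exclusion_reason == "distorted_emg"


def _event(offset_ms):
    return BlinkEvent(0, 0, offset_ms, True, None)


class TestAggregateOffsets:
    def test_identical_offsets(self):
        est = aggregate_offsets([_event(36.0)] * 3)
        assert est.mean_offset_ms == 36.0
        assert est.std_ms == 0.0
        assert est.n_used == 3

    def test_three_sigma_outlier_excluded(self):
        # 20 x 36 ms plus one 500 ms event: mean 58.1, STD 101.2,
        # |500 - 58.1| = 441.9 > 3 x 101.2 -> excluded, mean returns to 36
        events = [_event(36.0) for _ in range(20)] + [_event(500.0)]
        est = aggregate_offsets(events)
        assert est.mean_offset_ms == pytest.approx(36.0)
        assert est.n_used == 20
        assert est.n_excluded == 1
        assert events[-1].exclusion_reason == "outlier"

    def test_single_event_rejected(self):
        with pytest.raises(BlinkSyncError, match="insufficient"):
            aggregate_offsets([_event(36.0)])

    @pytest.mark.parametrize("seed", range(5))
    def test_exclusion_never_increases_retained_std(self, seed):
        rng = np.random.default_rng(seed)
        offs = rng.normal(36, 5, 40).tolist() + rng.uniform(200, 400, 2).tolist()
        events = [_event(o) for o in offs]
        before = np.std(offs, ddof=1)
        est = aggregate_offsets(events)
        assert est.std_ms <= before + 1e-12


class TestSelectTrimming:
    def test_single_clean_recording_ties_to_first(self):
        rec, _ = simulate_blink_recording(BlinkSimParams(n_blinks=10, seed=1))
        strategy, est = select_trimming([rec])
        assert strategy == "none"
        assert est.n_used >= 8

    def test_corrupted_head_prefers_head_trim(self):
        rec_a, _ = simulate_blink_recording(BlinkSimParams(n_blinks=10, seed=2))
        rec_b, _ = simulate_blink_recording(BlinkSimParams(n_blinks=13, seed=3))
        # corrupt the first three blinks of B: shift their EMG bursts
        emg = rec_b["emg"]
        for k, shift in enumerate((10, 20, 30)):  # 20/40/60 ms at 500 Hz
            lo = int((2.0 + k - 0.45) * 500)
            hi = int((2.0 + k + 0.45) * 500)
            emg.samples[lo:hi, 0] = np.roll(emg.samples[lo:hi, 0], shift)
        strategy, est = select_trimming([rec_a, rec_b])
        assert strategy == "head"

    def test_empty_strategy_list_rejected(self):
        rec, _ = simulate_blink_recording(BlinkSimParams(n_blinks=5, seed=4))
        with pytest.raises(BlinkSyncError, match="strategy"):
            select_trimming([rec], strategies=[])


class TestEstimateOffsetEndToEnd:
    def test_recovers_36ms_within_device_granularity(self):
        rec, _ = simulate_blink_recording(
            BlinkSimParams(n_blinks=20, true_offset_ms=36.0, seed=7)
        )
        est = estimate_offset(rec)
        assert abs(est.mean_offset_ms - 36.0) <= 1000.0 / 120.0

    def test_zero_offset_within_device_granularity(self):
        rec, _ = simulate_blink_recording(
            BlinkSimParams(n_blinks=20, true_offset_ms=0.0, seed=8)
        )
        est = estimate_offset(rec)
        assert abs(est.mean_offset_ms) <= 1000.0 / 120.0

    def test_no_blinks_rejected(self):
        n = 2500
        eye = TimedStream(
            "eye",
            ["both_blinking", "left_openness", "right_openness"],
            np.column_stack([np.zeros(n), np.ones(n), np.ones(n)]),
            RATE,
            np.arange(n) / RATE,
        )
        emg = TimedStream(
            "emg", ["EMG"], np.zeros((n, 1)), RATE, np.arange(n) / RATE
        )
        from vrsync.streams import Recording

        with pytest.raises(BlinkSyncError, match="no closure"):
            estimate_offset(Recording(streams=[eye, emg]))

    def test_time_shift_equivariance(self):
        rec, _ = simulate_blink_recording(
            BlinkSimParams(n_blinks=15, true_offset_ms=36.0, seed=9)
        )
        base = estimate_offset(rec).mean_offset_ms
        k = 5  # delay EMG by 5 analysis samples = 20 ms
        rec["emg"].timestamps += k / RATE
        shifted = estimate_offset(rec).mean_offset_ms
        assert shifted - base == pytest.approx(k * 1000.0 / RATE, abs=1e-9)

    @pytest.mark.parametrize("true_offset", [0.0, 12.0, 36.0, 60.0])
    def test_parameter_recovery_grid(self, true_offset):
        rec, _ = simulate_blink_recording(
            BlinkSimParams(n_blinks=100, true_offset_ms=true_offset, seed=11)
        )
        est = estimate_offset(rec)
        assert abs(est.mean_offset_ms - true_offset) <= 1000.0 / 120.0
        # quantization-jitter floor stays under the printed 9 ms bound
        assert est.std_ms <= 9.0

    @pytest.mark.parametrize("sigma", [4.0, 8.0])
    def test_injected_jitter_recovery(self, sigma):
        rec, _ = simulate_blink_recording(
            BlinkSimParams(
                n_blinks=500, true_offset_ms=36.0, jitter_sd_ms=sigma, seed=5
            )
        )
        est = estimate_offset(rec)
        assert 0.6 * sigma <= est.std_ms <= 1.5 * sigma


class TestModelResults:
    def test_fit_and_summary(self):
        rec, _ = simulate_blink_recording(BlinkSimParams(n_blinks=12, seed=21))
        res = BlinkOffsetModel(rec, BlinkSyncConfig()).fit()
        assert abs(res.mean_offset_ms - 36.0) <= 1000.0 / 120.0
        text = res.summary()
        assert "mean offset" in text and "jitter" in text
        d = res.to_dict()
        assert set(d) >= {"mean_offset_ms", "std_ms", "n_used", "n_excluded"}
        lo, hi = res.conf_int()
        assert lo < res.mean_offset_ms < hi

    def test_multi_recording_fit_selects_strategy(self):
        recs = [
            simulate_blink_recording(BlinkSimParams(n_blinks=n, seed=s))[0]
            for n, s in ((10, 31), (12, 32))
        ]
        res = BlinkOffsetModel(recs).fit()
        assert res.strategy in ("none", "head", "tail", "symmetric")
        assert abs(res.mean_offset_ms - 36.0) <= 1000.0 / 120.0
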