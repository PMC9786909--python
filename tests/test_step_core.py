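from datetime import datetime, timedelta

import numpy as np
import pytest

from stepsense import (
    DataError,
    RawRecording,
    VERISENSE_1,
    VERISENSE_2,
    StepParameters,
    count_steps,
    load_preset,
    naive_count_steps,
    vector_magnitude,
)
from stepsense.signal_io import MagnitudeSeries, resample_magnitude
from stepsense.simulator import GaitBoutSpec, simulate_bout
from stepsense.step_core import (
    PeakList,
    filter_continuity,
    filter_magnitude,
    filter_periodicity,
    filter_similarity,
    find_candidate_peaks,
)

from conftest import random_recording

START = datetime(2022, 1, 3, 12, 0, 0)


def mag_series(values, rate=15.0) -> MagnitudeSeries:
    return MagnitudeSeries(START, rate, np.asarray(values, dtype=float))


def peaks_at(indices, heights) -> PeakList:
    return PeakList(np.asarray(indices), np.asarray(heights, dtype=float))


class TestPresets:
    def test_published_threshold_sets(self):
        assert (
            VERISENSE_1.peak_win_samples,
            VERISENSE_1.min_period_samples,
            VERISENSE_1.max_period_samples,
            VERISENSE_1.similarity_threshold_g,
            VERISENSE_1.continuity_window_samples,
            VERISENSE_1.continuity_count_threshold,
            VERISENSE_1.variance_threshold_g2,
            VERISENSE_1.magnitude_threshold_g,
        ) == (3, 5, 15, -0.5, 4, 4, 0.001, 1.2)
        assert (
            VERISENSE_2.peak_win_samples,
            VERISENSE_2.min_period_samples,
            VERISENSE_2.max_period_samples,
            VERISENSE_2.similarity_threshold_g,
            VERISENSE_2.continuity_window_samples,
            VERISENSE_2.continuity_count_threshold,
            VERISENSE_2.variance_threshold_g2,
            VERISENSE_2.magnitude_threshold_g,
        ) == (4, 4, 20, -1.0, 4, 4, 0.01, 1.25)

    def test_json_presets_match_builtins(self):
        from importlib import resources

        for name, preset in (("verisense1", VERISENSE_1), ("verisense2", VERISENSE_2)):
            path = resources.files("stepsense") / "presets" / f"{name}.json"
            assert load_preset(str(path)) == preset
        assert load_preset("verisense2") is VERISENSE_2

    def test_invalid_parameters_rejected(self):
        with pytest.raises(DataError):
            StepParameters(3, 10, 5, -0.5, 4, 4, 0.001, 1.2)  # min > max
        with pytest.raises(DataError):
            StepParameters(3, 5, 15, 0.5, 4, 4, 0.001, 1.2)  # positive similarity


class TestFindCandidatePeaks:
    def test_monotone_series_has_no_candidates(self):
        assert len(find_candidate_peaks(mag_series(np.arange(50.0)), 3)) == 0

    def test_single_strict_maximum(self):
        # exhaustive-scan oracle agrees: only index 2 beats every neighbour in ±2
        peaks = find_candidate_peaks(mag_series([1, 1, 2, 1, 1]), 2)
        assert list(peaks.indices) == [2]
        assert list(peaks.heights_g) == [2.0]

    def test_plateau_ties_yield_no_candidate(self):
        peaks = find_candidate_peaks(mag_series([0, 1, 2, 2, 1, 0, 0, 0, 0]), 2)
        assert len(peaks) == 0

    def test_boundary_indices_excluded(self):
        values = [5, 1, 1, 1, 1, 1, 5]  # end maxima are within k of the edges
        assert len(find_candidate_peaks(mag_series(values), 3)) == 0

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(21)
        values = rng.normal(1.0, 0.5, 300)
        k = 4
        got = find_candidate_peaks(mag_series(values), k)
        expected = [
            i
            for i in range(k, len(values) - k)
            if all(values[i] > values[j] for j in range(i - k, i + k + 1) if j != i)
        ]
        assert list(got.indices) == expected

    def test_short_series_warns_empty(self):
        with pytest.warns(UserWarning):
            assert len(find_candidate_peaks(mag_series([1, 2, 1]), 3)) == 0


class TestFilterMagnitude:
    def test_table_thresholds(self):
        peaks = peaks_at([10, 20], [1.1, 1.3])
        kept = filter_magnitude(peaks, 1.2)
        assert list(kept.heights_g) == [1.3]

    def test_empty_input(self):
        assert len(filter_magnitude(peaks_at([], []), 1.2)) == 0

    def test_zero_threshold_is_identity(self):
        peaks = peaks_at([1, 5, 9], [0.5, 1.5, 2.5])
        assert list(filter_magnitude(peaks, 0.0).indices) == [1, 5, 9]


class TestFilterPeriodicity:
    def test_regular_gaps_all_retained(self):
        peaks = peaks_at(np.arange(0, 100, 10), np.ones(10))
        kept = filter_periodicity(peaks, 5, 15)
        assert list(kept.indices) == list(range(0, 100, 10))

    def test_gap_16_removed_v1_retained_v2(self):
        peaks = peaks_at(np.arange(0, 160, 16), np.ones(10))
        assert len(filter_periodicity(peaks, 5, 15)) == 0  # original window
        assert len(filter_periodicity(peaks, 4, 20)) == 10  # optimized window

    def test_isolated_peak_removed(self):
        assert len(filter_periodicity(peaks_at([42], [2.0]), 5, 15)) == 0

    def test_chain_restarts_after_break(self):
        # two runs separated by a large gap: both runs survive independently
        idx = np.concatenate([np.arange(0, 40, 10), np.arange(200, 240, 10)])
        kept = filter_periodicity(peaks_at(idx, np.ones(8)), 5, 15)
        assert list(kept.indices) == list(idx)


class TestFilterSimilarity:
    def test_equal_heights_always_retained(self):
        peaks = peaks_at([0, 10, 20], [1.5, 1.5, 1.5])
        for thr in (-0.01, -0.5, -1.0):
            assert len(filter_similarity(peaks, thr)) == 3

    def test_alternating_13_25_all_removed(self):
        heights = [1.3, 2.5] * 4
        peaks = peaks_at(np.arange(0, 80, 10), heights)
        assert len(filter_similarity(peaks, -0.5)) == 0
        assert len(filter_similarity(peaks, -1.0)) == 0  # |Δ|=1.2 beats both

    def test_gap_07_split_between_presets(self):
        heights = [1.3, 2.0] * 4  # |Δ| = 0.7
        peaks = peaks_at(np.arange(0, 80, 10), heights)
        assert len(filter_similarity(peaks, VERISENSE_1.similarity_threshold_g)) == 0
        assert len(filter_similarity(peaks, VERISENSE_2.similarity_threshold_g)) == 8


class TestFilterContinuity:
    def test_constant_signal_removes_all(self):
        mag = mag_series(np.ones(200))
        peaks = peaks_at([50, 100, 150], [1.0, 1.0, 1.0])
        assert len(filter_continuity(peaks, mag, 4, 4, 0.001)) == 0

    def test_lone_spike_removed(self):
        values = np.ones(200)
        values[100] = 3.0
        mag = mag_series(values)
        # hand check: only the spike's own window has variance; neighbours are flat
        kept = filter_continuity(peaks_at([100], [3.0]), mag, 4, 4, 0.001)
        assert len(kept) == 0

    def test_matches_naive_window_variance_oracle(self, gait_recording):
        rec, _ = gait_recording
        mag15 = resample_magnitude(vector_magnitude(rec), 15.0)
        peaks = find_candidate_peaks(mag15, 4)
        kept = filter_continuity(peaks, mag15, 4, 4, 0.01)

        w, m, thr = 4, 4, 0.01
        values = mag15.values_g
        n_windows = int(np.ceil(values.size / w))

        def in_motion(j):
            if not 0 <= j < n_windows:
                return False
            vals = values[j * w : min((j + 1) * w, values.size)]
            return np.mean((vals - vals.mean()) ** 2) > thr

        expected = [
            int(p)
            for p in peaks.indices
            if sum(in_motion(p // w + off) for off in range(-m, m + 1) if off != 0) >= m
        ]
        assert list(kept.indices) == expected


class TestCountSteps:
    def test_still_wear_counts_zero(self, still_recording):
        for params in (VERISENSE_1, VERISENSE_2):
            assert len(count_steps(still_recording, params)) == 0

    def test_clean_gait_within_two_steps_and_matches_oracle(self):
        rec, times = simulate_bout(GaitBoutSpec(cadence_spm=120, duration_s=10, swing_amplitude_g=0.8))
        fast = count_steps(rec, VERISENSE_2)
        slow = naive_count_steps(rec, VERISENSE_2)
        assert list(fast.times) == list(slow.times)
        assert abs(len(fast) - len(times)) <= 2

    def test_both_presets_run_on_same_trace(self, gait_recording):
        rec, _ = gait_recording
        v1 = count_steps(rec, VERISENSE_1)
        v2 = count_steps(rec, VERISENSE_2)
        assert v1.source_params == VERISENSE_1
        assert v2.source_params == VERISENSE_2
        assert len(v1) > 0 and len(v2) > 0

    def test_deterministic_across_runs(self, gait_recording):
        rec, _ = gait_recording
        a = count_steps(rec, VERISENSE_2)
        b = count_steps(rec, VERISENSE_2)
        assert list(a.times) == list(b.times)

    def test_monotone_filtering_pipeline(self, gait_recording):
        rec, _ = gait_recording
        mag15 = resample_magnitude(vector_magnitude(rec), 15.0)
        p = find_candidate_peaks(mag15, VERISENSE_2.peak_win_samples)
        stages = [len(p)]
        p = filter_magnitude(p, VERISENSE_2.magnitude_threshold_g)
        stages.append(len(p))
        p = filter_periodicity(p, VERISENSE_2.min_period_samples, VERISENSE_2.max_period_samples)
        stages.append(len(p))
        p = filter_similarity(p, VERISENSE_2.similarity_threshold_g)
        stages.append(len(p))
        p = filter_continuity(p, mag15, 4, 4, VERISENSE_2.variance_threshold_g2)
        stages.append(len(p))
        assert stages == sorted(stages, reverse=True)

    def test_times_within_recording_span(self, gait_recording):
        rec, _ = gait_recording
        events = count_steps(rec, VERISENSE_2)
        start = np.datetime64(rec.start_time)
        end = start + np.timedelta64(int(rec.duration_s * 1e9), "ns")
        assert (events.times.values >= start).all()
        assert (events.times.values <= end).all()

    def test_short_recording_warns_zero(self):
        rec = RawRecording(START, 100.0, np.tile([0.0, 0.0, 1.0], (10, 1)))
        with pytest.warns(UserWarning):
            assert len(count_steps(rec, VERISENSE_2)) == 0

    def test_chunking_stability_at_epoch_boundaries(self, gait_recording):
        rec, _ = gait_recording
        whole = len(count_steps(rec, VERISENSE_2))
        for split_s in (20.0, 30.0, 45.0):
            n = int(split_s * rec.sample_rate_hz)
            head = RawRecording(rec.start_time, rec.sample_rate_hz, rec.samples[:n])
            tail = RawRecording(
                rec.start_time + timedelta(seconds=split_s),
                rec.sample_rate_hz,
                rec.samples[n:],
            )
            parts = len(count_steps(head, VERISENSE_2)) + len(count_steps(tail, VERISENSE_2))
            assert abs(whole - parts) <= 2


class TestNaiveOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_random_signal_equivalence(self, seed):
        rec = random_recording(seed)
        for params in (VERISENSE_1, VERISENSE_2):
            fast = count_steps(rec, params)
            slow = naive_count_steps(rec, params)
            assert list(fast.times) == list(slow.times), f"seed={seed} params={params.name}"

    def test_zero_on_empty_motion(self, still_recording):
        assert len(naive_count_steps(still_recording, VERISENSE_2)) == 0
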