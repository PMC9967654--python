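import numpy as np
import pytest

from pulsepat.ecg_delineation import BeatAnnotations, T_MISSING
from pulsepat.pat_pipeline import (
    correct_low_quality,
    estimate_pat,
    event_windows,
    interpolate_pat,
    median_filter_pat,
    percentage_change,
    run_pat_pipeline,
)
from pulsepat.ppg_delineation import PulseFeatures
from pulsepat.synthgen import ArtifactSegment, SynthConfig, generate_recording


def _pulses(onsets, systolic, beat_index, fs=256.0):
    return PulseFeatures(
        onset_idx=np.asarray(onsets),
        systolic_idx=np.asarray(systolic),
        e_ppg=np.ones(len(onsets)),
        beat_index=np.asarray(beat_index),
        fs=fs,
    )


class TestEstimatePat:
    def test_worked_example(self):
        beats = BeatAnnotations(np.array([0, 300]), np.array([80, T_MISSING]), 256.0)
        pulses = _pulses([30], [64], [0])
        np.testing.assert_allclose(estimate_pat(beats, pulses), [0.25])

    def test_invalid_negative_pat_missing(self, caplog):
        beats = BeatAnnotations(np.array([100, 400]), np.array([180, T_MISSING]), 256.0)
        pulses = _pulses([110], [90], [0])
        with caplog.at_level("WARNING"):
            pat = estimate_pat(beats, pulses)
        assert np.isnan(pat[0])

    def test_mean_recovered_on_clean_synthetic(self, clean_pipeline):
        _, truth, _, series, _, _ = clean_pipeline
        assert abs(np.nanmean(series.pat_raw_s) - 0.25) < 1.0 / 256.0


class TestCorrectLowQuality:
    def test_all_high_quality_unchanged(self, rng):
        pat = rng.uniform(0.2, 0.3, 30)
        out = correct_low_quality(pat, np.ones(30, dtype=int))
        np.testing.assert_array_equal(out, pat)

    def test_mean_of_following_five(self):
        pat = np.array([0.5, 0.2, 0.22, 0.21, 0.2, 0.22])
        sqi = np.array([0, 1, 1, 1, 1, 1])
        out = correct_low_quality(pat, sqi, M=5)
        assert out[0] == pytest.approx(0.21)
        np.testing.assert_array_equal(out[1:], pat[1:])

    def test_fewer_than_m_following_uses_available(self):
        pat = np.array([0.24, 0.9, 0.20, 0.22])
        sqi = np.array([1, 0, 1, 1])
        out = correct_low_quality(pat, sqi, M=5)
        assert out[1] == pytest.approx(0.21)

    def test_carry_forward_when_nothing_follows(self):
        pat = np.array([0.24, 0.24, 0.9])
        sqi = np.array([0, 1, 0])
        out = correct_low_quality(pat, sqi, M=5)
        # last beat: no following values at all -> previous corrected value
        assert out[2] == pytest.approx(out[1]) == pytest.approx(0.24)

    def test_missing_values_skipped_in_window(self):
        pat = np.array([0.9, np.nan, 0.2, 0.22])
        sqi = np.array([0, 1, 1, 1])
        out = correct_low_quality(pat, sqi, M=2)
        assert out[0] == pytest.approx(0.21)

    def test_never_alters_high_quality_entries(self, rng):
        for _ in range(50):
            n = rng.integers(5, 40)
            pat = rng.uniform(0.15, 0.35, n)
            sqi = rng.integers(0, 2, n)
            out = correct_low_quality(pat, sqi)
            np.testing.assert_array_equal(out[sqi == 1], pat[sqi == 1])

    def test_iterative_mode_uses_corrected_values(self):
        pat = np.array([0.9, 0.8, 0.2, 0.2])
        sqi = np.array([0, 0, 1, 1])
        fwd = correct_low_quality(pat, sqi, M=2, iterative=False)
        it = correct_low_quality(pat, sqi, M=2, iterative=True)
        assert fwd[0] == pytest.approx((0.8 + 0.2) / 2)
        assert it[0] == pytest.approx((0.2 + 0.2) / 2)  # uses corrected 0.8 -> 0.2


class TestMedianFilterPat:
    def test_constant_unchanged(self):
        x = np.full(40, 0.25)
        np.testing.assert_array_equal(median_filter_pat(x, 15), x)

    def test_single_outlier_removed(self):
        x = np.full(40, 0.25)
        x[20] = 0.6
        assert median_filter_pat(x, 15)[20] == 0.25

    def test_matches_sliding_oracle(self, rng):
        x = rng.uniform(0.2, 0.3, 100)
        n = 15
        half = n // 2
        expected = np.array(
            [np.median(x[max(0, i - half) : i + half + 1]) for i in range(len(x))]
        )
        np.testing.assert_array_equal(median_filter_pat(x, n), expected)

    def test_even_order_rejected(self):
        with pytest.raises(ValueError):
            median_filter_pat(np.zeros(10), 4)


class TestInterpolation:
    def test_grid_spacing_exactly_5hz(self, rng):
        t = np.sort(rng.uniform(0, 60, 70))
        t = t[np.concatenate(([True], np.diff(t) > 1e-3))]
        v = rng.uniform(0.2, 0.3, len(t))
        grid, _ = interpolate_pat(t, v, out_rate=5.0)
        np.testing.assert_allclose(np.diff(grid), 0.2, rtol=0, atol=1e-12)
        assert grid[0] == t[0] and grid[-1] <= t[-1]

    def test_knots_reproduced(self):
        t = np.arange(0, 10, 0.2)  # knots on the grid
        v = np.sin(t)
        grid, out = interpolate_pat(t, v, out_rate=5.0)
        np.testing.assert_allclose(out, np.sin(grid), atol=1e-12)

    def test_affine_data_exact(self):
        t = np.sort(np.concatenate((np.arange(0, 20, 0.8), [3.33, 7.77])))
        v = 0.1 + 0.005 * t
        grid, out = interpolate_pat(t, v, out_rate=5.0)
        np.testing.assert_allclose(out, 0.1 + 0.005 * grid, atol=1e-12)

    def test_fewer_than_two_knots_raises(self):
        with pytest.raises(ValueError):
            interpolate_pat(np.array([1.0]), np.array([0.25]))


class TestPercentageChange:
    def test_worked_example(self):
        t = np.array([0.0, 0.2, 0.4])
        v = np.array([90.0, 95.0, 100.0])
        assert percentage_change(t, v, (0.0, 1.0)) == pytest.approx(0.10)

    def test_constant_is_zero(self):
        t = np.arange(0, 2, 0.2)
        assert percentage_change(t, np.full(len(t), 5.0), (0, 2)) == 0.0

    def test_event_window_construction(self):
        during, after = event_windows(100.0, 25.0, after_s=30.0)
        assert during == (100.0, 125.0)
        assert after == (125.0, 155.0)

    def test_empty_overlap_missing(self):
        t = np.arange(0, 2, 0.2)
        assert np.isnan(percentage_change(t, np.ones(len(t)), (10, 11)))


class TestRunPipeline:
    def test_clean_uniform_series_near_truth(self, clean_pipeline):
        _, _, _, series, _, _ = clean_pipeline
        assert len(series.uniform_t_s) == len(series.uniform_pat_s)
        np.testing.assert_allclose(np.diff(series.uniform_t_s), 0.2, atol=1e-12)
        interior = (series.uniform_t_s > series.uniform_t_s[0] + 5) & (
            series.uniform_t_s < series.uniform_t_s[-1] - 5
        )
        assert np.max(np.abs(series.uniform_pat_s[interior] - 0.25)) <= 1.5 / 256.0

    def test_uniform_series_within_knot_range_plus_overshoot(self, clean_pipeline):
        _, _, _, series, _, _ = clean_pipeline
        knots = series.pat_corr_s[~np.isnan(series.pat_corr_s)]
        span = knots.max() - knots.min()
        assert series.uniform_pat_s.min() >= knots.min() - 0.05 * span - 1e-12
        assert series.uniform_pat_s.max() <= knots.max() + 0.05 * span + 1e-12

    def test_contaminated_dispersion_reduced(self):
        seg = ArtifactSegment(120, 30, "noise_burst")
        cfg = SynthConfig(duration_s=300, seed=11, artifact_segments=[seg])
        rec, _, _ = generate_recording(cfg)
        series, _, _ = run_pat_pipeline(rec)
        m = (series.beat_time_s >= 120) & (series.beat_time_s < 150)

        def iqr(x):
            x = x[~np.isnan(x)]
            return np.subtract(*np.percentile(x, [75, 25]))

        assert iqr(series.pat_corr_s[m]) <= iqr(series.pat_raw_s[m])

    def test_programmed_dip_seen_after_event_not_during(self):
        from pulsepat.synthgen import PatProfile

        prof = PatProfile(base_s=0.25, dips=[(230, 30, 0.05)])
        cfg = SynthConfig(
            duration_s=360, seed=2, pat_profile=prof, events=[("OSA", 200.0, 30.0)]
        )
        rec, _, _ = generate_recording(cfg)
        series, _, _ = run_pat_pipeline(rec)
        during, after = event_windows(200.0, 30.0)
        pc_d = percentage_change(series.uniform_t_s, series.uniform_pat_s, during)
        pc_a = percentage_change(series.uniform_t_s, series.uniform_pat_s, after)
        assert pc_a > pc_d

    def test_exclude_mode_drops_low_quality_knots(self):
        seg = ArtifactSegment(120, 30, "dropout")
        cfg = SynthConfig(duration_s=300, seed=3, artifact_segments=[seg])
        rec, _, _ = generate_recording(cfg)
        series, pulses, _ = run_pat_pipeline(rec, elimination_mode="exclude")
        assert np.isnan(series.pat_corr_s[pulses.sqi == 0]).all() or np.all(
            pulses.sqi == 1
        )

    def test_invalid_mode_rejected(self, clean_recording):
        _, rec, _, _ = clean_recording
        with pytest.raises(ValueError):
            run_pat_pipeline(rec, elimination_mode="drop")
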