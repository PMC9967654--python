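import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pulsepat.ecg_delineation import delineate_ecg
from pulsepat.ppg_delineation import preprocess_ppg
from pulsepat.quality import (
    QualityParams,
    align_stencil_to_pulses,
    classify_sqi,
    ecg_guided_sqi,
    envelope_second_derivative,
    normalize_ppg,
    offset_abs_derivative,
    smooth_abs_derivative,
    tm_pulse_labels,
    tm_sqi,
)
from pulsepat.synthgen import ArtifactSegment, SynthConfig, generate_recording


# independent brute-force oracles
def _d2_oracle(e):
    return np.array([abs(e[i + 2] - 2 * e[i + 1] + e[i]) for i in range(len(e) - 2)])


def _median_oracle(x, order):
    half = order // 2
    return np.array(
        [np.median(x[max(0, i - half) : i + half + 1]) for i in range(len(x))]
    )


def _offset_oracle(x, k):
    n = len(x)
    lo = int(np.floor(abs(0.25 * n) + 0.5))
    hi = int(np.floor(abs(0.75 * n) + 0.5))
    return x - k * np.mean(x[lo : hi + 1])


class TestEnvelopeSecondDerivative:
    def test_affine_sequence_is_zero(self):
        np.testing.assert_array_equal(
            envelope_second_derivative([1, 2, 3, 4]), [0.0, 0.0]
        )

    def test_worked_example(self):
        np.testing.assert_array_equal(envelope_second_derivative([1, 3, 2]), [3.0])

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            e = rng.normal(size=rng.integers(3, 40))
            np.testing.assert_array_equal(
                envelope_second_derivative(e), _d2_oracle(e)
            )

    def test_short_input_empty(self):
        assert len(envelope_second_derivative([1.0, 2.0])) == 0


class TestMedianSmoothing:
    def test_constant_unchanged(self):
        x = np.full(10, 2.5)
        np.testing.assert_array_equal(smooth_abs_derivative(x, 5), x)

    def test_single_outlier_removed(self):
        np.testing.assert_array_equal(
            smooth_abs_derivative(np.array([0.0, 0, 9, 0, 0]), 5), np.zeros(5)
        )

    def test_matches_sliding_oracle(self, rng):
        for _ in range(200):
            x = rng.normal(size=rng.integers(1, 50))
            order = rng.choice([3, 5, 7])
            np.testing.assert_array_equal(
                smooth_abs_derivative(x, order), _median_oracle(x, order)
            )

    def test_even_order_rejected(self):
        with pytest.raises(ValueError):
            smooth_abs_derivative(np.zeros(5), 4)


class TestOffsetting:
    def test_constant_with_k3(self):
        np.testing.assert_allclose(
            offset_abs_derivative(np.full(20, 1.0), 3.0), np.full(20, -2.0)
        )

    def test_all_zeros(self):
        np.testing.assert_array_equal(
            offset_abs_derivative(np.zeros(10), 3.0), np.zeros(10)
        )

    def test_central_slice_indices_n100(self, rng):
        """N=100: central slice is [25, 75] inclusive, 51 values."""
        x = rng.normal(size=100)
        expected = x - 3.0 * np.mean(x[25:76])
        np.testing.assert_allclose(offset_abs_derivative(x, 3.0), expected)

    def test_matches_oracle(self, rng):
        for _ in range(200):
            x = rng.normal(size=rng.integers(4, 60))
            k = float(rng.uniform(0.5, 5))
            np.testing.assert_allclose(offset_abs_derivative(x, k), _offset_oracle(x, k))

    def test_short_input_uses_full_mean_with_warning(self):
        with pytest.warns(UserWarning):
            out = offset_abs_derivative(np.array([1.0, 2.0, 3.0]), 1.0)
        np.testing.assert_allclose(out, np.array([1, 2, 3]) - 2.0)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    e=arrays(
        np.float64,
        st.integers(4, 50),
        elements=st.floats(-1e3, 1e3, allow_nan=False),
    ),
    k=st.floats(0.0, 5.0),
)
def test_envelope_chain_properties(e, k):
    """Structural invariants of the envelope statistic for arbitrary inputs:
    non-negativity and length of the stencil, length preservation and
    range-boundedness of the median, and exactness of the offset shift."""
    d2 = envelope_second_derivative(e)
    assert len(d2) == len(e) - 2
    assert np.all(d2 >= 0)
    d2s = smooth_abs_derivative(d2, 5)
    assert len(d2s) == len(d2)
    if len(d2):
        assert d2s.min() >= d2.min() and d2s.max() <= d2.max()
    d2o = offset_abs_derivative(d2s, k)
    if len(d2s):
        shift = d2s - d2o
        np.testing.assert_allclose(shift, shift[0], rtol=0, atol=1e-9 * max(1.0, abs(shift[0])))


class TestClassify:
    """Threshold arithmetic with the default operating point θ1=0, θ2=5e-4."""

    def test_high_quality_pulse(self):
        sqi, _ = classify_sqi(np.array([-0.1]), np.array([0.001, 0.001, 0.001]))
        assert list(sqi) == [1, 1, 1]

    def test_amplitude_instability_fails_first_condition(self):
        sqi, _ = classify_sqi(np.array([0.2]), np.array([0.001, 0.001, 0.001]))
        assert list(sqi) == [0, 0, 0]

    def test_weak_envelope_fails_second_condition(self):
        sqi, _ = classify_sqi(np.array([-0.1]), np.array([0.0001, 0.0001, 0.0001]))
        assert list(sqi) == [0, 0, 0]

    def test_alignment_central_pulse_and_edge_inheritance(self):
        d2o = np.array([1.0, -1.0, 2.0])
        aligned = align_stencil_to_pulses(d2o, 5)
        np.testing.assert_array_equal(aligned, [1.0, 1.0, -1.0, 2.0, 2.0])

    def test_alignment_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            align_stencil_to_pulses(np.zeros(4), 5)


class TestQualityParams:
    def test_defaults_are_study_operating_point(self):
        p = QualityParams()
        assert (p.k, p.theta1, p.theta2, p.median_order) == (3.0, 0.0, 0.0005, 5)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            QualityParams(median_order=4)
        with pytest.raises(ValueError):
            QualityParams(theta2=0.0)


class TestEcgGuidedSqi:
    def test_clean_recording_mostly_high_quality(self, clean_pipeline):
        _, _, _, _, pulses, _ = clean_pipeline
        assert np.mean(pulses.sqi == 1) >= 0.99

    def test_amplitude_instability_flagged(self):
        seg = ArtifactSegment(100, 20, "amplitude_step")
        cfg = SynthConfig(duration_s=300, seed=4, artifact_segments=[seg])
        rec, truth, _ = generate_recording(cfg)
        beats = delineate_ecg(rec.ecg, rec.fs_ecg)
        pulses = ecg_guided_sqi(preprocess_ppg(rec.ppg, rec.fs_ppg), beats)
        mask = truth.artifact_mask[np.clip(pulses.beat_index, 0, len(truth.artifact_mask) - 1)]
        assert np.mean(pulses.sqi[mask] == 0) >= 0.90

    def test_dropout_always_flagged(self):
        seg = ArtifactSegment(100, 15, "dropout")
        cfg = SynthConfig(duration_s=300, seed=4, artifact_segments=[seg])
        rec, truth, _ = generate_recording(cfg)
        beats = delineate_ecg(rec.ecg, rec.fs_ecg)
        pulses = ecg_guided_sqi(preprocess_ppg(rec.ppg, rec.fs_ppg), beats)
        weak = pulses.e_ppg < QualityParams().theta2
        assert weak.any()
        assert np.all(pulses.sqi[weak] == 0)

    def test_k_monotonicity(self, rng):
        """Raising k only ever shrinks the offset statistic, so the count of
        pulses failing the amplitude condition cannot grow."""
        e = np.abs(rng.normal(0.03, 0.01, 60))
        d2 = envelope_second_derivative(e)
        d2s = smooth_abs_derivative(d2, 5)
        prev_fail = None
        for k in [0.5, 1, 2, 3, 5]:
            d2o = offset_abs_derivative(d2s, k)
            sqi, _ = classify_sqi(d2o, e, QualityParams(k=k, theta2=1e-12))
            fails = np.sum(sqi == 0)
            if prev_fail is not None:
                assert fails <= prev_fail
            prev_fail = fails

    def test_scale_covariance(self, rng):
        e = np.abs(rng.normal(0.03, 0.005, 40))
        c = 7.3
        d2o = offset_abs_derivative(smooth_abs_derivative(envelope_second_derivative(e), 5), 3)
        d2o_c = offset_abs_derivative(
            smooth_abs_derivative(envelope_second_derivative(c * e), 5), 3
        )
        np.testing.assert_allclose(d2o_c, c * d2o, rtol=1e-12)
        sqi, _ = classify_sqi(d2o, e)
        sqi_c, _ = classify_sqi(
            d2o_c, c * e, QualityParams(theta2=c * QualityParams().theta2)
        )
        np.testing.assert_array_equal(sqi, sqi_c)

    def test_normalize_ppg_unit_scale(self, clean_recording):
        _, rec, _, _ = clean_recording
        x = normalize_ppg(preprocess_ppg(rec.ppg, rec.fs_ppg))
        n = len(x)
        assert 0.9 < np.percentile(np.abs(x[n // 4 : 3 * n // 4]), 95) < 1.1


class TestTemplateMatching:
    def test_identical_pulses_high_quality(self):
        fs = 100.0
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * 1.0 * t) ** 21  # sharp repeated pulses
        peaks = np.argwhere(np.isclose(t % 1.0, 0.25, atol=1 / fs / 2)).ravel()
        bits, corrs = tm_sqi(x, peaks, fs)
        assert bits[:-1].min() == 1
        assert np.nanmin(corrs) > 0.99

    def test_white_noise_windows_low_quality(self, rng):
        fs = 100.0
        hits = 0
        for _ in range(100):
            x = rng.normal(size=int(10 * fs))
            peaks = np.arange(50, 950, 80)  # plausible but meaningless peaks
            bits, _ = tm_sqi(x, peaks, fs)
            hits += int(bits[0] == 0)
        assert hits >= 95

    def test_af_rhythm_flagged_more_than_ecg_guided(self):
        """Irregular rhythm trips the comparator's interval-ratio rule while
        the envelope-based index keeps the same pulses as high quality."""
        worse = 0
        n = 20
        for seed in range(n):
            cfg = SynthConfig(duration_s=240, seed=seed, rr_mode="afib_like", mean_rr_s=0.8)
            rec, _, _ = generate_recording(cfg)
            beats = delineate_ecg(rec.ecg, rec.fs_ecg)
            ppg_f = preprocess_ppg(rec.ppg, rec.fs_ppg)
            pulses = ecg_guided_sqi(ppg_f, beats)
            bits, _ = tm_sqi(ppg_f, pulses.systolic_idx, rec.fs_ppg)
            tm_lq = np.mean(tm_pulse_labels(bits, pulses.systolic_idx, rec.fs_ppg) == 0)
            ecg_lq = np.mean(pulses.sqi == 0)
            worse += int(tm_lq > ecg_lq)
        assert worse >= int(0.95 * n)

    def test_too_few_pulses_window_low_quality(self):
        bits, corrs = tm_sqi(np.zeros(3000), np.array([100]), 100.0)
        assert bits[0] == 0 and np.isnan(corrs[0])
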