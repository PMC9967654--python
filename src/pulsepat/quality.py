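"""Per-pulse PPG signal-quality assessment.

The ECG-guided index works on the pulse-amplitude envelope: the absolute
second finite difference of the per-pulse envelope is smoothed with a
5-point running median, offset by ``k`` times the mean of its central 50%,
and a pulse is high quality (SQI = 1) iff the offset statistic is below θ1
and its envelope exceeds θ2. Because it only looks at amplitude stability —
never at pulse-interval regularity — it stays valid during irregular
rhythms, unlike correlation-with-template approaches.

A template-matching (TM) comparator is provided as the reference method:
per 10-s window, pulses are extracted at the median beat-to-beat width
around each peak, correlated with their mean template, and the window is
low quality when the average correlation falls below a threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pulsepat.ecg_delineation import BeatAnnotations, round_half_away
from pulsepat.ppg_delineation import PulseFeatures, delineate_pulses

logger = logging.getLogger(__name__)


@dataclass
class QualityParams:
    """Quality-rule parameters.

    ``k`` offsets the smoothed envelope second difference so that θ1 = 0
    separates stable from unstable amplitudes; θ2 is the smallest envelope
    at which pulse morphology is still usable (both in the device's PPG
    amplitude units, so they are equipment-dependent).
    """

    k: float = 3.0
    theta1: float = 0.0
    theta2: float = 0.0005
    median_order: int = 5

    def __post_init__(self) -> None:
        if self.median_order < 3 or self.median_order % 2 == 0:
            raise ValueError("median_order must be odd and >= 3")
        if self.theta2 <= 0:
            raise ValueError("theta2 must be > 0")


def envelope_second_derivative(e_ppg: np.ndarray) -> np.ndarray:
    """|e''(i)| = |e(i+2) - 2 e(i+1) + e(i)|, length N-2."""
    e = np.asarray(e_ppg, dtype=float)
    if len(e) < 3:
        return np.array([], dtype=float)
    return np.abs(e[2:] - 2.0 * e[1:-1] + e[:-2])


def smooth_abs_derivative(d2: np.ndarray, median_order: int = 5) -> np.ndarray:
    """Centred running median of odd window ``median_order``; windows shrink
    at the edges so the output keeps the input length."""
    if median_order % 2 == 0:
        raise ValueError("median_order must be odd")
    d2 = np.asarray(d2, dtype=float)
    if len(d2) == 0:
        return d2.copy()
    return (
        pd.Series(d2)
        .rolling(median_order, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def offset_abs_derivative(d2_s: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Subtract ``k`` times the mean of the central 50% of the signal
    (indices ``round(0.25 N) .. round(0.75 N)`` inclusive): the central slice
    sidesteps the corrupted lead-in/lead-out typical of overnight PPG."""
    d2_s = np.asarray(d2_s, dtype=float)
    n = len(d2_s)
    if n == 0:
        return d2_s.copy()
    if n < 4:
        warnings.warn("fewer than 4 values: offsetting with the full-signal mean")
        center_mean = float(np.mean(d2_s))
    else:
        lo = round_half_away(0.25 * n)
        hi = round_half_away(0.75 * n)
        center_mean = float(np.mean(d2_s[lo : hi + 1]))
    return d2_s - k * center_mean


def align_stencil_to_pulses(d2_o: np.ndarray, n_pulses: int) -> np.ndarray:
    """Map the N-2 second-difference stencil values back onto N pulses: the
    stencil over pulses (j, j+1, j+2) is assigned to its central pulse j+1;
    the first and last pulse inherit their nearest assigned value."""
    d2_o = np.asarray(d2_o, dtype=float)
    if len(d2_o) != max(n_pulses - 2, 0):
        raise ValueError(
            f"stencil length {len(d2_o)} does not match {n_pulses} pulses"
        )
    if n_pulses == 0:
        return np.array([], dtype=float)
    aligned = np.empty(n_pulses, dtype=float)
    if n_pulses <= 2:
        aligned[:] = np.inf  # too few pulses to assess amplitude stability
        return aligned
    aligned[1:-1] = d2_o
    aligned[0] = aligned[1]
    aligned[-1] = aligned[-2]
    return aligned


def classify_sqi(
    d2_o: np.ndarray, e_ppg: np.ndarray, params: QualityParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """SQI(i) = 1 iff aligned |e''|o(i) < θ1 and e(i) > θ2, else 0.

    ``d2_o`` is the stencil-length offset statistic; it is aligned to pulses
    here. Returns (sqi bits, aligned_d2o).
    """
    params = params or QualityParams()
    e_ppg = np.asarray(e_ppg, dtype=float)
    aligned = align_stencil_to_pulses(d2_o, len(e_ppg))
    sqi = ((aligned < params.theta1) & (e_ppg > params.theta2)).astype(int)
    return sqi, aligned


def ecg_guided_sqi(
    ppg_filtered: np.ndarray,
    beats: BeatAnnotations,
    params: QualityParams | None = None,
) -> PulseFeatures:
    """Full ECG-guided quality assessment: delineate pulses, build the
    envelope statistic, classify each pulse."""
    params = params or QualityParams()
    pulses = delineate_pulses(ppg_filtered, beats)
    if len(pulses) == 0:
        return pulses
    d2 = envelope_second_derivative(pulses.e_ppg)
    d2_s = smooth_abs_derivative(d2, params.median_order)
    d2_o = offset_abs_derivative(d2_s, params.k)
    sqi, aligned = classify_sqi(d2_o, pulses.e_ppg, params)
    pulses.sqi = sqi
    pulses.aligned_d2o = aligned
    return pulses


def normalize_ppg(ppg_filtered: np.ndarray) -> np.ndarray:
    """Divide by the interior 95th-percentile absolute amplitude (middle 50%
    of the recording) so that θ2 can be used across devices with different
    gains."""
    x = np.asarray(ppg_filtered, dtype=float)
    n = len(x)
    interior = x[n // 4 : 3 * n // 4] if n >= 8 else x
    scale = float(np.percentile(np.abs(interior), 95))
    if scale <= 0:
        return x.copy()
    return x / scale


def tm_sqi(
    ppg_filtered: np.ndarray,
    pulse_peaks: np.ndarray,
    fs: float,
    window_s: float = 10.0,
    corr_threshold: float = 0.86,
    hr_range_bpm: tuple[float, float] = (40.0, 180.0),
    max_gap_s: float = 3.0,
    max_ibi_ratio: float = 2.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Template-matching quality per non-overlapping ``window_s`` window.

    Follows the comparator's original two-stage description: physiological
    plausibility rules first — window heart rate inside ``hr_range_bpm``, no
    inter-beat gap above ``max_gap_s``, max/min beat interval ratio at most
    ``max_ibi_ratio`` — then template matching: (i) median peak-to-peak
    interval; (ii) pulses extracted in windows of that width centred on each
    peak; (iii) mean pulse template; (iv) Pearson correlation of each pulse
    with the template; (v) window quality = 1 iff the average correlation
    reaches ``corr_threshold``. Windows failing a rule or holding fewer than
    two complete pulses are low quality. Irregular rhythms trip the interval-
    ratio rule even when every pulse is clean, which is exactly the
    behaviour the ECG-guided index is designed to avoid. Returns (per-window
    bits, average correlations; NaN where undefined).
    """
    x = np.asarray(ppg_filtered, dtype=float)
    peaks = np.asarray(pulse_peaks, dtype=int)
    win = int(round(window_s * fs))
    n_windows = int(np.ceil(len(x) / win)) if len(x) else 0
    bits = np.zeros(n_windows, dtype=int)
    corrs = np.full(n_windows, np.nan)
    for w in range(n_windows):
        lo, hi = w * win, min((w + 1) * win, len(x))
        in_win = peaks[(peaks >= lo) & (peaks < hi)]
        if len(in_win) < 2:
            continue
        ibis_s = np.diff(in_win) / fs
        window_hr = 60.0 * len(in_win) / window_s
        if not hr_range_bpm[0] <= window_hr <= hr_range_bpm[1]:
            continue
        if np.max(ibis_s) > max_gap_s:
            continue
        if np.min(ibis_s) > 0 and np.max(ibis_s) / np.min(ibis_s) > max_ibi_ratio:
            continue
        ibi = int(np.median(np.diff(in_win))) if len(in_win) > 1 else 0
        if ibi < 2:
            continue
        half = ibi // 2
        segs = []
        for p in in_win:
            a, b = p - half, p - half + ibi
            if a >= 0 and b <= len(x):
                segs.append(x[a:b])
        if len(segs) < 2:
            continue
        mat = np.vstack(segs)
        template = mat.mean(axis=0)
        t_sd = template.std()
        s_sd = mat.std(axis=1)
        if t_sd == 0:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            cc = ((mat - mat.mean(axis=1, keepdims=True)) @ (template - template.mean())) / (
                len(template) * s_sd * t_sd
            )
        cc = np.where(np.isfinite(cc), cc, 0.0)
        avg = float(np.mean(cc))
        corrs[w] = avg
        bits[w] = int(avg >= corr_threshold)
    return bits, corrs


def tm_pulse_labels(
    bits: np.ndarray, pulse_peaks: np.ndarray, fs: float, window_s: float = 10.0
) -> np.ndarray:
    """Spread per-window TM bits onto pulses: every pulse whose peak falls in
    a low-quality window is low quality (the whole window is flagged even if
    only part of it is bad)."""
    peaks = np.asarray(pulse_peaks, dtype=int)
    win = int(round(window_s * fs))
    widx = np.clip(peaks // win, 0, max(len(bits) - 1, 0))
    if len(bits) == 0:
        return np.zeros(len(peaks), dtype=int)
    return bits[widx]
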