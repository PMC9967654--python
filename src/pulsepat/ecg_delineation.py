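"""ECG pre-processing and R/T-wave delineation.

Pre-processing is a zero-phase 4th-order Butterworth low-pass at 25 Hz
followed by baseline removal: the baseline is the per-window median over 1-s
windows hopping every 0.5 s, linearly interpolated between window centres
(edges held constant) and subtracted.

T waves are found on an additionally band-passed (1-6 Hz) copy of the ECG as
the first local maximum in the search region ``[R_i + 0.06 s, R_{i+1})`` —
the 0.06 s standoff skips the QRS complex (about half its maximal normal
duration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

#: marker for beats whose T wave could not be delineated
T_MISSING = -1


@dataclass
class BeatAnnotations:
    """Per-beat R-peak and T-peak sample indices (``t_idx == T_MISSING``
    where no T wave was found; the last beat never has one because its
    search region is unbounded)."""

    r_idx: np.ndarray
    t_idx: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.r_idx = np.asarray(self.r_idx, dtype=int)
        self.t_idx = np.asarray(self.t_idx, dtype=int)
        if len(self.r_idx) != len(self.t_idx):
            raise ValueError("r_idx and t_idx must be beat-aligned")
        if len(self.r_idx) > 1 and not np.all(np.diff(self.r_idx) > 0):
            raise ValueError("r_idx must be strictly increasing")

    @property
    def t_present(self) -> np.ndarray:
        return self.t_idx != T_MISSING

    def __len__(self) -> int:
        return len(self.r_idx)


def round_half_away(x: float) -> int:
    """Round half away from zero (symmetric, unlike banker's rounding)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def _check_length(x: np.ndarray, fs: float, min_s: float = 2.0) -> None:
    if len(x) < min_s * fs:
        raise ValueError(f"signal shorter than {min_s} s at fs={fs}")


def median_baseline(x: np.ndarray, fs: float, window_s: float = 1.0, hop_s: float = 0.5) -> np.ndarray:
    """Baseline estimate: medians of overlapping windows (1 s long, 0.5 s
    hop) linearly interpolated back to the sample grid, edges held constant."""
    win = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    starts = np.arange(0, max(len(x) - win, 0) + 1, hop)
    if len(starts) == 0:
        starts = np.array([0])
        win = len(x)
    centers = starts + (win - 1) / 2.0
    meds = np.array([np.median(x[s : s + win]) for s in starts])
    return np.interp(np.arange(len(x)), centers, meds)


def preprocess_ecg(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Low-pass (25 Hz, zero-phase 4th-order Butterworth) and remove the
    median-filter baseline. Output has the input's length."""
    ecg = np.asarray(ecg, dtype=float)
    if fs <= 50:
        raise ValueError(f"fs must exceed 50 Hz for the 25 Hz low-pass, got {fs}")
    _check_length(ecg, fs)
    sos = signal.butter(4, 25.0, btype="low", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, ecg)
    return filtered - median_baseline(filtered, fs)


def smooth_for_t(ecg_filtered: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass 1-6 Hz, used only to make
    the broad T wave the dominant local structure between beats."""
    ecg_filtered = np.asarray(ecg_filtered, dtype=float)
    _check_length(ecg_filtered, fs)
    sos = signal.butter(4, [1.0, 6.0], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, ecg_filtered)


def detect_r_peaks(ecg_filtered: np.ndarray, fs: float) -> np.ndarray:
    """Default adaptive-threshold R detector (pluggable: any callable
    returning strictly increasing indices can replace it in the pipeline).

    Candidate peaks come from a 0.2-s refractory peak search; the amplitude
    threshold is 40% of the median of per-2-s block maxima, which tracks the
    recording's own R amplitude.
    """
    x = np.asarray(ecg_filtered, dtype=float)
    if len(x) == 0:
        return np.array([], dtype=int)
    block = max(1, int(round(2.0 * fs)))
    nblocks = max(1, len(x) // block)
    block_max = np.array([np.max(x[i * block : (i + 1) * block]) for i in range(nblocks)])
    scale = float(np.median(block_max))
    if scale <= 0 or not np.isfinite(scale):
        logger.warning("no beats found: non-positive amplitude scale")
        return np.array([], dtype=int)
    peaks, _ = signal.find_peaks(
        x, height=0.4 * scale, distance=max(1, int(round(0.2 * fs)))
    )
    if len(peaks) == 0:
        logger.warning("no beats found by R detector")
    return peaks.astype(int)


RDetector = Callable[[np.ndarray, float], np.ndarray]


def _first_local_max(x: np.ndarray) -> int | None:
    """Index of the first strict local maximum (plateaus resolved to their
    first sample); None if the segment is monotone."""
    if len(x) < 3:
        return None
    # plateau-aware: after a rise, the first strictly falling step ends the peak
    for i in range(1, len(x) - 1):
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < len(x) and x[j + 1] == x[j]:
                j += 1
            if j + 1 < len(x) and x[j + 1] < x[j]:
                return i
    return None


def detect_t_waves(
    ecg_smoothed: np.ndarray, r_idx: np.ndarray, fs: float
) -> np.ndarray:
    """First local maximum of the smoothed ECG in ``[R_i + 0.06 s, R_{i+1})``
    per beat; ``T_MISSING`` where the region is monotone (flat-T mode) and
    always for the final beat."""
    r_idx = np.asarray(r_idx, dtype=int)
    n = len(r_idx)
    t_idx = np.full(n, T_MISSING, dtype=int)
    if n == 0:
        return t_idx
    offset = round_half_away(0.06 * fs)
    for i in range(n - 1):
        lo = r_idx[i] + offset
        hi = r_idx[i + 1]
        if hi - lo < 3:
            continue
        m = _first_local_max(ecg_smoothed[lo:hi])
        if m is not None:
            t_idx[i] = lo + m
    return t_idx


def delineate_ecg(
    ecg: np.ndarray, fs: float, r_detector: RDetector | None = None
) -> BeatAnnotations:
    """Full ECG delineation: preprocess, detect R peaks, then T peaks."""
    filtered = preprocess_ecg(ecg, fs)
    detector = r_detector if r_detector is not None else detect_r_peaks
    r_idx = detector(filtered, fs)
    smoothed = smooth_for_t(filtered, fs)
    t_idx = detect_t_waves(smoothed, r_idx, fs)
    return BeatAnnotations(r_idx=r_idx, t_idx=t_idx, fs=fs)
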