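"""PPG pre-processing and ECG-guided pulse delineation.

Pulse onsets are the PPG minima between each ECG R peak and its T peak;
systolic peaks are the PPG maxima between consecutive onsets, and the pulse
envelope value ``e_ppg`` is that maximum. All searches use half-open
intervals ``[a, b)`` with ties resolved to the first index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from pulsepat.ecg_delineation import BeatAnnotations

logger = logging.getLogger(__name__)


@dataclass
class PulseFeatures:
    """Per-pulse delineation results; ``beat_index[i]`` is the index into the
    originating ``BeatAnnotations`` whose R peak starts pulse i. ``sqi`` is
    filled by the quality module (-1 until then)."""

    onset_idx: np.ndarray
    systolic_idx: np.ndarray
    e_ppg: np.ndarray
    beat_index: np.ndarray
    fs: float
    sqi: np.ndarray = field(default=None)  # type: ignore[assignment]
    aligned_d2o: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sqi is None:
            self.sqi = np.full(len(self.onset_idx), -1, dtype=int)
        n = len(self.onset_idx)
        if not (len(self.systolic_idx) == len(self.e_ppg) == len(self.beat_index) == n):
            raise ValueError("per-pulse arrays must share one length")
        if n > 1 and not np.all(np.diff(self.onset_idx) > 0):
            raise ValueError("onset_idx must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onset_idx)

    @property
    def onset_time_s(self) -> np.ndarray:
        return self.onset_idx / self.fs


def preprocess_ppg(ppg: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass 0.4-6 Hz; removes baseline
    wander and high-frequency noise while preserving pulse timing."""
    ppg = np.asarray(ppg, dtype=float)
    if fs <= 12:
        raise ValueError(f"fs must exceed 12 Hz for the 6 Hz band edge, got {fs}")
    if len(ppg) < 2 * fs:
        raise ValueError("signal shorter than 2 s")
    sos = signal.butter(4, [0.4, 6.0], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, ppg)


def detect_pulse_onsets(
    ppg_filtered: np.ndarray, beats: BeatAnnotations
) -> tuple[np.ndarray, np.ndarray]:
    """Onset of pulse i = argmin of the filtered PPG on ``[R_i, T_i)``.

    Beats with a missing T (or a degenerate search interval) produce no
    onset. Returns (onset_idx, beat_index).
    """
    onsets: list[int] = []
    beat_index: list[int] = []
    n_skipped = 0
    for i in range(len(beats)):
        if not beats.t_present[i]:
            n_skipped += 1
            continue
        lo, hi = int(beats.r_idx[i]), int(beats.t_idx[i])
        if hi <= lo:
            logger.warning("beat %d: T at/before R, skipped", i)
            continue
        hi = min(hi, len(ppg_filtered))
        if hi <= lo:
            continue
        onsets.append(lo + int(np.argmin(ppg_filtered[lo:hi])))
        beat_index.append(i)
    if n_skipped:
        logger.info("%d beats without T wave skipped in onset detection", n_skipped)
    if not onsets:
        logger.warning("no pulse onsets detected")
    return np.asarray(onsets, dtype=int), np.asarray(beat_index, dtype=int)


def detect_systolic_peaks(
    ppg_filtered: np.ndarray, onset_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Systolic peak of pulse i = argmax of the PPG on
    ``[onset_i, onset_{i+1})``; ``e_ppg[i]`` is that maximum (the pulse
    envelope). The final onset opens no pulse. Ties go to the first index."""
    onset_idx = np.asarray(onset_idx, dtype=int)
    if len(onset_idx) < 2:
        return np.array([], dtype=int), np.array([], dtype=float)
    systolic = np.empty(len(onset_idx) - 1, dtype=int)
    e_ppg = np.empty(len(onset_idx) - 1, dtype=float)
    for i in range(len(onset_idx) - 1):
        lo, hi = onset_idx[i], min(onset_idx[i + 1], len(ppg_filtered))
        seg = ppg_filtered[lo:hi]
        k = int(np.argmax(seg))
        systolic[i] = lo + k
        e_ppg[i] = seg[k]
    return systolic, e_ppg


def delineate_pulses(
    ppg_filtered: np.ndarray, beats: BeatAnnotations
) -> PulseFeatures:
    """Onsets then systolic peaks; pulse i links back to the beat whose R
    starts it."""
    onset_idx, beat_index = detect_pulse_onsets(ppg_filtered, beats)
    systolic_idx, e_ppg = detect_systolic_peaks(ppg_filtered, onset_idx)
    n = len(systolic_idx)
    return PulseFeatures(
        onset_idx=onset_idx[:n],
        systolic_idx=systolic_idx,
        e_ppg=e_ppg,
        beat_index=beat_index[:n],
        fs=beats.fs,
    )
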