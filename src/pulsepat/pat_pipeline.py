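"""Pulse arrival time estimation and quality-robust post-processing.

PAT(i) is the delay from the ECG R peak to the PPG systolic peak of pulse i.
Post-processing, in order: low-quality values are replaced by the mean of
the M following raw values; an n-point running median removes residual
spikes; a modified Akima (makima) interpolant resamples the beat-indexed
series onto a uniform 5 Hz grid. The systolic peak (not the onset) is used
because it shows the clearer dipping pattern during apneas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import Akima1DInterpolator

from pulsepat.ecg_delineation import BeatAnnotations, delineate_ecg
from pulsepat.io_psg import Recording
from pulsepat.ppg_delineation import PulseFeatures, preprocess_ppg
from pulsepat.quality import QualityParams, ecg_guided_sqi, normalize_ppg

logger = logging.getLogger(__name__)


@dataclass
class PatSeries:
    """Beat-indexed PAT (raw and corrected) plus the uniform 5 Hz series.

    All beat-aligned arrays are per-pulse (one entry per delineated pulse);
    NaN marks missing values.
    """

    beat_time_s: np.ndarray
    pat_raw_s: np.ndarray
    pat_corr_s: np.ndarray
    sqi: np.ndarray
    uniform_t_s: np.ndarray
    uniform_pat_s: np.ndarray

    def __len__(self) -> int:
        return len(self.beat_time_s)


def estimate_pat(
    beats: BeatAnnotations, pulses: PulseFeatures, fs: float | None = None
) -> np.ndarray:
    """Per-pulse PAT in seconds: (systolic index − R index) / fs.

    Physiologically invalid values (systolic at/before R) become NaN with a
    warning. Assumes beat and pulse indices share one sample clock; pass
    ``fs`` to override ``beats.fs``.
    """
    fs = float(fs if fs is not None else beats.fs)
    r = beats.r_idx[pulses.beat_index]
    pat = (pulses.systolic_idx - r) / fs
    bad = pat <= 0
    if bad.any():
        logger.warning("%d physiologically invalid PAT values set missing", bad.sum())
        pat = np.where(bad, np.nan, pat)
    return pat


def correct_low_quality(
    pat_raw_s: np.ndarray,
    sqi: np.ndarray,
    M: int = 5,
    iterative: bool = False,
) -> np.ndarray:
    """Replace each low-quality PAT by the mean of the M following values.

    The replacement window walks forward in beat order, skipping missing
    values; with fewer than M values left it averages what remains, and with
    none it carries the previous corrected value forward. ``iterative=True``
    averages already-corrected instead of raw following values (the default
    single forward pass is non-recursive).
    """
    pat = np.asarray(pat_raw_s, dtype=float)
    sqi = np.asarray(sqi, dtype=int)
    if len(pat) != len(sqi):
        raise ValueError("pat and sqi must be aligned")
    if len(pat) == 0 or np.all(np.isnan(pat)):
        return np.array([], dtype=float) if len(pat) == 0 else pat.copy()
    out = pat.copy()
    source = out if iterative else pat
    # iterative mode walks back-to-front so every replacement already sees
    # corrected following values; the default is a single literal pass
    order = range(len(pat) - 1, -1, -1) if iterative else range(len(pat))
    carry_forward: list[int] = []
    for i in order:
        if sqi[i] != 0:
            continue
        following = source[i + 1 :]
        following = following[~np.isnan(following)][:M]
        if len(following):
            out[i] = float(np.mean(following))
        elif i > 0:
            carry_forward.append(i)
    for i in sorted(carry_forward):
        out[i] = out[i - 1]
    return out


def median_filter_pat(pat: np.ndarray, n: int = 15) -> np.ndarray:
    """Centred n-point running median (n odd), shrunken windows at the
    edges, NaN-skipping; length preserved."""
    if n % 2 == 0:
        raise ValueError("median filter order n must be odd")
    pat = np.asarray(pat, dtype=float)
    if len(pat) == 0:
        return pat.copy()
    return pd.Series(pat).rolling(n, center=True, min_periods=1).median().to_numpy()


def interpolate_pat(
    beat_time_s: np.ndarray, pat: np.ndarray, out_rate: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Modified Akima cubic Hermite (makima) interpolation of the beat
    series onto a uniform grid at ``out_rate`` Hz, never evaluated outside
    the knot span. NaN knots are dropped first."""
    t = np.asarray(beat_time_s, dtype=float)
    v = np.asarray(pat, dtype=float)
    ok = ~np.isnan(v) & ~np.isnan(t)
    t, v = t[ok], v[ok]
    if len(t) < 2:
        raise ValueError("need at least two knots to interpolate")
    if not np.all(np.diff(t) > 0):
        raise ValueError("knot times must be strictly increasing")
    step = 1.0 / out_rate
    n = int(np.floor((t[-1] - t[0]) / step + 1e-9)) + 1
    grid = t[0] + step * np.arange(n)
    interp = Akima1DInterpolator(t, v, method="makima")
    return grid, interp(grid)


def percentage_change(
    uniform_t_s: np.ndarray,
    uniform_pat_s: np.ndarray,
    interval: tuple[float, float],
) -> float:
    """Range over maximum of the samples in ``[start, end)``; NaN when the
    overlap has fewer than two samples or a non-positive maximum."""
    t = np.asarray(uniform_t_s, dtype=float)
    v = np.asarray(uniform_pat_s, dtype=float)
    start, end = interval
    sel = (t >= start) & (t < end) & ~np.isnan(v)
    if sel.sum() < 2:
        return float("nan")
    vmax, vmin = float(np.max(v[sel])), float(np.min(v[sel]))
    if vmax <= 0:
        return float("nan")
    return (vmax - vmin) / vmax


def event_windows(
    start_s: float, duration_s: float, after_s: float = 30.0
) -> tuple[tuple[float, float], tuple[float, float]]:
    """The "during" window of an event and the window ``after_s`` seconds
    after it: ``[t0, t0+d)`` and ``[t0+d, t0+d+after_s)``."""
    end = start_s + duration_s
    return (start_s, end), (end, end + after_s)


def run_pat_pipeline(
    recording: Recording,
    quality_params: QualityParams | None = None,
    M: int = 5,
    n_median: int = 15,
    out_rate: float = 5.0,
    normalize: bool = False,
    elimination_mode: str = "correct",
    r_detector=None,
) -> tuple[PatSeries, PulseFeatures, BeatAnnotations]:
    """Full pipeline: preprocess both channels, delineate, assess quality,
    estimate PAT, correct, smooth, resample to a uniform grid.

    ``elimination_mode="correct"`` replaces low-quality PAT via the
    M-following-mean rule; ``"exclude"`` drops low-quality beats from the
    series before smoothing and interpolation instead.
    """
    if elimination_mode not in {"correct", "exclude"}:
        raise ValueError("elimination_mode must be 'correct' or 'exclude'")
    quality_params = quality_params or QualityParams()
    beats = delineate_ecg(recording.ecg, recording.fs_ecg, r_detector=r_detector)
    ppg_f = preprocess_ppg(recording.ppg, recording.fs_ppg)
    if normalize:
        ppg_f = normalize_ppg(ppg_f)
    if recording.fs_ppg != recording.fs_ecg:
        # move beat fiducials onto the PPG sample grid
        ratio = recording.fs_ppg / recording.fs_ecg
        beats = BeatAnnotations(
            r_idx=np.round(beats.r_idx * ratio).astype(int),
            t_idx=np.where(
                beats.t_present, np.round(beats.t_idx * ratio).astype(int), -1
            ),
            fs=recording.fs_ppg,
        )
    pulses = ecg_guided_sqi(ppg_f, beats, quality_params)
    n_lq = int(np.sum(pulses.sqi == 0))
    logger.info(
        "pipeline: %d beats, %d T waves, %d pulses, %d low quality (%.1f%%)",
        len(beats),
        int(beats.t_present.sum()),
        len(pulses),
        n_lq,
        100.0 * n_lq / max(len(pulses), 1),
    )
    if len(pulses) == 0:
        empty = np.array([], dtype=float)
        return (
            PatSeries(empty, empty, empty, empty.astype(int), empty, empty),
            pulses,
            beats,
        )
    pat_raw = estimate_pat(beats, pulses)
    beat_time = beats.r_idx[pulses.beat_index] / beats.fs
    if elimination_mode == "correct":
        pat_corr = correct_low_quality(pat_raw, pulses.sqi, M=M)
        pat_smooth = median_filter_pat(pat_corr, n=n_median)
    else:
        # eliminate: low-quality beats leave the series entirely; the median
        # filter runs over the surviving beats only
        keep = (pulses.sqi == 1) & ~np.isnan(pat_raw)
        pat_smooth = np.full(len(pat_raw), np.nan)
        pat_smooth[keep] = median_filter_pat(pat_raw[keep], n=n_median)
    n_knots = int(np.sum(~np.isnan(pat_smooth)))
    if n_knots >= 2:
        grid, uniform = interpolate_pat(beat_time, pat_smooth, out_rate=out_rate)
    else:
        logger.warning("fewer than two valid PAT knots; empty uniform series")
        grid = uniform = np.array([], dtype=float)
    return (
        PatSeries(
            beat_time_s=beat_time,
            pat_raw_s=pat_raw,
            pat_corr_s=pat_smooth,
            sqi=pulses.sqi,
            uniform_t_s=grid,
            uniform_pat_s=uniform,
        ),
        pulses,
        beats,
    )
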