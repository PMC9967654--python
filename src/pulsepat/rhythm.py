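"""Irregular-rhythm flagging from RR intervals.

A deliberately simple, low-complexity detector used only to stratify quality
and PAT statistics by rhythm — inspired by sliding-window atrial-fibrillation
detectors but not claimed equivalent to any published coefficient set. Per
8-beat window it (a) median-filters ectopic RR outliers, (b) suppresses
bigeminy (alternating short-long couplets), (c) counts successive RR
differences above 50 ms, and (d) fuses the irregularity count with a heart-
rate plausibility veto; per-beat labels are the majority vote over the
overlapping windows covering the beat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pulsepat.io_psg import IntervalAnnotations, Label

logger = logging.getLogger(__name__)


@dataclass
class RhythmParams:
    """Constants of the simplified detector (all config-exposed)."""

    window_len: int = 8
    ectopic_dev: float = 0.30  # relative deviation from running median
    ectopic_median_order: int = 5
    diff_threshold_s: float = 0.050
    irregularity_threshold: float = 0.7  # fraction of large successive diffs
    bigeminy_autocorr_threshold: float = 0.8  # lag-2 RR autocorrelation
    hr_tolerance: float = 0.2  # veto only windows clearly below baseline HR
    baseline_beats: int = 120


@dataclass
class RhythmLabels:
    """Per-RR-interval rhythm flags. ``analyzed`` is False for beats removed
    from analysis (e.g. the terminal wake segment)."""

    irregular: np.ndarray
    analyzed: np.ndarray
    beat_time_s: np.ndarray | None = None
    window_len: int = 8

    def __post_init__(self) -> None:
        self.irregular = np.asarray(self.irregular, dtype=bool)
        self.analyzed = np.asarray(self.analyzed, dtype=bool)
        if len(self.irregular) != len(self.analyzed):
            raise ValueError("irregular and analyzed must be aligned")

    def __len__(self) -> int:
        return len(self.irregular)

    @property
    def flagged_fraction(self) -> float:
        if not self.analyzed.any():
            return float("nan")
        return float(self.irregular[self.analyzed].mean())


def filter_ectopic(rr_s: np.ndarray, params: RhythmParams | None = None) -> np.ndarray:
    """Replace isolated RR outliers (deviation > ``ectopic_dev`` from a
    centred running median of ``ectopic_median_order``) by that median.

    Only the ectopic signature is replaced: a premature (short) interval
    immediately followed by a compensatory (long) one. Sustained
    irregularity — atrial fibrillation deviates beat after beat without the
    short-then-long couplet — must survive this stage so the irregularity
    count can see it."""
    params = params or RhythmParams()
    rr = np.asarray(rr_s, dtype=float)
    med = (
        pd.Series(rr)
        .rolling(params.ectopic_median_order, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    safe_med = np.where(med > 0, med, np.inf)
    short = rr < (1.0 - params.ectopic_dev) * safe_med
    long_next = np.concatenate(
        (rr[1:] > (1.0 + 0.5 * params.ectopic_dev) * safe_med[1:], [False])
    )
    ectopic = short & long_next
    out = rr.copy()
    out[ectopic] = med[ectopic]
    out[np.concatenate(([False], ectopic[:-1]))] = med[
        np.concatenate(([False], ectopic[:-1]))
    ]
    return out


def _window_is_bigeminy(rr_win: np.ndarray, params: RhythmParams) -> bool:
    d = np.diff(rr_win)
    if np.any(d == 0) or not np.all(d[:-1] * d[1:] < 0):
        return False  # successive differences must strictly alternate in sign
    a, b = rr_win[:-2], rr_win[2:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return False
    r2 = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return r2 > params.bigeminy_autocorr_threshold


def detect_irregular_rhythm(
    rr_s: np.ndarray,
    params: RhythmParams | None = None,
    beat_time_s: np.ndarray | None = None,
) -> RhythmLabels:
    """Label each RR interval regular/irregular with the windowed detector.

    With fewer than ``window_len`` intervals everything is regular (with a
    warning). The heart-rate fusion term vetoes a window only when its mean
    rate falls below ``(1 - hr_tolerance)`` times the running baseline rate,
    so irregular rhythms at an unchanged mean rate remain detectable.
    """
    params = params or RhythmParams()
    rr = np.asarray(rr_s, dtype=float)
    n = len(rr)
    analyzed = np.ones(n, dtype=bool)
    if n < params.window_len:
        logger.warning("fewer than %d RR intervals: all regular", params.window_len)
        return RhythmLabels(
            np.zeros(n, dtype=bool), analyzed, beat_time_s, params.window_len
        )
    rr_f = filter_ectopic(rr, params)
    hr = 60.0 / rr_f
    baseline_hr = (
        pd.Series(hr)
        .rolling(params.baseline_beats, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    w = params.window_len
    votes_irr = np.zeros(n)
    votes_tot = np.zeros(n)
    for i in range(n - w + 1):
        win = rr_f[i : i + w]
        d = np.abs(np.diff(win))
        frac = float(np.mean(d > params.diff_threshold_s))
        win_hr = float(np.mean(hr[i : i + w]))
        base = float(np.mean(baseline_hr[i : i + w]))
        irregular = frac >= params.irregularity_threshold and win_hr >= (
            1.0 - params.hr_tolerance
        ) * base
        if irregular and _window_is_bigeminy(win, params):
            irregular = False
        votes_irr[i : i + w] += irregular
        votes_tot[i : i + w] += 1
    flags = votes_irr * 2 > votes_tot  # strict majority over covering windows
    return RhythmLabels(flags, analyzed, beat_time_s, w)


def exclude_terminal_wake(
    labels: RhythmLabels, stages: IntervalAnnotations
) -> RhythmLabels:
    """Mark beats inside the final annotated wake stage as not analyzed
    (subjects are fully awake there); earlier wake segments are kept."""
    if labels.beat_time_s is None:
        raise ValueError("labels need beat_time_s to apply stage exclusions")
    stage_ivs = stages.stages()
    if not stage_ivs or stage_ivs[-1].label != Label.WAKE:
        return labels
    final_wake = stage_ivs[-1]
    t = np.asarray(labels.beat_time_s, dtype=float)
    analyzed = labels.analyzed & ~np.asarray(final_wake.contains(t))
    return RhythmLabels(
        labels.irregular.copy(), analyzed, labels.beat_time_s, labels.window_len
    )
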