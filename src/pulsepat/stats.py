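"""Stratified summaries and paired nonparametric statistics.

Per subject and category (sleep stage, respiratory event, rhythm, quality),
the summaries are the proportion of high-quality pulses and the IQR of PAT
before and after post-processing. Paired comparisons across subjects use the
Wilcoxon signed-rank test with the matched-pairs rank-biserial correlation
as effect size (small < 0.30 ≤ medium < 0.50 ≤ large).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from pulsepat.io_psg import IntervalAnnotations
from pulsepat.pat_pipeline import PatSeries
from pulsepat.ppg_delineation import PulseFeatures
from pulsepat.rhythm import RhythmLabels

logger = logging.getLogger(__name__)


def _iqr(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    if len(x) == 0:
        return float("nan")
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 - q1)


def aggregate_by_category(
    pulses: PulseFeatures,
    pat: PatSeries,
    annotations: IntervalAnnotations | None = None,
    rhythm: RhythmLabels | None = None,
    subject_id: str = "",
) -> pd.DataFrame:
    """Per-category summary rows: n_pulses, proportion of SQI=1, and PAT IQR
    raw (PATb) and post-processed (PATa).

    A pulse belongs to an annotation category iff its onset time falls in
    one of the category's half-open intervals; rhythm categories use the
    per-beat rhythm flags, and quality categories split on the pulse's own
    SQI bit.
    """
    onset_s = pulses.onset_time_s
    members: dict[str, np.ndarray] = {}
    if annotations is not None:
        for label in {iv.label for iv in annotations}:
            sel = np.zeros(len(pulses), dtype=bool)
            for iv in annotations.by_label(label):
                sel |= np.asarray(iv.contains(onset_s))
            members[label.value] = sel
    if rhythm is not None and len(rhythm):
        flags = rhythm.irregular
        analyzed = rhythm.analyzed
        bi = np.clip(pulses.beat_index, 0, len(flags) - 1)
        ok = analyzed[bi]
        members["REGULAR"] = ok & ~flags[bi]
        members["IRREGULAR"] = ok & flags[bi]
    members["HIGH_QUALITY"] = pulses.sqi == 1
    members["LOW_QUALITY"] = pulses.sqi == 0

    rows = []
    for cat in sorted(members):
        sel = members[cat]
        n = int(sel.sum())
        if n == 0:
            rows.append(
                dict(
                    subject_id=subject_id,
                    category=cat,
                    n_pulses=0,
                    proportion_hq=float("nan"),
                    pat_iqr_raw_s=float("nan"),
                    pat_iqr_corr_s=float("nan"),
                )
            )
            continue
        rows.append(
            dict(
                subject_id=subject_id,
                category=cat,
                n_pulses=n,
                proportion_hq=float(np.mean(pulses.sqi[sel] == 1)),
                pat_iqr_raw_s=_iqr(pat.pat_raw_s[sel]),
                pat_iqr_corr_s=_iqr(pat.pat_corr_s[sel]),
            )
        )
    return pd.DataFrame(rows)


def wilcoxon_paired(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test; zero differences dropped.

    Exact null distribution for n ≤ 25 nonzero pairs, otherwise the normal
    approximation with continuity correction. Returns (statistic, p); both
    NaN when every difference is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[~np.isnan(d)]
    n_nonzero = int(np.sum(d != 0))
    if n_nonzero == 0:
        warnings.warn("all paired differences are zero; p undefined")
        return float("nan"), float("nan")
    method = "exact" if n_nonzero <= 25 else "approx"
    res = sps.wilcoxon(
        d, zero_method="wilcox", alternative="two-sided", method=method,
        correction=(method == "approx"),
    )
    return float(res.statistic), float(res.pvalue)


def matched_pairs_rc(x: np.ndarray, y: np.ndarray) -> float:
    """Matched-pairs rank-biserial correlation |W+ − W−| / (W+ + W−) over
    the signed ranks of the nonzero differences; NaN when none differ."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[~np.isnan(d) & (d != 0)]
    if len(d) == 0:
        return float("nan")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return abs(w_plus - w_minus) / (w_plus + w_minus)


def effect_size_label(rc: float) -> str:
    """small (< 0.30), medium (≥ 0.30), large (≥ 0.50)."""
    if not 0 <= rc <= 1:
        raise ValueError(f"rc must lie in [0, 1], got {rc}")
    if rc >= 0.50:
        return "large"
    if rc >= 0.30:
        return "medium"
    return "small"


def compare_categories(
    summaries: pd.DataFrame, value: str = "proportion_hq"
) -> pd.DataFrame:
    """Pairwise Wilcoxon + rank-biserial comparison of per-subject medians
    between every pair of categories present in a long-format summary table."""
    cats = sorted(summaries["category"].unique())
    wide = summaries.pivot_table(
        index="subject_id", columns="category", values=value, aggfunc="median"
    )
    rows = []
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            if a not in wide or b not in wide:
                continue
            sub = wide[[a, b]].dropna()
            if len(sub) < 2:
                continue
            stat, p = wilcoxon_paired(sub[a].to_numpy(), sub[b].to_numpy())
            rc = matched_pairs_rc(sub[a].to_numpy(), sub[b].to_numpy())
            rows.append(
                dict(
                    category_a=a,
                    category_b=b,
                    n_subjects=len(sub),
                    statistic=stat,
                    p_value=p,
                    rc=rc,
                    effect_size=effect_size_label(rc) if np.isfinite(rc) else "",
                )
            )
    return pd.DataFrame(rows)


def normality_diagnostic(x: np.ndarray) -> tuple[float, float]:
    """Anderson-Darling normality statistic and its 5% critical value
    (diagnostic only; gates nothing downstream)."""
    res = sps.anderson(np.asarray(x, dtype=float), dist="norm")
    crit_5 = float(res.critical_values[list(res.significance_level).index(5.0)])
    return float(res.statistic), crit_5
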