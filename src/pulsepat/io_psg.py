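"""Reading PSG signals and annotations; writing tabular results.

Conventions: time is in seconds from recording start, sample indices are
0-based, and all intervals are half-open ``[start, start + duration)``.
Channels keep their native sampling rates; a beat index always refers to the
sample grid of its own channel.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)


class Label(str, Enum):
    """Sleep stages and sleep-disordered-breathing events."""

    WAKE = "WAKE"
    NREM1 = "NREM1"
    NREM2 = "NREM2"
    NREM3 = "NREM3"
    REM = "REM"
    OSA = "OSA"
    HYPOPNEA = "HYPOPNEA"
    OXY_DESAT = "OXY_DESAT"
    AROUSAL = "AROUSAL"


STAGE_LABELS = frozenset(
    {Label.WAKE, Label.NREM1, Label.NREM2, Label.NREM3, Label.REM}
)
EVENT_LABELS = frozenset(
    {Label.OSA, Label.HYPOPNEA, Label.OXY_DESAT, Label.AROUSAL}
)


@dataclass(frozen=True)
class Interval:
    label: Label
    start_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"interval duration must be > 0, got {self.duration_s}")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def contains(self, t: float | np.ndarray) -> bool | np.ndarray:
        return (t >= self.start_s) & (t < self.end_s)


@dataclass
class IntervalAnnotations:
    """Stage and event intervals.

    Stage intervals must not overlap each other; events may overlap stages
    and one another.
    """

    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        stages = sorted(
            (iv for iv in self.intervals if iv.label in STAGE_LABELS),
            key=lambda iv: iv.start_s,
        )
        for a, b in zip(stages, stages[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValueError(
                    f"overlapping stage intervals: {a.label.value}@{a.start_s} "
                    f"and {b.label.value}@{b.start_s}"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def by_label(self, label: Label) -> list[Interval]:
        return [iv for iv in self.intervals if iv.label == label]

    def stages(self) -> list[Interval]:
        return sorted(
            (iv for iv in self.intervals if iv.label in STAGE_LABELS),
            key=lambda iv: iv.start_s,
        )

    def events(self) -> list[Interval]:
        return sorted(
            (iv for iv in self.intervals if iv.label in EVENT_LABELS),
            key=lambda iv: iv.start_s,
        )


@dataclass
class Recording:
    """Synchronized ECG/PPG(/SpO2) channels of one PSG recording.

    Channels are stored at their native rates; ``fs_ecg`` etc. are the
    per-channel sampling frequencies in Hz. Amplitudes are in whatever units
    the source file declares (arbitrary for the pipeline).
    """

    ecg: np.ndarray
    ppg: np.ndarray
    fs_ecg: float
    fs_ppg: float
    spo2: np.ndarray | None = None
    fs_spo2: float | None = None
    t0: float = 0.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        if self.fs_ecg <= 0 or self.fs_ppg <= 0:
            raise ValueError("sampling frequencies must be > 0")
        for name, x in (("ecg", self.ecg), ("ppg", self.ppg)):
            if np.isnan(x).any():
                raise ValueError(f"{name} channel contains NaN after ingestion")
        if self.spo2 is not None:
            self.spo2 = np.asarray(self.spo2, dtype=float)
            if self.fs_spo2 is None or self.fs_spo2 <= 0:
                raise ValueError("spo2 present but fs_spo2 missing or <= 0")
        d_ecg = len(self.ecg) / self.fs_ecg
        d_ppg = len(self.ppg) / self.fs_ppg
        tol = max(1.0 / self.fs_ecg, 1.0 / self.fs_ppg)
        if abs(d_ecg - d_ppg) > tol + 1e-9:
            raise ValueError(
                f"channel durations inconsistent: ecg {d_ecg:.3f}s vs ppg {d_ppg:.3f}s"
            )

    @property
    def duration_s(self) -> float:
        return len(self.ecg) / self.fs_ecg


class ChannelNotFoundError(KeyError):
    """A requested channel label is not present in the file."""


def _read_edf_channel(path: Path, label: str) -> tuple[np.ndarray, float]:
    # one channel per call so mne never resamples across heterogeneous rates
    import mne

    try:
        raw = mne.io.read_raw_edf(
            str(path), include=[label], preload=True, verbose="ERROR"
        )
    except Exception as exc:  # mne raises plain ValueError on bad files
        raise IOError(f"could not read EDF file {path}: {exc}") from exc
    if label not in raw.ch_names:
        raise ChannelNotFoundError(f"channel {label!r} not found in {path}")
    data = raw.get_data(picks=[label])[0]
    return np.asarray(data, dtype=float), float(raw.info["sfreq"])


def read_recording(
    path: str | Path,
    ecg_label: str,
    ppg_label: str,
    spo2_label: str | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read the named ECG/PPG(/SpO2) channels from an EDF/EDF+ file.

    Each channel is extracted at its native sampling rate with amplitudes
    unchanged (as decoded from the file's physical calibration).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    ecg, fs_ecg = _read_edf_channel(path, ecg_label)
    ppg, fs_ppg = _read_edf_channel(path, ppg_label)
    spo2 = fs_spo2 = None
    if spo2_label is not None:
        spo2, fs_spo2 = _read_edf_channel(path, spo2_label)
    return Recording(
        ecg=ecg,
        ppg=ppg,
        fs_ecg=fs_ecg,
        fs_ppg=fs_ppg,
        spo2=spo2,
        fs_spo2=fs_spo2,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def _fmt_edf_float(x: float) -> str:
    s = f"{x:.8g}"
    if len(s) > 8:
        s = f"{x:.2e}"
    return s[:8]


def write_recording(
    path: str | Path,
    signals: Sequence[np.ndarray],
    labels: Sequence[str],
    fs_list: Sequence[float],
    dimensions: Sequence[str] | None = None,
) -> None:
    """Write channels to a minimal EDF file (16-bit, 1-s data records).

    Intended for test fixtures and synthetic recordings only; sampling rates
    must be positive integers. Physical min/max are taken from each channel's
    data, so the quantization step is ``(max - min) / 65535``.
    """
    path = Path(path)
    nsig = len(signals)
    if not (len(labels) == len(fs_list) == nsig):
        raise ValueError("signals, labels and fs_list must have equal lengths")
    if dimensions is None:
        dimensions = [""] * nsig
    fs_int = []
    for f in fs_list:
        if f <= 0 or abs(f - round(f)) > 1e-9:
            raise ValueError(f"EDF writer requires integer sampling rates, got {f}")
        fs_int.append(int(round(f)))
    n_records = max(
        int(math.ceil(len(s) / f)) for s, f in zip(signals, fs_int)
    )

    def pad(s: str, n: int) -> bytes:
        return s.encode("ascii")[:n].ljust(n)

    # physical min/max are stored as 8-char ASCII; pad the range and use the
    # parsed header values for digitization so writer and reader agree exactly
    pmins, pmaxs = [], []
    for s in signals:
        s = np.asarray(s, dtype=float)
        pmin, pmax = float(np.min(s)), float(np.max(s))
        if pmax <= pmin:
            pmax = pmin + 1.0
        pad_frac = 2e-3
        while True:
            rng = pmax - pmin
            pmin_h = float(_fmt_edf_float(pmin - pad_frac * rng))
            pmax_h = float(_fmt_edf_float(pmax + pad_frac * rng))
            if pmin_h <= pmin and pmax_h >= pmax:
                break
            pad_frac *= 2
        pmins.append(pmin_h)
        pmaxs.append(pmax_h)

    hdr = b""
    hdr += pad("0", 8)
    hdr += pad("X X X X", 80)
    hdr += pad("Startdate 01-JAN-2000 X X X", 80)
    hdr += pad("01.01.00", 8) + pad("00.00.00", 8)
    hdr += pad(str(256 * (nsig + 1)), 8)
    hdr += pad("", 44)
    hdr += pad(str(n_records), 8)
    hdr += pad("1", 8)
    hdr += pad(str(nsig), 4)
    for lab in labels:
        hdr += pad(lab, 16)
    for _ in range(nsig):
        hdr += pad("", 80)  # transducer
    for dim in dimensions:
        hdr += pad(dim, 8)
    for v in pmins:
        hdr += pad(_fmt_edf_float(v), 8)
    for v in pmaxs:
        hdr += pad(_fmt_edf_float(v), 8)
    for _ in range(nsig):
        hdr += pad("-32768", 8)
    for _ in range(nsig):
        hdr += pad("32767", 8)
    for _ in range(nsig):
        hdr += pad("", 80)  # prefiltering
    for f in fs_int:
        hdr += pad(str(f), 8)
    for _ in range(nsig):
        hdr += pad("", 32)

    digital = []
    for s, pmin, pmax in zip(signals, pmins, pmaxs):
        gain = (pmax - pmin) / (32767 - (-32768))
        d = np.round((np.asarray(s, dtype=float) - pmin) / gain) - 32768
        digital.append(np.clip(d, -32768, 32767).astype("<i2"))

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            for d, f in zip(digital, fs_int):
                chunk = d[r * f : (r + 1) * f]
                if len(chunk) < f:
                    chunk = np.pad(chunk, (0, f - len(chunk)))
                fh.write(chunk.tobytes())


# -- annotations --------------------------------------------------------------

# profusion-style stage codes: 0 wake, 1-3 NREM1-3, 4 also NREM3 (old R&K), 5 REM
_STAGE_CODE = {
    "0": Label.WAKE,
    "1": Label.NREM1,
    "2": Label.NREM2,
    "3": Label.NREM3,
    "4": Label.NREM3,
    "5": Label.REM,
}

_NAME_PATTERNS: list[tuple[str, Label]] = [
    ("obstructive apnea", Label.OSA),
    ("obstructive sleep apnea", Label.OSA),
    ("osa", Label.OSA),
    ("hypopnea", Label.HYPOPNEA),
    ("desat", Label.OXY_DESAT),
    ("oxy_desat", Label.OXY_DESAT),
    ("spo2 artifact", Label.OXY_DESAT),
    ("arousal", Label.AROUSAL),
    ("wake", Label.WAKE),
    ("stage 1", Label.NREM1),
    ("stage 2", Label.NREM2),
    ("stage 3", Label.NREM3),
    ("stage 4", Label.NREM3),
    ("nrem1", Label.NREM1),
    ("nrem2", Label.NREM2),
    ("nrem3", Label.NREM3),
    ("rem", Label.REM),
]


def _map_label(name: str) -> Label | None:
    lowered = name.strip().lower()
    try:
        return Label(name.strip().upper())
    except ValueError:
        pass
    for pat, lab in _NAME_PATTERNS:
        if pat in lowered:
            return lab
    return None


def _read_annotations_csv(path: Path) -> IntervalAnnotations:
    intervals: list[Interval] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            if row[0].strip().lower() in {"label", "name"}:
                continue  # header
            if len(row) < 3:
                raise ValueError(f"malformed annotation row in {path}: {row!r}")
            lab = _map_label(row[0])
            if lab is None:
                logger.warning("skipping unknown annotation label %r", row[0])
                continue
            try:
                start, dur = float(row[1]), float(row[2])
            except ValueError as exc:
                raise ValueError(
                    f"malformed annotation row in {path}: {row!r}"
                ) from exc
            intervals.append(Interval(lab, start, dur))
    return IntervalAnnotations(intervals)


def _read_annotations_nsrr_xml(path: Path) -> IntervalAnnotations:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed NSRR XML file {path}: {exc}") from exc
    root = tree.getroot()
    intervals: list[Interval] = []
    for ev in root.iter("ScoredEvent"):
        name_el = ev.find("Name")
        if name_el is None:
            name_el = ev.find("EventConcept")
        start_el, dur_el = ev.find("Start"), ev.find("Duration")
        if name_el is None or start_el is None or dur_el is None:
            logger.warning("skipping incomplete ScoredEvent in %s", path)
            continue
        lab = _map_label(name_el.text or "")
        if lab is None:
            logger.warning("skipping unknown event name %r", name_el.text)
            continue
        intervals.append(Interval(lab, float(start_el.text), float(dur_el.text)))
    # profusion hypnogram: one <SleepStage> code per 30-s epoch
    stage_codes = [el.text for el in root.iter("SleepStage")]
    if stage_codes:
        epoch_s = 30.0
        t = 0.0
        run_start, run_code = 0.0, stage_codes[0]
        for code in stage_codes[1:] + [None]:
            t += epoch_s
            if code != run_code:
                lab = _STAGE_CODE.get((run_code or "").strip())
                if lab is None:
                    logger.warning("skipping unknown stage code %r", run_code)
                else:
                    intervals.append(Interval(lab, run_start, t - run_start))
                run_start, run_code = t, code
    return IntervalAnnotations(intervals)


def read_annotations(path: str | Path, dialect: str = "csv") -> IntervalAnnotations:
    """Read stage/event annotations.

    ``dialect="csv"`` expects rows of ``label,start_s,duration_s``;
    ``dialect="nsrr_xml"`` parses profusion-style ScoredEvent/SleepStage XML.
    Unknown labels are skipped with a logged warning.
    """
    path = Path(path)
    if dialect == "csv":
        return _read_annotations_csv(path)
    if dialect == "nsrr_xml":
        return _read_annotations_nsrr_xml(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_results(table: pd.DataFrame | Iterable[dict], path: str | Path) -> None:
    """Write per-pulse or per-category records as CSV with a deterministic
    row order (by time column if present, then label) and full float
    precision."""
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(list(table))
    sort_cols = [
        c
        for c in ("time_s", "onset_s", "t", "start_s", "beat_time_s", "label", "category")
        if c in df.columns
    ]
    if sort_cols and len(df):
        df = df.sort_values(sort_cols, kind="mergesort")
    df.to_csv(path, index=False, float_format="%.17g")
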