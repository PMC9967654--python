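"""Synthetic ECG+PPG generator with exact ground truth.

Waveforms are analytic templates (sums of Gaussians for the ECG, asymmetric
raised-cosine pulses with a small dicrotic wave for the PPG), not
physiological simulators: every fiducial point — R peak, T peak, pulse onset
(foot), systolic peak — is placed by construction, so detector recovery error
is measurable in samples. The programmed pulse onset is the global minimum of
the pulse within ``[R_i, T_i]``, matching the detector's definition.

Default amplitude scaling puts the clean pulse envelope around 0.01-0.1
units, comfortably above the dropout threshold θ2 = 5e-4; the dropout
artifact scales pulses to ~1e-4 so both branches of the quality rule are
exercised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

from pulsepat.io_psg import Interval, IntervalAnnotations, Label, Recording

logger = logging.getLogger(__name__)

ArtifactKind = Literal["amplitude_step", "noise_burst", "dropout"]


@dataclass(frozen=True)
class ArtifactSegment:
    start_s: float
    duration_s: float
    kind: ArtifactKind

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class PatProfile:
    """Programmed PAT as a function of time: a constant base with optional
    smooth apnea-style dips (raised-cosine, ``rel_depth`` fractional depth at
    the dip centre)."""

    base_s: float = 0.25
    dips: list[tuple[float, float, float]] = field(default_factory=list)

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        pat = np.full(t.shape, self.base_s)
        for start, dur, depth in self.dips:
            u = (t - start) / dur
            inside = (u >= 0) & (u < 1)
            pat = np.where(
                inside, self.base_s * (1.0 - depth * np.sin(np.pi * u) ** 2), pat
            )
        return pat


@dataclass
class SynthConfig:
    """Study conditions for one synthetic recording."""

    fs: float = 256.0
    duration_s: float = 120.0
    rr_mode: Literal["regular", "afib_like", "bigeminy"] = "regular"
    mean_rr_s: float = 1.0
    rr_cv: float | None = None  # None -> per-mode default
    pat_profile: Callable[[np.ndarray], np.ndarray] | PatProfile = field(
        default_factory=PatProfile
    )
    artifact_segments: list[ArtifactSegment] = field(default_factory=list)
    events: list[tuple[str, float, float]] = field(default_factory=list)
    stages: list[tuple[str, float, float]] | None = None
    seed: int = 0

    # waveform geometry (amplitudes arbitrary units, times seconds)
    ppg_amplitude: float = 0.05
    resp_mod_depth: float = 0.01  # respiratory amplitude modulation of the PPG
    resp_rate_hz: float = 0.25  # ~15 breaths/min, typical of sleep
    onset_delay_s: float = 0.13  # R-to-foot delay, must stay below programmed PAT
    amplitude_step_factor: float = 2.5
    noise_burst_sigma_rel: float = 2.0  # noise sd relative to pulse amplitude
    dropout_scale: float = 0.002  # pushes the envelope to ~1e-4, below θ2

    def __post_init__(self) -> None:
        if not 0.3 <= self.mean_rr_s <= 2.0:
            raise ValueError(f"mean_rr_s must be in [0.3, 2.0], got {self.mean_rr_s}")
        if self.rr_cv is not None and self.rr_cv < 0:
            raise ValueError("rr_cv must be >= 0")
        for seg in self.artifact_segments:
            if seg.start_s < 0 or seg.end_s > self.duration_s:
                raise ValueError(f"artifact segment {seg} outside recording")

    @property
    def cv(self) -> float:
        if self.rr_cv is not None:
            return self.rr_cv
        return {"regular": 0.01, "afib_like": 0.20, "bigeminy": 0.01}[self.rr_mode]


@dataclass
class SyntheticTruth:
    """Ground-truth fiducials and labels, beat-aligned.

    ``r_idx``, ``t_idx``, ``onset_idx``, ``systolic_idx``, ``pat_true_s`` and
    ``rhythm_label`` have one entry per beat; ``artifact_mask`` has one entry
    per pulse (interval between consecutive onsets), i.e. ``n_beats - 1``.
    """

    r_idx: np.ndarray
    t_idx: np.ndarray
    onset_idx: np.ndarray
    systolic_idx: np.ndarray
    pat_true_s: np.ndarray
    artifact_mask: np.ndarray
    rhythm_label: np.ndarray
    fs: float

    def validate(self) -> None:
        r, t, o = self.r_idx, self.t_idx, self.onset_idx
        if not np.all(np.diff(r) > 0):
            raise AssertionError("r_idx not strictly increasing")
        if not (np.all(t[:-1] > r[:-1]) and np.all(t[:-1] < r[1:])):
            raise AssertionError("t_idx outside (r_i, r_{i+1})")
        if not (np.all(o >= r) and np.all(o <= t)):
            raise AssertionError("onset_idx outside [r_i, t_i]")
        if len(self.artifact_mask) != len(r) - 1:
            raise AssertionError("artifact_mask must have one entry per pulse")


def generate_rr(config: SynthConfig) -> np.ndarray:
    """Draw a per-beat RR sequence (seconds) for the configured rhythm mode.

    ``regular``: tight Gaussian jitter around the mean; ``afib_like``:
    independent gamma draws at the configured coefficient of variation;
    ``bigeminy``: alternating short/long couplets (±30% of the mean).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = int(np.ceil(config.duration_s / config.mean_rr_s * 1.5)) + 10
    cv = config.cv
    if config.rr_mode == "regular":
        rr = config.mean_rr_s * (1.0 + cv * rng.standard_normal(n))
    elif config.rr_mode == "afib_like":
        if cv <= 0:
            raise ValueError("afib_like mode requires rr_cv > 0")
        shape = 1.0 / cv**2
        rr = rng.gamma(shape, config.mean_rr_s / shape, size=n)
    elif config.rr_mode == "bigeminy":
        base = np.where(np.arange(n) % 2 == 0, 0.7, 1.3) * config.mean_rr_s
        rr = base * (1.0 + cv * rng.standard_normal(n))
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown rr_mode {config.rr_mode!r}")
    return np.clip(rr, 0.3, 2.0)


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def generate_ecg(
    rr: np.ndarray, fs: float, lead_in_s: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render an ECG from RR intervals as Gaussian-bump beats.

    Each beat has a dominant positive R wave (amplitude 1, sigma 12 ms)
    flanked by small Q/S deflections, and a lower broad T wave (amplitude
    0.3, sigma 50 ms) whose peak is programmed at ``R_i + min(0.30 s,
    0.75·RR_i)`` — inside the physiologic (R+0.10 s, R+0.40 s) band and
    before the next R. Returns (samples, programmed R indices, programmed
    T indices).
    """
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("rr intervals must be positive")
    t_off = np.minimum(0.30, 0.75 * rr)
    if np.any(t_off <= 0.10):
        raise ValueError("rr too short to place a T wave after R + 0.10 s")
    r_times = lead_in_s + np.concatenate(([0.0], np.cumsum(rr[:-1])))
    t_times = r_times + t_off
    duration = r_times[-1] + rr[-1]
    n = int(round(duration * fs))
    ecg = np.zeros(n)

    def add_bump(mu: float, sigma: float, amp: float) -> None:
        lo = max(0, int((mu - 6 * sigma) * fs))
        hi = min(n, int((mu + 6 * sigma) * fs) + 1)
        if hi > lo:
            ecg[lo:hi] += amp * _gauss(np.arange(lo, hi) / fs, mu, sigma)

    for r_t, t_t in zip(r_times, t_times):
        add_bump(r_t, 0.012, 1.0)  # R
        add_bump(r_t - 0.030, 0.010, -0.10)  # Q
        add_bump(r_t + 0.030, 0.010, -0.15)  # S
        add_bump(t_t, 0.050, 0.30)  # T
    r_idx = np.round(r_times * fs).astype(int)
    t_idx = np.round(t_times * fs).astype(int)
    return ecg, r_idx, t_idx


def _pulse_shape(
    tau: np.ndarray,
    t_rise: float,
    width: float,
    dicrotic_scale: float = 1.0,
    apex_scale: float = 1.0,
) -> np.ndarray:
    """Unit-amplitude pulse over ``tau`` seconds since its foot.

    Geometry chosen so that the fiducials survive zero-phase band-pass
    filtering unshifted: a parabolic apex (locally symmetric around the
    systolic peak), a cosine diastolic decay with a small dicrotic bump, and
    a final parabolic plunge whose foot slope roughly mirrors the next
    pulse's upstroke (an asymmetric V-foot would bias the detected onset
    toward its flatter side).
    """
    t_mirror = 0.45 * t_rise  # symmetric-apex half-width past the peak
    kappa = 0.65  # foot-slope ratio of the descent vs the upstroke
    t_end = min(0.05, max(0.25 * (width - 1.45 * t_rise), 0.01))
    t_m = min(t_rise + t_mirror, width - t_end)
    t_f = width - t_end
    v_f = t_end / t_rise
    y_m = 1.0 - ((t_m - t_rise) / t_rise) ** 2
    y_f = kappa * (2 * v_f - v_f**2)

    y = np.empty_like(tau)
    s1 = tau <= t_rise
    u = tau[s1] / t_rise
    y[s1] = 2 * u - u**2
    s2 = (tau > t_rise) & (tau <= t_m)
    d = (tau[s2] - t_rise) / t_rise
    y[s2] = 1.0 - d**2
    s3 = (tau > t_m) & (tau <= t_f)
    if t_f > t_m:
        z = (tau[s3] - t_m) / (t_f - t_m)
        y[s3] = y_f + (y_m - y_f) * 0.5 * (1.0 + np.cos(np.pi * z))
    else:
        y[s3] = y_f
    s4 = tau > t_f
    v = (width - tau[s4]) / t_rise
    y[s4] = kappa * (2 * v - v**2)
    # dicrotic wave on the diastolic limb, well away from apex and foot
    y += np.where(
        s3,
        0.12 * dicrotic_scale * np.exp(-0.5 * ((tau - (t_rise + 0.28)) / 0.07) ** 2),
        0.0,
    )
    # sharp symmetric apex: high curvature pins the filtered maximum to the
    # programmed systolic sample despite the slow baseline the band-pass tilts
    y += 0.6 * apex_scale * np.exp(-0.5 * ((tau - t_rise) / 0.02) ** 2)
    return y


def generate_ppg(
    r_idx: np.ndarray,
    pat_true_s: np.ndarray,
    fs: float,
    artifacts: Sequence[ArtifactSegment] = (),
    n_samples: int | None = None,
    onset_delay_s: float = 0.13,
    amplitude: float = 0.05,
    amplitude_step_factor: float = 2.5,
    noise_burst_sigma_rel: float = 2.0,
    dropout_scale: float = 0.002,
    rng: np.random.Generator | None = None,
    amp_factors: np.ndarray | None = None,
    dicrotic_factors: np.ndarray | None = None,
    apex_factors: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Render a PPG whose foot and systolic peak are programmed per beat.

    The foot (onset) of pulse i sits at ``r_idx[i] + round(onset_delay_s·fs)``
    and its maximum at ``r_idx[i] + round(pat_true_s[i]·fs)``. Artifact
    segments modulate the rendering: ``amplitude_step`` alternates pulse
    amplitudes between ×factor and ×1 inside the segment (amplitude
    instability), ``noise_burst`` adds broadband noise at
    ``noise_burst_sigma_rel`` times the pulse amplitude, and ``dropout``
    scales pulses by ``dropout_scale``. Returns (ppg, onset_idx,
    systolic_idx, artifact_mask); ``artifact_mask`` flags the ``n-1`` pulses
    delimited by consecutive onsets.
    """
    r_idx = np.asarray(r_idx, dtype=int)
    pat = np.asarray(pat_true_s, dtype=float)
    if len(pat) != len(r_idx):
        raise ValueError("pat_true_s must be beat-aligned with r_idx")
    if np.any(pat <= onset_delay_s):
        raise ValueError("programmed PAT must exceed the onset delay")
    onset_idx = r_idx + int(round(onset_delay_s * fs))
    systolic_idx = r_idx + np.round(pat * fs).astype(int)
    if np.any(systolic_idx[:-1] >= onset_idx[1:]):
        raise ValueError("programmed systolic peak at/after the next onset")

    if n_samples is None:
        n_samples = int(onset_idx[-1] + np.median(np.diff(onset_idx)))
    if rng is None:
        rng = np.random.default_rng(0)

    n_pulses = len(r_idx) - 1
    seg_of_pulse: list[ArtifactSegment | None] = [None] * n_pulses
    artifact_mask = np.zeros(n_pulses, dtype=bool)
    for j in range(n_pulses):
        a, b = onset_idx[j] / fs, onset_idx[j + 1] / fs
        for seg in artifacts:
            if a < seg.end_s and b > seg.start_s:
                artifact_mask[j] = True
                seg_of_pulse[j] = seg
                break

    ppg = np.zeros(n_samples)
    pulse_amp = np.full(n_pulses + 1, amplitude)
    if amp_factors is not None:
        pulse_amp = pulse_amp * np.resize(np.asarray(amp_factors, float), n_pulses + 1)
    dic = np.ones(n_pulses + 1)
    if dicrotic_factors is not None:
        dic = np.resize(np.asarray(dicrotic_factors, float), n_pulses + 1)
    apex = np.ones(n_pulses + 1)
    if apex_factors is not None:
        apex = np.resize(np.asarray(apex_factors, float), n_pulses + 1)
    step_parity = 0
    for j in range(n_pulses):
        seg = seg_of_pulse[j]
        if seg is not None and seg.kind == "amplitude_step":
            pulse_amp[j] *= amplitude_step_factor if step_parity == 0 else 1.0
            step_parity ^= 1
        elif seg is not None and seg.kind == "dropout":
            pulse_amp[j] *= dropout_scale
    for j in range(n_pulses):
        a, b = onset_idx[j], onset_idx[j + 1]
        if b > n_samples:
            break
        tau = (np.arange(a, b) - a) / fs
        ppg[a:b] = pulse_amp[j] * _pulse_shape(
            tau, (systolic_idx[j] - a) / fs, (b - a) / fs, dic[j], apex[j]
        )
    # terminal partial pulse so the last beat is not a flatline
    a = onset_idx[-1]
    width = int(np.median(np.diff(onset_idx)))
    b = min(n_samples, a + width)
    if b > a:
        tau = (np.arange(a, b) - a) / fs
        ppg[a:b] = pulse_amp[-1] * _pulse_shape(
            tau, (systolic_idx[-1] - a) / fs, width / fs, dic[-1], apex[-1]
        )
    # partial lead-in pulse so the recording does not start from a flatline
    if n_pulses >= 1:
        w0 = onset_idx[1] - onset_idx[0]
        a0 = max(0, onset_idx[0] - w0)
        if onset_idx[0] > a0:
            tau = (np.arange(a0, onset_idx[0]) - (onset_idx[0] - w0)) / fs
            ppg[a0 : onset_idx[0]] = pulse_amp[0] * _pulse_shape(
                tau, (systolic_idx[0] - onset_idx[0]) / fs, w0 / fs, dic[0], apex[0]
            )
    # sharp symmetric notch pinning each foot (PPG feet are sharp); symmetry
    # keeps the filtered minimum at the programmed onset sample
    sigma_o = 0.018 * fs
    for j, o in enumerate(onset_idx):
        namp = 0.45 * min(pulse_amp[max(j - 1, 0)], pulse_amp[j])
        lo, hi = max(0, int(o - 4 * sigma_o)), min(n_samples, int(o + 4 * sigma_o))
        k = np.arange(lo, hi)
        ppg[lo:hi] -= namp * np.exp(-0.5 * ((k - o) / sigma_o) ** 2)

    for seg in artifacts:
        if seg.kind == "noise_burst":
            lo = max(0, int(round(seg.start_s * fs)))
            hi = min(n_samples, int(round(seg.end_s * fs)))
            ppg[lo:hi] += rng.normal(
                0.0, noise_burst_sigma_rel * amplitude, hi - lo
            )
    return ppg, onset_idx, systolic_idx, artifact_mask


def generate_recording(
    config: SynthConfig,
) -> tuple[Recording, SyntheticTruth, IntervalAnnotations]:
    """Compose RR, ECG, PPG (and a simple SpO2 ramp channel) into a full
    synthetic recording with ground truth and annotations. Fully reproducible
    from ``config.seed``."""
    # render on an extended internal timeline with warm-up/cool-down pulses
    # outside the emitted window, so the emitted PPG starts and ends
    # mid-train: analysis-filter edge transients then fall on padding beats
    # rather than on ground-truth pulses
    margin_s = 4.0
    ext = replace(config, duration_s=config.duration_s + 2 * margin_s)
    rr = generate_rr(ext)
    r_rel = 0.5 + np.concatenate(([0.0], np.cumsum(rr[:-1])))
    keep = r_rel + rr <= ext.duration_s
    rr, r_rel = rr[keep], r_rel[keep]
    truth_sel = (r_rel >= margin_s) & (r_rel + rr <= margin_s + config.duration_s)
    if truth_sel.sum() < 2:
        raise ValueError("duration too short for two beats")
    ecg, r_idx, t_idx = generate_ecg(rr, config.fs)
    lo = int(round(margin_s * config.fs))
    n_samples = int(round(config.duration_s * config.fs))
    # ECG carries beats only inside the emitted window (between beats the
    # baseline is zero, so zeroing the padding region leaves no step)
    i0 = int(np.argmax(truth_sel))
    i1 = len(rr) - int(np.argmax(truth_sel[::-1]))
    ecg_blank_lo = max(0, r_idx[i0] - int(0.35 * config.fs))
    ecg_blank_hi = min(len(ecg), t_idx[i1 - 1] + int(0.35 * config.fs))
    ecg[:ecg_blank_lo] = 0.0
    ecg[ecg_blank_hi:] = 0.0

    pat_true = np.asarray(
        config.pat_profile((r_idx - lo) / config.fs), dtype=float
    )
    # systolic peak must precede the next onset even for short RR
    max_pat = np.concatenate((np.diff(r_idx) / config.fs, [np.inf]))
    pat_true = np.minimum(pat_true, max_pat + config.onset_delay_s - 0.08)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    # respiration modulates pulse amplitudes; a smooth envelope ripple is a
    # feature of real PPG and gives the central-mean offset its working point
    phase = rng.uniform(0.0, 2.0 * np.pi)
    amp_f = 1.0 + config.resp_mod_depth * np.sin(
        2.0 * np.pi * config.resp_rate_hz * r_idx / config.fs + phase
    )
    dic_f = apex_f = None
    if config.rr_mode == "afib_like":
        # beat-to-beat morphology variability of irregular rhythm: stroke
        # volume (hence pulse amplitude) follows the preceding filling time,
        # and the pulse contour varies with it
        rr_prev = np.concatenate(([rr[0]], rr[:-1]))
        amp_f = amp_f * np.clip(rr_prev / config.mean_rr_s, 0.35, 1.8)
        dic_f = rng.uniform(0.4, 1.6, len(r_idx))
        apex_f = rng.uniform(0.75, 1.25, len(r_idx))
    shifted_artifacts = [
        ArtifactSegment(seg.start_s + margin_s, seg.duration_s, seg.kind)
        for seg in config.artifact_segments
    ]
    ppg, onset_idx, systolic_idx, artifact_mask = generate_ppg(
        r_idx,
        pat_true,
        config.fs,
        artifacts=shifted_artifacts,
        n_samples=int(round(ext.duration_s * config.fs)),
        onset_delay_s=config.onset_delay_s,
        amplitude=config.ppg_amplitude,
        amplitude_step_factor=config.amplitude_step_factor,
        noise_burst_sigma_rel=config.noise_burst_sigma_rel,
        dropout_scale=config.dropout_scale,
        rng=rng,
        amp_factors=amp_f,
        dicrotic_factors=dic_f,
        apex_factors=apex_f,
    )
    # cut the emitted window and keep truth for fully contained beats
    if len(ecg) < lo + n_samples:
        ecg = np.pad(ecg, (0, lo + n_samples - len(ecg)))
    if len(ppg) < lo + n_samples:
        ppg = np.pad(ppg, (0, lo + n_samples - len(ppg)))
    ecg = ecg[lo : lo + n_samples]
    ppg = ppg[lo : lo + n_samples]
    rr = rr[i0:i1]
    r_idx = r_idx[i0:i1] - lo
    t_idx = t_idx[i0:i1] - lo
    onset_idx = onset_idx[i0:i1] - lo
    systolic_idx = systolic_idx[i0:i1] - lo
    pat_true = pat_true[i0:i1]
    artifact_mask = artifact_mask[i0 : i1 - 1]

    intervals: list[Interval] = []
    stages = config.stages
    if stages is None:
        stages = [("NREM2", 0.0, config.duration_s)]
    for lab, start, dur in stages:
        intervals.append(Interval(Label(lab), start, dur))
    for lab, start, dur in config.events:
        intervals.append(Interval(Label(lab), start, dur))
    annotations = IntervalAnnotations(intervals)

    spo2 = np.full(int(config.duration_s), 96.0)
    for iv in annotations.by_label(Label.OXY_DESAT):
        lo, hi = int(iv.start_s), min(len(spo2), int(iv.end_s))
        u = np.linspace(0, 1, max(hi - lo, 1), endpoint=False)
        spo2[lo:hi] -= 4.0 * np.sin(np.pi * u)

    rhythm = np.full(
        len(r_idx), "irregular" if config.rr_mode == "afib_like" else "regular"
    )
    truth = SyntheticTruth(
        r_idx=r_idx,
        t_idx=t_idx,
        onset_idx=onset_idx,
        systolic_idx=systolic_idx,
        pat_true_s=pat_true,
        artifact_mask=artifact_mask,
        rhythm_label=rhythm,
        fs=config.fs,
    )
    truth.validate()
    recording = Recording(
        ecg=ecg,
        ppg=ppg,
        fs_ecg=config.fs,
        fs_ppg=config.fs,
        spo2=spo2,
        fs_spo2=1.0,
        subject_id=f"synth-{config.seed}",
    )
    return recording, truth, annotations


def with_seed(config: SynthConfig, seed: int) -> SynthConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
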