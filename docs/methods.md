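# Methods

This note documents the models, numerical conventions, and design decisions
behind `pulsepat`, and what the synthetic validation does and does not show.

## Signal model and pre-processing

Both channels are filtered zero-phase (forward-backward, `sosfiltfilt`) with
4th-order Butterworth designs, so fiducial timing is never skewed by filter
phase delay:

- **ECG**: low-pass at 25 Hz, then baseline removal. The baseline is the
  per-window median over 1-s windows hopping every 0.5 s, linearly
  interpolated between window centres with the edges held constant, and
  subtracted. A second, heavier band-pass (1–6 Hz) copy is produced solely
  for T-wave search: in that band the broad T wave dominates the residual
  QRS energy.
- **PPG**: band-pass 0.4–6 Hz, which removes baseline wander and
  high-frequency noise while keeping the first few pulse harmonics.

## Delineation

- **R peaks**: a deliberately simple adaptive-threshold detector (candidates
  from a 0.2-s-refractory peak search; threshold 40% of the median of
  per-2-s block maxima). It reaches sensitivity and positive predictivity
  ≥ 0.99 on clean synthetic ECG and is pluggable — any callable producing
  strictly increasing indices can replace it, since published QRS detectors
  are interchangeable here.
- **T peaks**: the first strict local maximum of the 1–6 Hz ECG in
  `[R_i + 0.06 s, R_{i+1})`. The 0.06-s standoff (about half the maximal
  normal QRS duration) is converted to samples by round-half-away-from-zero;
  plateaus resolve to their first sample. A monotone search region yields a
  missing T, and that beat simply produces no pulse ("no T" mode).
- **Pulse onsets**: argmin of the filtered PPG on `[R_i, T_i)`; **systolic
  peaks / envelope**: argmax and max on `[onset_i, onset_{i+1})`. All
  searches are half-open with ties resolved to the first index; the
  conventions are arbitrary but fixed and tested.

## Quality index

Per pulse, with defaults `k = 3`, `θ1 = 0`, `θ2 = 5·10⁻⁴` (envelope units),
median order 5:

1. `|e″(i)| = |e(i+2) − 2e(i+1) + e(i)|` over the per-pulse envelope;
2. 5-point centred running median (shrunken windows at the edges, so length
   is preserved);
3. subtract `k ×` the mean of the central 50% of the smoothed series
   (indices `round(0.25 N) … round(0.75 N)` inclusive, rounding half away
   from zero — the off-by-one here is unresolvable in principle and is fixed
   by this documented convention). The central slice avoids the corrupted
   lead-in/lead-out typical of overnight recordings;
4. `SQI = 1` iff the offset statistic is below `θ1` **and** the envelope
   exceeds `θ2`.

The N−2 stencil values map back to N pulses by assigning each stencil to its
central pulse; the first and last pulse inherit their nearest assigned
value. With fewer than three pulses the amplitude condition is
indeterminate and such pulses are conservatively low quality.

`θ2` (and hence `k`'s working point) is in raw filtered-amplitude units and
therefore device-dependent; `normalize_ppg` (CLI `--normalize-ppg`) divides
by the interior 95th-percentile amplitude for cross-device use.

Because the index watches only amplitude stability, rhythm-driven
variability is absorbed into the adaptive offset; this is what keeps
irregular rhythms high-quality. The flip side: the offset is a global
statistic, so the method assumes artifacts occupy a small fraction of the
recording (true overnight; the validation keeps contamination ≤ ~5% per
recording for the same reason).

## Template-matching comparator

The comparator follows its original two-stage description: per
non-overlapping 10-s window, physiological plausibility rules first (window
heart rate within 40–180 bpm, no inter-beat gap above 3 s, max/min
beat-interval ratio ≤ 2.2), then pulse extraction at the median peak-to-peak
width centred on each peak, a mean template, and per-pulse Pearson
correlation; the window passes iff the average correlation reaches 0.86 (the
threshold from the comparator's original publication; configurable). All
pulses in a failed window are low quality — which is exactly why a few bad
seconds cost the whole window, and why the interval-ratio rule condemns
clean irregular-rhythm windows.

## PAT pipeline

`PAT(i) = (systolic_idx(i) − r_idx(i)) / fs`, using the systolic peak (its
apnea dipping pattern is more pronounced than the onset's). Post-processing
order is fixed: correction → median filter → interpolation.

- **Correction**: SQI = 0 values are replaced by the mean of the M = 5
  following raw values in a single literal forward pass (the rule is
  non-recursive as written); missing values are skipped rather than counted;
  with fewer than M left the available ones are averaged, with none the
  previous corrected value is carried forward. `iterative=True` substitutes
  already-corrected values by walking back-to-front. An alternative
  `elimination_mode="exclude"` drops low-quality beats from the series
  entirely instead of correcting them — both modes exist because correction
  and elimination are equally defensible readings of "removing low-quality
  PAT"; `correct` is the default.
- **Smoothing**: n = 15 centred running median, shrunken at the edges
  (n = 15 is the largest order that still preserves the apnea dipping
  pattern at ~1 Hz beat rates).
- **Resampling**: modified Akima (makima) cubic Hermite interpolation on a
  uniform 5-Hz grid starting at the first valid knot, never extrapolating.
  Makima is exact on affine data and limits overshoot; the uniform series
  stays within the knot range plus < 5% of its span (asserted empirically).

Event analysis uses half-open windows: an event `[t0, t0+d)` and its
aftermath `[t0+d, t0+d+30 s)`; percentage change over a window is
`(max − min) / max`, undefined for fewer than two samples or a non-positive
maximum.

## Irregular-rhythm detector

A simplified, "inspired-by" sliding-window detector — it stratifies
statistics and is not claimed equivalent to any published coefficient set.
Per 8-beat window of the RR series: (a) ectopy filtering replaces only the
premature-short-then-compensatory-long couplet (>30% below / >15% above the
running 5-beat median) with the median — a deviation-only rule would also
flatten genuine sustained irregularity; (b) bigeminy windows (strictly
alternating difference signs with lag-2 RR autocorrelation > 0.8) are forced
regular; (c) the window is irregular when ≥ 70% of its successive
differences exceed 50 ms, (d) unless its mean heart rate falls below 0.8×
the 120-beat running baseline rate (a one-sided veto: a rule requiring rate
strictly *above* baseline would blind the detector to irregular rhythms at
an unchanged mean rate). Beat labels are the majority vote over covering
windows. On synthetic irregular rhythm (independent gamma RR, cv 0.25,
mean 1.0 s) about 91% of beats are flagged, pooled over seeds — adequate for
stratification, and honestly short of a tuned clinical detector. The final
annotated wake segment is excluded from rhythm analysis.

## Statistics

Per subject and category (stages, events, rhythm, quality — membership by
pulse onset time in half-open intervals), the summaries are the proportion
of SQI = 1 pulses and the IQR of PAT before/after post-processing. Paired
comparisons use the two-sided Wilcoxon signed-rank test (exact null for
n ≤ 25 nonzero pairs, else normal approximation with continuity correction;
zero differences dropped) with the matched-pairs rank-biserial correlation
`|W⁺ − W⁻| / (W⁺ + W⁻)` as an unsigned effect size: small < 0.30 ≤ medium
< 0.50 ≤ large. Anderson–Darling normality is reported as a diagnostic only.

## Synthetic generator

Waveforms are analytic templates, not physiological simulators, so every
fiducial is exact by construction:

- **ECG**: per beat, Gaussian Q/R/S bumps (R amplitude 1, σ = 12 ms) and a
  broad T (amplitude 0.3, σ = 50 ms) programmed at `R + min(0.30 s,
  0.75·RR)`.
- **PPG**: per pulse (onset-to-onset), a parabolic upstroke (foot → peak in
  130 ms), a mirrored parabola past the peak (locally symmetric apex), a
  cosine diastolic decay with a small dicrotic wave, and a final parabolic
  plunge into the next foot. A sharp symmetric Gaussian apex bump (σ = 20 ms)
  and foot notch (σ = 18 ms) pin the filtered extrema to the programmed
  samples: under zero-phase filtering only locally *asymmetric* features
  drift, so symmetry — not amplitude — is what makes recovery error
  measurable in samples. Respiration modulates pulse amplitudes by ±1% at
  0.25 Hz; this smooth physiological ripple is also what gives the central-
  mean offset a realistic working point. The recording is cut from a longer
  internal timeline with warm-up/cool-down pulses outside the emitted
  window, so analysis-filter edge transients fall on padding, not truth.
- **Rhythms**: `regular` (Gaussian jitter, cv 0.01), `afib_like`
  (independent gamma draws, cv 0.20 by default, plus beat-to-beat morphology
  variability — pulse amplitude follows the preceding filling time, dicrotic
  and apex prominence jitter), `bigeminy` (±30% alternating couplets).
- **Artifacts**: `amplitude_step` alternates pulse amplitudes ×2.5/×1 within
  the segment (amplitude instability — a *uniform* sustained rescale is
  invisible to any second-difference statistic by construction, and is not
  what motion artifacts look like in the envelope); `noise_burst` adds
  broadband noise at 2× pulse amplitude; `dropout` scales pulses by 0.002,
  pushing the envelope to ~10⁻⁴, below θ2. Clean pulse envelopes sit at
  ~0.03 units, so both branches of the quality rule are exercised.
- **SpO2** is a programmed 96% baseline with 4% desaturation ramps at
  annotated events — no physiology intended.

Ground truth (`SyntheticTruth`) carries per-beat R/T/onset/systolic indices,
programmed PAT, per-pulse artifact flags and rhythm labels, all validated on
every generation.

### What passing tests show — and don't

The generator proves the *mechanics*: delineation recovers programmed
fiducials to within a couple of samples; the quality rule separates
amplitude instability, noise and dropout from clean and from
irregular-but-clean pulses; post-processing contracts PAT dispersion where
artifacts corrupted it. It does not prove clinical performance: real PPG
morphology, device transfer functions, gradual artifact onsets, true
arrhythmia dynamics and inter-subject variability are all absent, and θ2 in
particular is device-specific. MESA-scale population statistics are out of
reach without that data.

## Validation conditions (scripts/acceptance.py and tests)

Study conditions used by the simulation-based checks, chosen once:
clean-recovery on a 10-min recording at 256 Hz with constant 0.25-s PAT;
artifact runs with one segment per recording — amplitude instability 20 s in
10 min, noise burst 40 s in 15 min, dropout 15 s in 10 min (≤ ~5%
contamination each, matching the small-artifact-fraction assumption of the
global offset); arrhythmia robustness on 4-min irregular-rhythm recordings
(mean RR 0.8 s); dispersion reduction inside a 40-s noise burst in 8-min
recordings; rhythm detection pooled over 4-min RR series (cv 0.25). Artifact
sensitivity is pooled over amplitude-instability and noise-burst pulses;
noise-burst misses concentrate at segment boundaries where the 5-point
median inherits clean neighbours, which is inherent to the smoothing.

## Known limitations

- θ1/θ2/k are equipment-dependent; the normalisation option mitigates but
  does not remove this.
- Beats with flat or undetectable T waves produce no pulse at all; a
  PPG-only fallback delineation is deliberately out of scope.
- The rhythm detector is a stratification aid, not a clinical AF detector.
- The EDF writer is minimal (16-bit, 1-s records, integer rates) and exists
  for fixtures and synthetic exports; reading uses mne, one channel per call
  so native per-channel rates are preserved.
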