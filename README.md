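# pulsepat

ECG-guided photoplethysmogram (PPG) signal-quality assessment and robust
pulse arrival time (PAT) estimation for polysomnography (PSG) recordings.

## The problem

PAT — the delay from the ECG R peak to the PPG systolic peak of the same
beat — tracks beat-to-beat blood-pressure changes and dips characteristically
around obstructive sleep apnea (OSA) and hypopnea events. Overnight PPG is,
however, riddled with motion artifacts, and the popular template-matching
quality indices misfire during irregular heart rhythms: pulses that differ in
timing are declared "low quality" even when each pulse is perfectly clean.

`pulsepat` implements a quality index that sidesteps rhythm entirely. For
each delineated pulse it takes the pulse-amplitude envelope
`ePPG(i) = max PPG` between adjacent pulse onsets and looks only at how
*stable* that envelope is:

```
|e″PPG(i)|   = |ePPG(i+2) − 2·ePPG(i+1) + ePPG(i)|        (absolute second difference)
|e″PPG(i)|s  = median5(|e″PPG(i)|)                         (5-point running median)
|e″PPG(i)|o  = |e″PPG(i)|s − k · mean(central 50%)         (offset, k = 3)

SQI(i) = 1  iff  |e″PPG(i)|o < θ1  and  ePPG(i) > θ2       (θ1 = 0, θ2 = 5·10⁻⁴)
```

Pulse onsets are found where an ECG should put them — at the PPG minimum
between each R peak and its T wave — so segmentation stays reliable even in
atrial fibrillation. Low-quality PAT values are replaced by the mean of the
M = 5 following values, smoothed with an n = 15 running median, and resampled
to a uniform 5 Hz series by modified Akima (makima) interpolation.

The package also ships the reference template-matching comparator, a
simplified RR-interval irregular-rhythm detector for stratification,
event-windowed percentage-change analysis, paired Wilcoxon / rank-biserial
statistics, and a synthetic PSG generator whose every fiducial (R, T, onset,
systolic peak, per-beat PAT, artifact labels) is known by construction.

## Worked example

```python
import numpy as np
from pulsepat import SynthConfig, generate_recording, run_pat_pipeline
from pulsepat.synthgen import ArtifactSegment

cfg = SynthConfig(
    duration_s=300.0, seed=11,
    artifact_segments=[ArtifactSegment(120.0, 30.0, "noise_burst")],
)
recording, truth, annotations = generate_recording(cfg)
series, pulses, beats = run_pat_pipeline(recording)

print(f"beats={len(beats)} pulses={len(pulses)} "
      f"low_quality={np.mean(pulses.sqi == 0):.3f}")
m = (series.beat_time_s >= 120) & (series.beat_time_s < 150)
iqr = lambda x: np.subtract(*np.nanpercentile(x, [75, 25]))
print(f"PAT IQR in artifact region: raw={iqr(series.pat_raw_s[m])*1e3:.1f} ms "
      f"corrected={iqr(series.pat_corr_s[m])*1e3:.1f} ms")
```

prints

```
beats=299 pulses=297 low_quality=0.071
PAT IQR in artifact region: raw=176.8 ms corrected=9.8 ms
```

The 30-s noise burst corrupts ~7% of pulses; the quality rule flags them,
and the correction/median/interpolation chain collapses the PAT dispersion
inside the contaminated region by an order of magnitude while leaving the
clean majority untouched (`series.uniform_t_s`, `series.uniform_pat_s` hold
the final 5 Hz series).

The same pipeline runs from the shell on EDF files:

```sh
pulsepat synth --seed 1 --out-dir demo/            # EDF + truth + annotations
pulsepat run demo/recording.edf --annotations demo/annotations.csv \
    --ecg-label EKG --ppg-label Pleth --out-dir demo/out
```

Channel names are mandatory because PSG montages vary; every algorithm
parameter (k, θ1, θ2, M, n, TM window and threshold, rhythm constants) can be
overridden from a YAML config, with CLI flags taking precedence.

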