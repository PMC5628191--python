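# fixclust

Noise-robust fixation detection for eye-tracking data by two-means
clustering, with monotone gap interpolation, a ground-truthed scanpath
simulator, and a noise × data-loss robustness evaluation harness.

## The problem

Remote video eye-trackers used with infants, school children and many
patient groups produce gaze recordings with high, variable position noise
and frequent episodes of data loss. Classical fixation detectors —
velocity-threshold (I-VT) and dispersion-threshold (I-DT) search rules —
degrade badly under those conditions: their outcome measures (number of
fixations, mean fixation duration) drift as soon as the noise level or the
amount of data loss changes, confounding any between-group or longitudinal
comparison. This package implements the identification-by-two-means-
clustering (I2MC) approach, a search rule designed specifically to keep
those outcome measures stable across a wide range of noise and data-loss
levels, for data from remote or tower-mounted trackers viewing static
stimuli.

## The algorithm

For a gaze position signal $(x_i, y_i)$ sampled at $f_s$ Hz (degrees of
visual angle), the pipeline is:

1. **Interpolation.** Runs of missing samples shorter than 100 ms, with at
   least two valid samples immediately on each side, are imputed with
   Steffen's monotonic piecewise-cubic interpolant (locally determined, no
   extrema between data points).
2. **Clustering weight.** A 200-ms window slides over the signal in 20-ms
   steps (with single-sample fallback at data-loss boundaries and the end
   of the trial). In each window the positions are forced into two
   clusters (2-means); every sample where cluster membership transitions
   receives weight $1/T$, $T$ the number of transitions in the window.
   This is repeated on the signal down-sampled to $f_s/2$, $f_s/5$ and
   $f_s/10$ (150/60/30 Hz at 300 Hz) and the per-rate weights are summed,
   then averaged over all windows covering each sample, and finally
   averaged across the two eyes. A window containing a saccade yields few
   transitions concentrated at the saccade (large weights); a
   fixation-only window yields many noise-driven transitions spread over
   the window (small weights).
3. **Labeling.** Samples with weight at or below the cutoff
   $\mu_w + 2\sigma_w$ become fixation candidates; adjacent candidates
   less than 0.7° apart and separated by less than 40 ms are merged;
   candidates shorter than 40 ms are removed.

All settings live in a single `Config` with the suggested 300-Hz values.

## Worked example

```python
import numpy as np
import fixclust as fc

# two fixations 8 degrees apart, 1 s at 300 Hz, 1 deg RMS-S2S noise
n, fs = 300, 300.0
x = np.zeros(n); x[150:] = 8.0
eye = lambda: fc.EyeSignal(x.copy(), np.zeros(n), np.zeros(n, dtype=np.uint8))
rec = fc.GazeRecording(np.arange(n) * 1000/fs, fs, eye(), eye())
noisy = fc.add_noise(rec, fc.NoiseSpec(target_rms_s2s=1.0), seed=3)

res = fc.detect_fixations(noisy)
print(fc.fixation_table(res.fixations).round(3).to_string(index=False))
```

prints

```
 start_ms  end_ms  duration_ms  x_deg  y_deg  rms_s2s_deg  frac_interpolated  frac_missing
    0.000   500.0      500.000  0.002  0.015        0.766                0.0           0.0
  516.667  1000.0      483.333  8.008  0.047        0.661                0.0           0.0
```

Two fixations are recovered despite 1° of injected noise; the centroids
sit at the true positions (0° and 8°), and the per-fixation RMS-S2S
(~0.7°) is the injected 1° per-eye noise reduced by √2 through binocular
averaging. The `examples/` directory contains one short script per
capability (detection, interpolation, simulation, robustness sweep).

The library is the primary interface; a thin CLI mirrors it for shell use:

```bash
fixclust simulate --n-fix 10 --noise-rms 2 --seed 1 --output gaze.tsv --truth truth.tsv
fixclust detect --input gaze.tsv --output fixations.tsv
fixclust sweep --noise 0,0.5,1,2 --loss 0,0.5,1 --reps 5 --out sweep_out
```

## Robustness evaluation

`fixclust.robustness_sweep` degrades a ground-truthed synthetic scanpath
with every combination of a noise grid (calibrated RMS-S2S amplitude,
white or AR(1)) and a data-loss grid (occurrence 0–100 % of the trial,
Poisson episode onsets, log-normal episode durations), runs the detector,
and tabulates the outcome measures plus ground-truth recovery statistics
(hits, misses, splits, merges, boundary errors). On a 10-fixation trial
the median detected count stays exactly 10 from 0–2° of added noise at
every loss level — the detector's headline property.

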