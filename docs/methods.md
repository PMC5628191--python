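# Methods

## Model and assumptions

The detector treats a gaze recording as an alternation of fixations
(position roughly constant, corrupted by tracker noise) and saccades
(fast, large position changes), sampled uniformly at `fs` Hz with
positions in degrees of visual angle. It labels **fixations only**: no
saccade, post-saccadic-oscillation or smooth-pursuit labeling is
attempted, and the approach assumes static stimuli (pursuit would defeat
the two-cluster assumption). The search rule is statistical rather than
kinematic: instead of thresholding a velocity or dispersion signal — whose
scale is exactly what noise corrupts — it asks, window by window, whether
a forced two-way clustering of the positions transitions once (saccade
evidence) or many times (noise). That makes the per-sample evidence
self-normalizing: each window distributes a total transition weight of
exactly 1 per clustering rate regardless of the noise amplitude.

Degrees are the canonical unit; pixel data are converted once at ingest
with a tangent-plane mapping centered on the screen (`atan(d/D)` for an
offset of `d` cm at viewing distance `D`), positive x rightward and
positive y downward. Sample indices are 0-based and intervals half-open,
so a duration is always `(end − start)·1000/fs` ms.

## Parameters (suggested values for 300-Hz data)

| setting | default | meaning / effect when changed |
|---|---|---|
| `interp_max_gap_ms` | 100 ms | longest gap imputed; larger values start bridging blinks and whole saccade–fixation–saccade sequences |
| `interp_edge_samples` | 2 | valid samples required on each side of a gap; also the knot count per side |
| `window_ms` | 200 ms | clustering window; long enough for at most ~2 fixations per window |
| `downsample_divisors` | 2, 5, 10 | extra clustering rates (150/60/30 Hz); removing them increases susceptibility to short noise bursts |
| `step_ms` | 20 ms | nominal window stride; outcome measures are stable between one-sample and 20-ms strides |
| `cutoff_sd` | 2 | candidate cutoff at mean + `cutoff_sd`·SD of the weight signal; higher is more conservative |
| `merge_dist_deg` | 0.7° | max centroid distance for merging adjacent candidates |
| `merge_gap_ms` | 40 ms | max temporal gap for merging |
| `min_fix_ms` | 40 ms | shorter candidates are discarded (strictly shorter; an exactly-40-ms candidate survives) |

## Numerical and design choices

- **Two-means procedure.** Cluster membership is found per window.
  Windows of at most 16 points — which covers the decimated rates at the
  default settings (12 and 6 points) — are clustered *exactly* by
  vectorized enumeration of all 2^(n−1) bipartitions, using the identity
  WCSS = Σ|p|² − |ΣS₁|²/n₁ − |ΣS₂|²/n₂. This costs no more than a few
  Lloyd sweeps at that size and removes the local-optimum failures that
  plain seeded Lloyd iteration shows on small, weakly structured windows
  (measured at tens of percent of random small windows). Larger windows
  use Lloyd iteration seeded deterministically from the means of the
  temporal halves of the window — reproducible, no randomness, and
  reliable there because full-rate windows carry strong two-cluster
  temporal structure. If a cluster empties it is reseeded with the point
  farthest from the surviving centroid. A zero-variance window returns a
  single cluster (zero transitions): "no saccade evidence".
- **Ties** in the point-to-centroid distance comparison go to cluster 1;
  only the transition pattern matters downstream, and label permutation is
  immaterial.
- **Decimation** is pure subsampling (every d-th sample from window
  index 0), without anti-alias filtering: the purpose of the extra rates
  is robustness to high-frequency noise via subsampling, and a low-pass
  filter would smear the very transitions being located. A transition at
  decimated index j is mapped back to original index j·d (first sample of
  the block), keeping it causally aligned with the step; the mapping is
  isolated in one place (`window_weights`) so block-center placement is a
  one-line change.
- **Window schedule.** The nominal stride is `step_ms`; when the next
  placement would include missing data or overrun the end, the start backs
  up one sample at a time to the last complete window, and after an
  unusable stretch the schedule restarts at the first complete window.
  Interpolated samples count as present (otherwise imputation would be
  pointless); residual missing samples are never covered and end up with
  undefined weight, which in turn breaks fixation candidates.
- **Candidate inclusion** is weight ≤ cutoff (not strict <) so that a
  saccade-free trial — whose weight signal is identically zero, hence
  cutoff zero — is labeled as one whole-trial fixation.
- **Merging** scans left to right repeatedly until a full pass makes no
  merge; the fixed point makes the result order-insensitive. Distance is
  centroid-to-centroid, recomputed from the underlying samples after each
  merge. Centroids are means over valid + interpolated samples; residual
  missing samples are excluded from the centroid but counted in
  `frac_missing`.
- **Steffen interpolation** uses as knots exactly the
  `interp_edge_samples` usable samples on each side of the gap (4 knots by
  default), matching the locality constraint. Gap eligibility is strict
  (`< 100 ms` fills, `= 100 ms` does not). Samples imputed by an earlier
  gap count as usable edges for a later one; gaps are processed left to
  right exactly once, which makes imputation idempotent.
- **Sample SD** (n−1 denominator) is used everywhere an SD is reported
  (weight cutoff, duration SD).

## The synthetic-data generator

`generate_scanpath` emulates an adult free-viewing protocol: fixation
durations uniform on 200–400 ms, saccade amplitudes uniform on 2–10°
("a wide range of amplitudes"), directions alternating horizontally/
vertically at random within a 30° field, both eyes identical before
degradation. Saccades have a smooth monotone sigmoidal position profile
(quintic smootherstep) with duration from the main-sequence rule
`2.2·A + 21` ms — realistic ramps that exercise the 200-ms window
assumption rather than idealized steps.

**Noise** is zero-mean, independent per eye and per axis, calibrated in
closed form to a target Euclidean sample-to-sample RMS: white Gaussian
with per-axis σ = target/2 (since the displacement variance is 4σ²), or a
stationary AR(1) process (per-axis σ = target/(2√(1−φ))) approximating
the temporal correlation of real video-tracker noise. The calibration is
exact in expectation; at 10⁵ samples the realized RMS-S2S is within 2 %
of the target.

**Data loss** occupies a contiguous region covering `occurrence` of the
trial (placed uniformly at random); within it, episode onsets follow a
Poisson process (default 1.0/s) and episode durations a log-normal
(median 60 ms, log-sigma 0.6) capped at 500 ms — short bursts of loss,
shared between the eyes as tracking failures are. These defaults are the
package's own parameterization of bursty remote-tracker loss; all of them
are exposed in `LossSpec` rather than hard-coded.

What the generator does **not** emulate: empirical infant noise spectra
(real tracker noise is neither white nor exactly AR(1)), pupil-size or
head-movement artifacts, blink dynamics (loss episodes are not blinks),
smooth pursuit, or position-dependent noise. Passing recovery tests on
this generator therefore demonstrates robustness to calibrated amplitude
and loss levels, not performance parity on any particular infant dataset.

## Evaluation machinery

Outcome measures are the fixation count, mean duration and SD of
durations. Recovery against ground truth uses greedy one-to-one matching
by maximal temporal overlap; a truth fixation overlapped by ≥ 2
detections counts as a split, a detection spanning ≥ 2 truth fixations as
a merge, and onset/offset errors are reported for matched pairs. The
noise level of a recording is estimated as the RMS-S2S of the longest
detected fixation. Sweeps derive one independent seed pair per
(noise, loss, replicate) cell from the base seed via `SeedSequence`, so
any cell can be reproduced in isolation.

Problem sizes: the standard robustness sweep uses a 10-fixation trial
(~3 s at 300 Hz), a 4-point noise grid (0–2°), a 3-point loss grid
(0–100 %) and 20 replicates — 240 detector runs, enough for stable
per-cell medians while keeping a full sweep under a minute.

## Known limitations

- **Boundary placement.** The clustering search rule concentrates
  membership transitions near the *spatial midpoint* of a saccade, so
  detected fixation boundaries fall inside the saccade transit (onsets a
  few ms early relative to saccade offset, offsets ~10–20 ms late relative
  to saccade onset for 2–10° saccades with realistic waveforms). Fixation
  *counts* and relative durations are robust; absolute boundary timing is
  accurate to the sample only for near-instantaneous position steps.
  Studies needing precise saccade onsets should use a dedicated saccade
  detector.
- Transition weights of a window with T transitions are stored as 1/T;
  their float sum reproduces 1 to ~1e-16, not always exactly.
- The stride fallback means window coverage (and hence the weight average)
  is denser near data-loss boundaries and the trial end; this is by
  design but makes per-sample coverage non-uniform.
- Merging compares centroid to centroid; two long candidates whose near
  edges are close but whose centroids are far stay unmerged.
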