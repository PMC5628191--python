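"""The two-means clustering-weight signal (the algorithm's search rule).

A 200-ms window slides over the gaze position signal.  In each window the
positions are forced into two clusters; if the window contains a saccade
there are few cluster-membership transitions, concentrated at the saccade,
whereas a window containing only a fixation produces many transitions
driven by noise, spread over the window.  Each transition sample receives a
clustering weight of 1/(number of transitions in the window); this is
repeated on the signal down-sampled to integer divisions of the sampling
frequency (150, 60 and 30 Hz for 300-Hz data) so that weight is not
dominated by high-frequency noise, the per-rate weights are summed, and
finally each sample's weights are averaged over every window placement that
covered it.  The resulting clustering-weight signal peaks at saccades and
stays low during fixations, across a wide range of noise levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError
from .recording import MISSING, Config, EyeSignal, window_samples

__all__ = [
    "WeightSignal",
    "two_means",
    "transition_weights",
    "decimate",
    "window_weights",
    "enumerate_windows",
    "weight_signal",
    "combine_eyes",
]

_MAX_LLOYD_ITER = 100
# Below this size the optimal two-clustering is found exactly by
# enumeration (2^(n-1) bipartitions); above it, Lloyd iteration from the
# deterministic temporal-halves seed.  Enumeration at n = 16 costs ~32k
# vectorized candidate evaluations, comparable to a few Lloyd iterations.
_EXACT_MAX_N = 16


@dataclass
class WeightSignal:
    """Per-sample averaged clustering weight plus window-coverage counts.

    ``weight`` is NaN exactly where ``coverage`` is 0 (samples never
    included in any complete window, e.g. inside residual data loss).
    """

    weight: np.ndarray
    coverage: np.ndarray

    @property
    def covered(self) -> np.ndarray:
        return self.coverage > 0


def two_means(points: np.ndarray) -> np.ndarray:
    """Force 2-D positions into two clusters; return labels in {1, 2}.

    Only where the membership transitions occur matters downstream, so the
    labeling is returned as-is (label permutation is immaterial).  A
    zero-variance window is degenerate and yields a single cluster (no
    transitions).

    Small windows (n ≤ 16, which covers the decimated rates at the default
    settings) are clustered exactly: every bipartition is enumerated and
    the global within-cluster sum-of-squares optimum returned.  Larger
    windows use Lloyd iteration from a deterministic seed — cluster 1 at
    the mean of the first half of the window, cluster 2 at the mean of the
    second half — exploiting the temporal structure of gaze data.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError("points must be an (n, 2) array")
    n = len(pts)
    if n < 2:
        raise InputError("two-means requires at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise InputError("points must be finite")
    if np.ptp(pts, axis=0).max() == 0.0:
        return np.ones(n, dtype=np.int8)
    if n <= _EXACT_MAX_N:
        return _two_means_exact(pts)
    return _two_means_lloyd(pts)


def _bipartition_masks(n: int) -> np.ndarray:
    """All 2^(n-1) − 1 non-trivial bipartition masks (point 0 in cluster 1)."""
    codes = np.arange(1, 2 ** (n - 1), dtype=np.uint32)
    return (codes[:, None] >> np.arange(n - 1)[None, :]) & 1


def _two_means_exact(pts: np.ndarray) -> np.ndarray:
    """Globally optimal two-clustering by vectorized enumeration.

    Uses the identity WCSS = Σ|p|² − |ΣS₁|²/n₁ − |ΣS₂|²/n₂ to score every
    bipartition in one pass.
    """
    n = len(pts)
    masks = _bipartition_masks(n)  # mask over points 1..n-1
    n2 = masks.sum(axis=1)
    n1 = n - n2
    s2 = masks @ pts[1:]  # cluster-2 coordinate sums
    s1 = pts.sum(axis=0) - s2
    score = (s1**2).sum(axis=1) / n1 + (s2**2).sum(axis=1) / n2
    best = int(np.argmax(score))  # max explained sum == min WCSS
    labels = np.ones(n, dtype=np.int8)
    labels[1:][masks[best] == 1] = 2
    return labels


def _two_means_lloyd(pts: np.ndarray) -> np.ndarray:
    n = len(pts)
    c = np.vstack([pts[: n // 2].mean(axis=0), pts[n // 2 :].mean(axis=0)])
    labels = np.zeros(n, dtype=np.int8)
    for _ in range(_MAX_LLOYD_ITER):
        d = ((pts[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
        new = np.where(d[:, 1] < d[:, 0], 2, 1).astype(np.int8)
        # k = 2 is maintained: if a cluster empties, it is reseeded with the
        # point farthest from the surviving centroid.
        for k in (1, 2):
            if not np.any(new == k):
                other = c[2 - k]  # surviving centroid
                far = int(np.argmax(((pts - other) ** 2).sum(axis=1)))
                new[far] = k
        if np.array_equal(new, labels):
            break
        labels = new
        for k in (1, 2):
            c[k - 1] = pts[labels == k].mean(axis=0)
    return labels


def transition_weights(labels: np.ndarray) -> np.ndarray:
    """Clustering weights for one window at one rate.

    A transition is a sample whose label differs from its predecessor; each
    transition sample gets 1/T where T is the total number of transitions
    in the window, all other samples get 0.
    """
    labels = np.asarray(labels)
    w = np.zeros(len(labels))
    trans = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    if trans.size:
        w[trans] = 1.0 / trans.size
    return w


def decimate(signal: np.ndarray, d: int) -> np.ndarray:
    """Every d-th sample starting at window-relative index 0."""
    signal = np.asarray(signal)
    if int(d) != d or d < 2:
        raise ConfigurationError("divisor must be an integer >= 2")
    if len(signal) % int(d) != 0:
        raise ConfigurationError("divisor must divide the window length")
    return signal[:: int(d)]


def window_weights(pts: np.ndarray, divisors: tuple[int, ...]) -> np.ndarray:
    """Summed per-sample weights for one window across all clustering rates.

    Runs two-means + transition weighting at the original rate and at each
    decimated rate; a decimated transition at index j (divisor d) is added
    at window-relative original index j·d (first sample of its block).
    """
    pts = np.asarray(pts, dtype=float)
    w = transition_weights(two_means(pts))
    for d in divisors:
        sub = decimate(pts, int(d))
        if len(sub) < 2:
            continue
        wd = transition_weights(two_means(sub))
        w[np.arange(len(sub)) * int(d)] += wd
    return w


def enumerate_windows(usable: np.ndarray, wl: int, step: int) -> list[int]:
    """Window start indices for the moving-window schedule.

    The window nominally advances by ``step`` samples.  When the proposed
    window would contain missing data or run past the end, the start index
    backs up one sample at a time to the last complete window; if none
    exists beyond the previous window, the schedule restarts at the first
    complete window after the unusable stretch.
    """
    usable = np.asarray(usable, dtype=bool)
    n = len(usable)
    if n < wl:
        raise InputError("signal shorter than one window")
    # bad[i] counts unusable samples in [i, i + wl)
    csum = np.concatenate(([0], np.cumsum(~usable)))
    bad = csum[wl:] - csum[:-wl]

    def clean(i: int) -> bool:
        return 0 <= i <= n - wl and bad[i] == 0

    starts: list[int] = []
    i = 0
    while i <= n - wl and not clean(i):
        i += 1
    if i > n - wl:
        return starts
    while True:
        starts.append(i)
        j = i + step
        if clean(j):
            i = j
            continue
        k = min(j, n - wl)
        while k > i and not clean(k):
            k -= 1
        if k > i and clean(k):
            i = k
            continue
        k = j
        while k <= n - wl and not clean(k):
            k += 1
        if k <= n - wl and clean(k):
            i = k
            continue
        break
    return starts


def weight_signal(sig: EyeSignal, cfg: Config, fs: float) -> WeightSignal:
    """Build the averaged clustering-weight signal for one eye.

    Interpolated samples count as present; windows never cover residual
    missing data.  The final weight of a sample is the arithmetic mean of
    the summed-across-rates weights it received from every window that
    included it; samples covered by no window have NaN weight.
    """
    wl = window_samples(cfg.window_ms, fs)
    cfg.validate(fs)
    step = max(1, int(round(cfg.step_ms * fs / 1000.0)))
    usable = sig.status != MISSING
    starts = enumerate_windows(usable, wl, step)
    n = len(sig.x)
    total = np.zeros(n)
    coverage = np.zeros(n, dtype=np.int64)
    pts_all = np.column_stack([sig.x, sig.y])
    for i in starts:
        w = window_weights(pts_all[i : i + wl], cfg.downsample_divisors)
        total[i : i + wl] += w
        coverage[i : i + wl] += 1
    weight = np.full(n, np.nan)
    np.divide(total, coverage, out=weight, where=coverage > 0)
    return WeightSignal(weight=weight, coverage=coverage)


def combine_eyes(
    wL: WeightSignal | None, wR: WeightSignal | None
) -> WeightSignal:
    """Average the two eyes' clustering-weight signals into the final signal.

    Where both eyes are defined the weights are averaged; where only one is
    defined that eye's weight is used; where neither, the result stays
    undefined.  With monocular input the single signal passes through.
    """
    if wL is None and wR is None:
        raise InputError("at least one eye's weight signal is required")
    if wL is None:
        return WeightSignal(wR.weight.copy(), wR.coverage.copy())
    if wR is None:
        return WeightSignal(wL.weight.copy(), wL.coverage.copy())
    stack = np.vstack([wL.weight, wR.weight])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        weight = np.nanmean(stack, axis=0)
    coverage = wL.coverage + wR.coverage
    return WeightSignal(weight=weight, coverage=coverage)
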