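"""Ground-truthed scanpath synthesis with controlled noise and data loss.

The generator emulates the evaluation protocol used to probe noise
robustness: start from a clean fixation–saccade sequence whose event
boundaries are known exactly, then inject (1) zero-mean position noise
calibrated to a target sample-to-sample RMS amplitude, and (2) episodes of
data loss covering a controllable fraction of the trial.  Because every
boundary is recorded in a :class:`GroundTruth`, detection output can be
scored against the truth at any noise × loss combination.

Saccades are synthesized with a smooth sigmoidal position profile whose
duration follows the main-sequence rule (2.2 ms/° · amplitude + 21 ms), a
standard empirical amplitude–duration relationship; fixations are
piecewise-stationary positions.  All three stochastic operations are
deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ConfigurationError, InputError
from .recording import MISSING, VALID, EyeSignal, GazeRecording

__all__ = [
    "GroundTruthEvent",
    "GroundTruth",
    "NoiseSpec",
    "LossSpec",
    "generate_scanpath",
    "add_noise",
    "add_data_loss",
    "resample_first_order",
    "truth_table",
]


@dataclass
class GroundTruthEvent:
    """One true event: a fixation (held position) or a saccade (endpoints)."""

    kind: str  # "fixation" | "saccade"
    start_ms: float
    end_ms: float
    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class GroundTruth:
    """The simulator's ordered event list; events tile the trial."""

    events: list[GroundTruthEvent]

    def fixations(self) -> list[GroundTruthEvent]:
        return [e for e in self.events if e.kind == "fixation"]

    def saccades(self) -> list[GroundTruthEvent]:
        return [e for e in self.events if e.kind == "saccade"]


@dataclass
class NoiseSpec:
    """Target amplitude and temporal model of injected position noise.

    ``target_rms_s2s`` is the Euclidean sample-to-sample RMS displacement
    of the added noise alone, in degrees.  ``white`` draws i.i.d. Gaussian
    noise; ``ar1`` draws a stationary first-order autoregressive process
    (coefficient ``ar1_phi``) approximating the temporally correlated noise
    real video trackers show.  Either model is calibrated in closed form so
    the realized RMS-S2S converges to the target.
    """

    target_rms_s2s: float
    model: str = "white"
    ar1_phi: float = 0.3

    def __post_init__(self) -> None:
        if self.target_rms_s2s < 0:
            raise ConfigurationError("target_rms_s2s must be non-negative")
        if self.model not in ("white", "ar1"):
            raise ConfigurationError("model must be 'white' or 'ar1'")
        if not (0 <= self.ar1_phi < 1):
            raise ConfigurationError("ar1_phi must be in [0, 1)")


@dataclass
class LossSpec:
    """Occurrence and per-episode duration model of injected data loss.

    ``occurrence`` is the fraction of the trial within which loss episodes
    may occur (0 = none, 1 = anywhere).  Episode onsets follow a Poisson
    process at ``rate_per_s``; each episode's duration is log-normal with
    the given median and log-scale sigma, capped at ``cap_ms`` so single
    episodes stay short bursts rather than wiping out whole trials.
    """

    occurrence: float
    rate_per_s: float = 1.0
    median_ms: float = 60.0
    sigma: float = 0.6
    cap_ms: float = 500.0

    def __post_init__(self) -> None:
        if not (0 <= self.occurrence <= 1):
            raise ConfigurationError("occurrence must be in [0, 1]")
        if self.median_ms <= 0 or self.rate_per_s < 0 or self.sigma < 0:
            raise ConfigurationError("invalid loss distribution parameters")
        if self.cap_ms < self.median_ms:
            raise ConfigurationError("cap_ms must be >= median_ms")


def _smootherstep(u: np.ndarray) -> np.ndarray:
    """Monotone sigmoidal ramp on [0, 1] with zero end-point velocity."""
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


def saccade_duration_ms(amplitude_deg: float) -> float:
    """Main-sequence amplitude–duration rule: 2.2 ms/° · A + 21 ms."""
    return 2.2 * amplitude_deg + 21.0


def generate_scanpath(
    n_fix: int = 10,
    fix_dur_ms: tuple[float, float] = (200.0, 400.0),
    sacc_amp_deg: tuple[float, float] = (2.0, 10.0),
    fs: float = 300.0,
    seed: int = 0,
    field_deg: float = 30.0,
) -> tuple[GazeRecording, GroundTruth]:
    """Generate a clean binocular scanpath with known event boundaries.

    Fixation durations and saccade amplitudes are drawn uniformly from the
    given (low, high) ranges; saccade directions alternate between
    horizontal and vertical at random, reflected to keep gaze inside a
    ``field_deg`` × ``field_deg`` box centered on (0, 0).  Both eyes carry
    identical positions (noise is added later, independently per eye).
    """
    if n_fix < 1:
        raise ConfigurationError("n_fix must be >= 1")
    if fs <= 0:
        raise ConfigurationError("fs must be positive")
    for lo, hi in (fix_dur_ms, sacc_amp_deg):
        if lo <= 0 or hi < lo:
            raise ConfigurationError("distribution ranges must be positive (low <= high)")
    rng = np.random.default_rng(seed)
    half = field_deg / 2.0

    events: list[GroundTruthEvent] = []
    t = 0.0
    pos = np.zeros(2)
    for i in range(n_fix):
        dur = float(rng.uniform(*fix_dur_ms))
        events.append(
            GroundTruthEvent("fixation", t, t + dur, pos[0], pos[1], pos[0], pos[1])
        )
        t += dur
        if i == n_fix - 1:
            break
        amp = float(rng.uniform(*sacc_amp_deg))
        axis = int(rng.integers(0, 2))  # 0 horizontal, 1 vertical
        sign = 1.0 if rng.random() < 0.5 else -1.0
        target = pos.copy()
        target[axis] += sign * amp
        if abs(target[axis]) > half:  # reflect to stay on the field
            target[axis] = pos[axis] - sign * amp
        sd = saccade_duration_ms(amp)
        events.append(
            GroundTruthEvent("saccade", t, t + sd, pos[0], pos[1], target[0], target[1])
        )
        t += sd
        pos = target

    total_ms = t
    n = int(round(total_ms * fs / 1000.0))
    time = np.arange(n) * (1000.0 / fs)
    x = np.empty(n)
    y = np.empty(n)
    bounds = np.array([e.start_ms for e in events] + [total_ms])
    idx = np.clip(np.searchsorted(bounds, time, side="right") - 1, 0, len(events) - 1)
    for k, ev in enumerate(events):
        sel = idx == k
        if not sel.any():
            continue
        if ev.kind == "fixation":
            x[sel] = ev.x0
            y[sel] = ev.y0
        else:
            u = (time[sel] - ev.start_ms) / ev.duration_ms
            s = _smootherstep(u)
            x[sel] = ev.x0 + (ev.x1 - ev.x0) * s
            y[sel] = ev.y0 + (ev.y1 - ev.y0) * s
    left = EyeSignal(x.copy(), y.copy(), np.full(n, VALID, dtype=np.uint8))
    right = EyeSignal(x.copy(), y.copy(), np.full(n, VALID, dtype=np.uint8))
    rec = GazeRecording(time=time, fs=fs, left=left, right=right,
                        meta={"generator": "scanpath", "seed": seed})
    return rec, GroundTruth(events=events)


def _noise_trace(n: int, spec: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """One axis of noise whose S2S difference variance is target²/4."""
    t = spec.target_rms_s2s
    if spec.model == "white":
        # Var(x_i − x_{i−1}) = 2σ² per axis; two axes sum to the Euclidean
        # displacement, so RMS-S2S = 2σ ⇒ σ = target/2.
        return rng.normal(0.0, t / 2.0, n)
    phi = spec.ar1_phi
    # Stationary AR(1): Var(Δx) = 2σx²(1−φ) per axis ⇒ σx = target/(2√(1−φ)).
    sx = t / (2.0 * np.sqrt(1.0 - phi))
    e = rng.normal(0.0, sx * np.sqrt(1.0 - phi**2), n)
    x0 = rng.normal(0.0, sx)
    out, _ = lfilter([1.0], [1.0, -phi], e, zi=[phi * x0])
    return out


def add_noise(rec: GazeRecording, spec: NoiseSpec, seed: int = 0) -> GazeRecording:
    """Add calibrated zero-mean noise, independently per eye and axis.

    The missing mask is untouched; a zero target returns a bit-identical
    copy.  The calibration is closed-form, so the realized RMS-S2S of the
    added noise converges to ``target_rms_s2s`` as the trial grows.
    """
    out = rec.copy()
    if spec.target_rms_s2s == 0:
        return out
    rng = np.random.default_rng(seed)
    for _, eye in out.eyes():
        nx = _noise_trace(rec.n, spec, rng)
        ny = _noise_trace(rec.n, spec, rng)
        ok = eye.present
        eye.x[ok] += nx[ok]
        eye.y[ok] += ny[ok]
    return out


def add_data_loss(rec: GazeRecording, spec: LossSpec, seed: int = 0) -> GazeRecording:
    """Inject data-loss episodes into a contiguous region of the trial.

    A region covering ``occurrence`` of the trial is placed uniformly at
    random; within it episode onsets follow a Poisson process and episode
    durations the capped log-normal model.  Affected samples of both eyes
    are set missing (tracking failure hits both eyes); valid samples
    elsewhere are untouched.
    """
    out = rec.copy()
    if spec.occurrence == 0 or spec.rate_per_s == 0:
        return out
    rng = np.random.default_rng(seed)
    t0, t1 = rec.time[0], rec.time[-1] + 1000.0 / rec.fs
    total = t1 - t0
    region_len = spec.occurrence * total
    region_start = t0 + rng.uniform(0.0, total - region_len)
    mask = np.zeros(rec.n, dtype=bool)
    t = region_start
    while True:
        t += rng.exponential(1000.0 / spec.rate_per_s)
        if t >= region_start + region_len:
            break
        dur = min(rng.lognormal(np.log(spec.median_ms), spec.sigma), spec.cap_ms)
        mask |= (rec.time >= t) & (rec.time < t + dur)
    for _, eye in out.eyes():
        eye.x[mask] = np.nan
        eye.y[mask] = np.nan
        eye.status[mask] = MISSING
    return out


def resample_first_order(rec: GazeRecording, target_fs: float) -> GazeRecording:
    """Down-sample with first-order (linear) interpolation.

    A target sample is missing iff either bracketing source sample is
    missing (an exact hit depends only on that one sample).
    """
    if target_fs <= 0:
        raise ConfigurationError("target_fs must be positive")
    if target_fs > rec.fs:
        raise InputError("target_fs must not exceed the source rate")
    n_new = int(np.floor((rec.time[-1] - rec.time[0]) * target_fs / 1000.0)) + 1
    t_new = rec.time[0] + np.arange(n_new) * (1000.0 / target_fs)

    def resample_eye(eye: EyeSignal) -> EyeSignal:
        left_idx = np.clip(
            np.searchsorted(rec.time, t_new, side="right") - 1, 0, rec.n - 1
        )
        right_idx = np.minimum(left_idx + 1, rec.n - 1)
        exact = np.isclose(t_new, rec.time[left_idx], rtol=0, atol=1e-9)
        right_idx = np.where(exact, left_idx, right_idx)
        denom = rec.time[right_idx] - rec.time[left_idx]
        frac = np.where(denom > 0, (t_new - rec.time[left_idx]) / np.where(denom > 0, denom, 1.0), 0.0)
        miss = eye.missing
        new_miss = miss[left_idx] | miss[right_idx]
        x = eye.x[left_idx] + (eye.x[right_idx] - eye.x[left_idx]) * frac
        y = eye.y[left_idx] + (eye.y[right_idx] - eye.y[left_idx]) * frac
        x[new_miss] = np.nan
        y[new_miss] = np.nan
        status = np.where(new_miss, MISSING, VALID).astype(np.uint8)
        return EyeSignal(x, y, status)

    return GazeRecording(
        time=t_new,
        fs=target_fs,
        left=resample_eye(rec.left) if rec.left is not None else None,
        right=resample_eye(rec.right) if rec.right is not None else None,
        meta={**rec.meta, "resampled_from_fs": rec.fs},
    )


def truth_table(truth: GroundTruth) -> pd.DataFrame:
    """Ground-truth events as a DataFrame for the tab-separated writer."""
    return pd.DataFrame(
        [
            {
                "kind": e.kind,
                "start_ms": e.start_ms,
                "end_ms": e.end_ms,
                "x0_deg": e.x0,
                "y0_deg": e.y0,
                "x1_deg": e.x1,
                "y1_deg": e.y1,
            }
            for e in truth.events
        ],
        columns=["kind", "start_ms", "end_ms", "x0_deg", "y0_deg", "x1_deg", "y1_deg"],
    )
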