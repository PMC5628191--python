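"""Core gaze-data containers, unit conversion and validation.

The canonical in-memory representation of an eye-tracking recording is a
:class:`GazeRecording`: a strictly increasing millisecond time base sampled
at a nominal frequency ``fs``, with one or two :class:`EyeSignal` streams
holding horizontal/vertical gaze position in degrees of visual angle and a
per-sample status mark.  Degrees are the canonical internal unit; pixel
input is converted once at ingest via :func:`pixels_to_degrees`.

Sample indexing is 0-based and every interval over samples is half-open
``[start, end)``, so a duration in milliseconds is always
``(end - start) * 1000 / fs``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InputError

__all__ = [
    "VALID",
    "MISSING",
    "INTERPOLATED",
    "EyeSignal",
    "GazeRecording",
    "ScreenGeometry",
    "Config",
    "ValidationReport",
    "pixels_to_degrees",
    "degrees_to_pixels",
    "validate_recording",
    "read_tsv",
    "write_tsv",
]

# Per-sample status codes.  Missing samples carry an explicit mark (their
# coordinates are NaN as well, but the mark is authoritative);
# INTERPOLATED is only ever assigned by the imputation stage.
VALID = 0
MISSING = 1
INTERPOLATED = 2


@dataclass
class EyeSignal:
    """Gaze position of one eye: degrees of visual angle plus a status mark."""

    x: np.ndarray
    y: np.ndarray
    status: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.status = np.asarray(self.status, dtype=np.uint8)
        if not (self.x.shape == self.y.shape == self.status.shape):
            raise InputError("x, y and status must have identical shapes")

    @classmethod
    def from_xy(cls, x: np.ndarray, y: np.ndarray) -> "EyeSignal":
        """Build a signal from raw coordinates; non-finite samples become missing."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        missing = ~(np.isfinite(x) & np.isfinite(y))
        status = np.where(missing, MISSING, VALID).astype(np.uint8)
        x = x.copy()
        y = y.copy()
        x[missing] = np.nan
        y[missing] = np.nan
        return cls(x=x, y=y, status=status)

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of samples with no usable coordinates."""
        return self.status == MISSING

    @property
    def present(self) -> np.ndarray:
        """Boolean mask of usable samples (valid or interpolated)."""
        return self.status != MISSING

    def copy(self) -> "EyeSignal":
        return EyeSignal(self.x.copy(), self.y.copy(), self.status.copy())


@dataclass
class GazeRecording:
    """A timestamped, possibly binocular gaze recording.

    Parameters
    ----------
    time
        Timestamps in milliseconds, strictly increasing, nominally uniform
        with spacing ``1000 / fs``.
    fs
        Sampling frequency in Hz.
    left, right
        Per-eye signals; at least one must be present.
    meta
        Free-form provenance notes.
    """

    time: np.ndarray
    fs: float
    left: EyeSignal | None = None
    right: EyeSignal | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.fs <= 0:
            raise InputError("fs must be positive")
        if self.left is None and self.right is None:
            raise InputError("at least one eye signal is required")
        for eye in (self.left, self.right):
            if eye is not None and eye.x.shape != self.time.shape:
                raise InputError("eye signal length must match time base")

    @property
    def n(self) -> int:
        return len(self.time)

    def eyes(self) -> list[tuple[str, EyeSignal]]:
        """Present eyes as (name, signal) pairs, left first."""
        out = []
        if self.left is not None:
            out.append(("left", self.left))
        if self.right is not None:
            out.append(("right", self.right))
        return out

    def copy(self) -> "GazeRecording":
        return GazeRecording(
            time=self.time.copy(),
            fs=self.fs,
            left=self.left.copy() if self.left is not None else None,
            right=self.right.copy() if self.right is not None else None,
            meta=dict(self.meta),
        )

    def combined_position(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean gaze position over the available eyes, NaN where none usable."""
        xs, ys = [], []
        for _, eye in self.eyes():
            xs.append(np.where(eye.present, eye.x, np.nan))
            ys.append(np.where(eye.present, eye.y, np.nan))
        with np.errstate(invalid="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                x = np.nanmean(np.vstack(xs), axis=0)
                y = np.nanmean(np.vstack(ys), axis=0)
        return x, y


@dataclass
class ScreenGeometry:
    """Screen size and viewing distance needed to map pixels to degrees."""

    width_px: float
    height_px: float
    width_cm: float
    height_cm: float
    distance_cm: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ConfigurationError(f"{f.name} must be strictly positive")


@dataclass
class Config:
    """Algorithm settings with the suggested values for 300-Hz data.

    ``window_ms`` is the width of the moving two-means window (200 ms keeps
    at most two fixations in a window); ``downsample_divisors`` give the
    extra clustering rates as integer divisors of ``fs`` (2, 5, 10 turn
    300 Hz into 150/60/30 Hz); ``cutoff_sd`` sets the fixation-candidate
    cutoff at mean + cutoff_sd·SD of the clustering-weight signal; merge and
    minimum-duration settings implement the categorization rules.
    """

    interp_max_gap_ms: float = 100.0
    interp_edge_samples: int = 2
    window_ms: float = 200.0
    downsample_divisors: tuple[int, ...] = (2, 5, 10)
    step_ms: float = 20.0
    cutoff_sd: float = 2.0
    merge_dist_deg: float = 0.7
    merge_gap_ms: float = 40.0
    min_fix_ms: float = 40.0

    def validate(self, fs: float | None = None) -> None:
        numeric = [
            "interp_max_gap_ms",
            "interp_edge_samples",
            "window_ms",
            "step_ms",
            "merge_dist_deg",
            "merge_gap_ms",
            "min_fix_ms",
        ]
        for name in numeric:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.cutoff_sd < 0:
            raise ConfigurationError("cutoff_sd must be non-negative")
        if self.window_ms <= self.step_ms:
            raise ConfigurationError("window_ms must exceed step_ms")
        for d in self.downsample_divisors:
            if int(d) != d or d < 2:
                raise ConfigurationError("downsample divisors must be integers >= 2")
        if fs is not None:
            wl = window_samples(self.window_ms, fs)
            for d in self.downsample_divisors:
                if wl % int(d) != 0:
                    raise ConfigurationError(
                        f"divisor {d} does not divide the window length ({wl} samples)"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        """Load a config whose keys mirror the field names exactly."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "downsample_divisors" in data:
            data["downsample_divisors"] = tuple(data["downsample_divisors"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["downsample_divisors"] = list(self.downsample_divisors)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def window_samples(window_ms: float, fs: float) -> int:
    """Number of samples in a window of ``window_ms`` at ``fs`` Hz."""
    return int(round(window_ms * fs / 1000.0))


def pixels_to_degrees(
    px_x: np.ndarray, px_y: np.ndarray, geom: ScreenGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Map pixel coordinates (origin top-left) to degrees of visual angle.

    Uses the tangent-plane mapping with the origin at the screen center:
    a point d centimeters from the center along an axis maps to
    ``atan(d / distance)`` degrees.  Positive x is rightward, positive y
    downward (screen convention).
    """
    px_x = np.asarray(px_x, dtype=float)
    px_y = np.asarray(px_y, dtype=float)
    cx = geom.width_px / 2.0
    cy = geom.height_px / 2.0
    x_cm = (px_x - cx) * (geom.width_cm / geom.width_px)
    y_cm = (px_y - cy) * (geom.height_cm / geom.height_px)
    deg_x = np.degrees(np.arctan2(x_cm, geom.distance_cm))
    deg_y = np.degrees(np.arctan2(y_cm, geom.distance_cm))
    return deg_x, deg_y


def degrees_to_pixels(
    deg_x: np.ndarray, deg_y: np.ndarray, geom: ScreenGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`pixels_to_degrees`."""
    deg_x = np.asarray(deg_x, dtype=float)
    deg_y = np.asarray(deg_y, dtype=float)
    x_cm = np.tan(np.radians(deg_x)) * geom.distance_cm
    y_cm = np.tan(np.radians(deg_y)) * geom.distance_cm
    px_x = x_cm / (geom.width_cm / geom.width_px) + geom.width_px / 2.0
    px_y = y_cm / (geom.height_cm / geom.height_px) + geom.height_px / 2.0
    return px_x, px_y


@dataclass
class ValidationReport:
    """Report-only summary of a recording's structural health."""

    n_samples: int
    fs: float
    flags: list[str]
    missing_fraction: dict[str, float]
    n_irregular_intervals: int

    @property
    def ok(self) -> bool:
        return not self.flags


def validate_recording(rec: GazeRecording) -> ValidationReport:
    """Check a recording against its structural invariants without mutating it.

    Flags raised: ``non-increasing time`` (any non-positive timestamp step),
    ``irregular spacing`` (any step deviating more than 1 % from 1000/fs),
    ``status/coordinate mismatch`` (finite coordinates flagged missing or
    NaNs flagged usable) and ``interpolated status on raw input`` when the
    recording has not passed through imputation but carries interpolated
    marks.
    """
    flags: list[str] = []
    dt = np.diff(rec.time)
    if np.any(dt <= 0):
        flags.append("non-increasing time")
    nominal = 1000.0 / rec.fs
    n_irr = int(np.sum(np.abs(dt - nominal) > 0.01 * nominal))
    if n_irr:
        flags.append("irregular spacing")
    missing_fraction: dict[str, float] = {}
    for name, eye in rec.eyes():
        finite = np.isfinite(eye.x) & np.isfinite(eye.y)
        if np.any(finite != eye.present):
            flags.append("status/coordinate mismatch")
        if not rec.meta.get("imputed", False) and np.any(eye.status == INTERPOLATED):
            flags.append("interpolated status on raw input")
        missing_fraction[name] = float(np.mean(eye.missing)) if rec.n else 0.0
    return ValidationReport(
        n_samples=rec.n,
        fs=rec.fs,
        flags=flags,
        missing_fraction=missing_fraction,
        n_irregular_intervals=n_irr,
    )


# ---------------------------------------------------------------------------
# Tab-separated I/O.  Dialect: header row `time_ms  L_X  L_Y  R_X  R_Y`;
# monocular files omit one eye pair; missing samples are empty fields or a
# configurable sentinel value.
# ---------------------------------------------------------------------------

def read_tsv(
    path: str | Path,
    fs: float | None = None,
    missing_sentinel: float | None = None,
) -> GazeRecording:
    """Read a gaze recording from a tab-separated file.

    If ``fs`` is omitted it is inferred from the median timestamp spacing.
    ``missing_sentinel`` marks an additional coordinate value (e.g. ``-9999``)
    to treat as missing besides empty fields.
    """
    df = pd.read_csv(path, sep="\t")
    if "time_ms" not in df.columns:
        raise InputError("expected a 'time_ms' column")
    time = df["time_ms"].to_numpy(dtype=float)
    if fs is None:
        if len(time) < 2:
            raise InputError("cannot infer fs from fewer than 2 samples")
        fs = 1000.0 / float(np.median(np.diff(time)))

    def eye_from(cols: tuple[str, str]) -> EyeSignal | None:
        if not all(c in df.columns for c in cols):
            return None
        x = df[cols[0]].to_numpy(dtype=float)
        y = df[cols[1]].to_numpy(dtype=float)
        if missing_sentinel is not None:
            x = np.where(x == missing_sentinel, np.nan, x)
            y = np.where(y == missing_sentinel, np.nan, y)
        return EyeSignal.from_xy(x, y)

    left = eye_from(("L_X", "L_Y"))
    right = eye_from(("R_X", "R_Y"))
    return GazeRecording(time=time, fs=fs, left=left, right=right,
                         meta={"source": str(path)})


def write_tsv(rec: GazeRecording, path: str | Path) -> None:
    """Write a recording in the same dialect; missing samples as empty fields."""
    data: dict[str, np.ndarray] = {"time_ms": rec.time}
    names = {"left": ("L_X", "L_Y"), "right": ("R_X", "R_Y")}
    for name, eye in rec.eyes():
        cx, cy = names[name]
        data[cx] = np.where(eye.present, eye.x, np.nan)
        data[cy] = np.where(eye.present, eye.y, np.nan)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, na_rep="")
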