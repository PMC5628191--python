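"""Gap detection and monotonic imputation of short data loss.

Short stretches of data loss (tracker dropouts, partial blinks) are filled
so that downstream windowed clustering keeps as much of the trial usable as
possible.  Two eligibility rules gate the imputation: the gap must be
shorter than ``interp_max_gap_ms`` (100 ms by default, so that entire
saccade–fixation–saccade sequences and most blinks are never bridged), and
at least ``interp_edge_samples`` usable samples must sit immediately on
both sides of the gap.

The interpolant is Steffen's monotonic piecewise cubic: it is determined
locally by the samples at each end of the gap and guarantees no extrema
between data points, so an imputed stretch can never overshoot the gaze
positions that bracket it — unlike an ordinary cubic spline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .recording import INTERPOLATED, MISSING, Config, EyeSignal, GazeRecording

__all__ = ["Gap", "find_gaps", "steffen_interpolate", "impute_gaps", "gap_table"]


@dataclass
class Gap:
    """A maximal run of missing samples, half-open over sample indices."""

    start: int
    end: int
    duration_ms: float
    eye: str = ""
    filled: bool = False


def find_gaps(sig: EyeSignal, fs: float, eye: str = "") -> list[Gap]:
    """Locate maximal runs of missing samples, in temporal order."""
    miss = sig.missing.astype(np.int8)
    if not miss.any():
        return []
    d = np.diff(np.concatenate(([0], miss, [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [
        Gap(start=int(s), end=int(e), duration_ms=(e - s) * 1000.0 / fs, eye=eye)
        for s, e in zip(starts, ends)
    ]


def _steffen_slopes(xk: np.ndarray, yk: np.ndarray) -> np.ndarray:
    """First-derivative estimates of Steffen's monotone interpolant."""
    h = np.diff(xk)              # interval widths
    s = np.diff(yk) / h          # secant slopes
    n = len(xk)
    dy = np.empty(n)
    if n == 2:
        # Single interval: the interpolant degenerates to the secant line.
        dy[:] = s[0]
        return dy
    # Interior points: weighted parabolic slope, limited so that the
    # interpolant stays monotone on each interval.
    p = (s[:-1] * h[1:] + s[1:] * h[:-1]) / (h[:-1] + h[1:])
    dy[1:-1] = (np.sign(s[:-1]) + np.sign(s[1:])) * np.minimum(
        np.minimum(np.abs(s[:-1]), np.abs(s[1:])), 0.5 * np.abs(p)
    )
    # Boundary points: one-sided parabola, clipped against the first/last
    # secant so that no extremum is introduced at the ends.
    p0 = s[0] * (1 + h[0] / (h[0] + h[1])) - s[1] * h[0] / (h[0] + h[1])
    if p0 * s[0] <= 0:
        dy[0] = 0.0
    elif abs(p0) > 2 * abs(s[0]):
        dy[0] = 2 * s[0]
    else:
        dy[0] = p0
    pn = s[-1] * (1 + h[-1] / (h[-1] + h[-2])) - s[-2] * h[-1] / (h[-1] + h[-2])
    if pn * s[-1] <= 0:
        dy[-1] = 0.0
    elif abs(pn) > 2 * abs(s[-1]):
        dy[-1] = 2 * s[-1]
    else:
        dy[-1] = pn
    return dy


def steffen_interpolate(
    xk: np.ndarray, yk: np.ndarray, xq: np.ndarray
) -> np.ndarray:
    """Evaluate Steffen's monotonic piecewise-cubic interpolant.

    Parameters
    ----------
    xk, yk
        Knot abscissae (strictly increasing, at least 2) and ordinates.
    xq
        Query abscissae inside ``[xk[0], xk[-1]]``.

    Returns
    -------
    ndarray
        Interpolant values; between two consecutive knots every value lies
        in the closed interval spanned by those two knot ordinates.
    """
    xk = np.asarray(xk, dtype=float)
    yk = np.asarray(yk, dtype=float)
    xq = np.asarray(xq, dtype=float)
    if len(xk) < 2:
        raise InputError("at least two knots are required")
    if np.any(np.diff(xk) <= 0):
        raise InputError("knot abscissae must be strictly increasing")
    if xq.size and (xq.min() < xk[0] or xq.max() > xk[-1]):
        raise InputError("query points must lie within the knot range")

    dy = _steffen_slopes(xk, yk)
    h = np.diff(xk)
    s = np.diff(yk) / h
    idx = np.clip(np.searchsorted(xk, xq, side="right") - 1, 0, len(xk) - 2)
    t = xq - xk[idx]
    a = (dy[idx] + dy[idx + 1] - 2 * s[idx]) / h[idx] ** 2
    b = (3 * s[idx] - 2 * dy[idx] - dy[idx + 1]) / h[idx]
    return ((a * t + b) * t + dy[idx]) * t + yk[idx]


def impute_gaps(rec: GazeRecording, cfg: Config | None = None) -> GazeRecording:
    """Fill eligible data-loss gaps, marking filled samples as interpolated.

    Each eye is processed independently, x and y independently.  A gap is
    filled iff its duration is strictly below ``cfg.interp_max_gap_ms`` and
    ``cfg.interp_edge_samples`` usable samples sit immediately on both
    sides; the knots are exactly those edge samples.  Edge samples filled by
    an earlier gap count as usable (gaps are processed left to right once).
    Ineligible gaps and valid samples are untouched; the operation is
    idempotent.
    """
    cfg = cfg or Config()
    out = rec.copy()
    k = int(cfg.interp_edge_samples)
    n = out.n
    for name, eye in out.eyes():
        gaps = find_gaps(eye, out.fs, eye=name)
        for gap in gaps:
            if gap.duration_ms >= cfg.interp_max_gap_ms:
                continue
            lo, hi = gap.start - k, gap.end + k
            if lo < 0 or hi > n:
                continue
            edges = np.r_[lo : gap.start, gap.end : hi]
            if np.any(eye.status[edges] == MISSING):
                continue
            xq = out.time[gap.start : gap.end]
            eye.x[gap.start : gap.end] = steffen_interpolate(
                out.time[edges], eye.x[edges], xq
            )
            eye.y[gap.start : gap.end] = steffen_interpolate(
                out.time[edges], eye.y[edges], xq
            )
            eye.status[gap.start : gap.end] = INTERPOLATED
            gap.filled = True
    out.meta["imputed"] = True
    return out


def gap_table(rec: GazeRecording, cfg: Config | None = None):
    """Gap report as a DataFrame (start_ms, end_ms, duration_ms, eye, filled).

    ``filled`` reflects eligibility under ``cfg`` without mutating ``rec``.
    """
    import pandas as pd

    cfg = cfg or Config()
    imputed = impute_gaps(rec, cfg)
    rows = []
    for name, eye in rec.eyes():
        imp_eye = dict(imputed.eyes())[name]
        for g in find_gaps(eye, rec.fs, eye=name):
            filled = bool(np.all(imp_eye.status[g.start : g.end] == INTERPOLATED))
            rows.append(
                {
                    "start_ms": rec.time[g.start],
                    "end_ms": rec.time[g.start] + g.duration_ms,
                    "duration_ms": g.duration_ms,
                    "eye": name,
                    "filled": "yes" if filled else "no",
                }
            )
    return pd.DataFrame(rows, columns=["start_ms", "end_ms", "duration_ms", "eye", "filled"])
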