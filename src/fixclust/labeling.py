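"""Fixation labeling: cutoff, merging, minimum duration, and the pipeline.

The categorization rules turn the clustering-weight signal into fixations:
all covered stretches with weight at or below a data-driven cutoff (mean
clustering weight plus ``cutoff_sd`` standard deviations) become fixation
candidates; adjacent candidates closer than ``merge_dist_deg`` and
separated by less than ``merge_gap_ms`` are merged; candidates shorter
than ``min_fix_ms`` are removed.  :func:`detect_fixations` orchestrates the
whole algorithm: gap imputation → per-eye weight signals → binocular
averaging → cutoff → candidates → merging → duration filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import WeightSignal, combine_eyes, weight_signal
from .errors import InputError
from .interpolate import Gap, find_gaps, impute_gaps
from .precision import rms_s2s
from .recording import INTERPOLATED, MISSING, Config, GazeRecording

__all__ = [
    "FixationCandidate",
    "Fixation",
    "DetectionResult",
    "weight_cutoff",
    "extract_candidates",
    "merge_candidates",
    "filter_short",
    "detect_fixations",
    "fixation_table",
]


@dataclass
class FixationCandidate:
    """A below-cutoff stretch, half-open over sample indices."""

    start: int
    end: int
    cx: float = np.nan
    cy: float = np.nan

    def duration_ms(self, fs: float) -> float:
        return (self.end - self.start) * 1000.0 / fs


@dataclass
class Fixation:
    """A labeled fixation with centroid, duration and quality descriptors."""

    start: int
    end: int
    start_ms: float
    end_ms: float
    duration_ms: float
    x: float
    y: float
    rms_s2s: float
    frac_interpolated: float
    frac_missing: float


@dataclass
class DetectionResult:
    """Fixations plus every intermediate needed to reproduce them."""

    fixations: list[Fixation]
    weight: WeightSignal
    cutoff: float
    gaps: list[Gap]
    recording: GazeRecording  # after imputation
    config: Config = field(default_factory=Config)


def weight_cutoff(w: WeightSignal, cfg: Config) -> float:
    """Fixation-candidate cutoff: mean + cutoff_sd · SD of covered weights.

    The standard deviation is the sample SD (n−1 denominator).
    """
    vals = w.weight[w.covered]
    if len(vals) < 2:
        raise InputError("cutoff requires at least 2 covered samples")
    return float(vals.mean() + cfg.cutoff_sd * vals.std(ddof=1))


def extract_candidates(w: WeightSignal, cutoff: float) -> list[FixationCandidate]:
    """Maximal covered runs with weight at or below the cutoff.

    Supra-cutoff samples and uncovered samples (residual data loss) both
    terminate a run, so fixation candidates may be broken up by periods of
    data loss.  Inclusion is weight ≤ cutoff so that a saccade-free trial
    (zero-variance weight signal) yields one whole-trial candidate.
    """
    if not np.isfinite(cutoff):
        raise InputError("cutoff must be finite")
    ok = w.covered & (np.nan_to_num(w.weight, nan=np.inf) <= cutoff)
    d = np.diff(np.concatenate(([0], ok.astype(np.int8), [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [FixationCandidate(int(s), int(e)) for s, e in zip(starts, ends)]


def _centroid(rec: GazeRecording, start: int, end: int) -> tuple[float, float]:
    """Mean combined-eye position over non-missing samples in [start, end)."""
    x, y = rec.combined_position()
    xs = x[start:end]
    ys = y[start:end]
    ok = np.isfinite(xs) & np.isfinite(ys)
    if not ok.any():
        return np.nan, np.nan
    return float(xs[ok].mean()), float(ys[ok].mean())


def merge_candidates(
    cands: list[FixationCandidate], rec: GazeRecording, cfg: Config
) -> list[FixationCandidate]:
    """Merge nearby candidates (centroid distance and temporal gap rules).

    Adjacent pairs with centroid Euclidean distance < ``merge_dist_deg``
    and inter-candidate gap < ``merge_gap_ms`` are merged, scanning left to
    right repeatedly until a full pass makes no merge (fixed point); the
    merged candidate's centroid is recomputed from the underlying samples.
    """
    for a, b in zip(cands, cands[1:]):
        if a.end > b.start:
            raise InputError("candidates must be non-overlapping and ordered")
    out = [FixationCandidate(c.start, c.end) for c in cands]
    for c in out:
        c.cx, c.cy = _centroid(rec, c.start, c.end)
    changed = True
    while changed:
        changed = False
        merged: list[FixationCandidate] = []
        i = 0
        while i < len(out):
            cur = out[i]
            while i + 1 < len(out):
                nxt = out[i + 1]
                gap_ms = (nxt.start - cur.end) * 1000.0 / rec.fs
                dist = float(np.hypot(cur.cx - nxt.cx, cur.cy - nxt.cy))
                if gap_ms < cfg.merge_gap_ms and dist < cfg.merge_dist_deg:
                    cur = FixationCandidate(cur.start, nxt.end)
                    cur.cx, cur.cy = _centroid(rec, cur.start, cur.end)
                    i += 1
                    changed = True
                else:
                    break
            merged.append(cur)
            i += 1
        out = merged
    return out


def filter_short(
    cands: list[FixationCandidate], rec: GazeRecording, cfg: Config
) -> list[Fixation]:
    """Drop candidates shorter than ``min_fix_ms``; finalize survivors.

    Removal is strict (< min_fix_ms), so a candidate of exactly the minimum
    duration is kept.  Survivors get centroid, RMS-S2S over their samples,
    and the fractions of interpolated and missing samples in their span.
    """
    x, y = rec.combined_position()
    out: list[Fixation] = []
    for c in cands:
        dur = c.duration_ms(rec.fs)
        if dur < cfg.min_fix_ms:
            continue
        sl = slice(c.start, c.end)
        cx, cy = _centroid(rec, c.start, c.end)
        try:
            rms = rms_s2s(x[sl], y[sl])
        except InputError:
            rms = np.nan
        span = c.end - c.start
        interp = missing = 0
        # A sample counts as interpolated if any contributing eye was
        # imputed there, missing if no eye has usable data.
        any_present = np.zeros(span, dtype=bool)
        any_interp = np.zeros(span, dtype=bool)
        for _, eye in rec.eyes():
            any_present |= eye.present[sl]
            any_interp |= eye.status[sl] == INTERPOLATED
        frac_missing = float(np.mean(~any_present))
        frac_interp = float(np.mean(any_interp & any_present))
        start_ms = float(rec.time[c.start])
        out.append(
            Fixation(
                start=c.start,
                end=c.end,
                start_ms=start_ms,
                end_ms=start_ms + dur,
                duration_ms=dur,
                x=cx,
                y=cy,
                rms_s2s=rms,
                frac_interpolated=frac_interp,
                frac_missing=frac_missing,
            )
        )
    return out


def detect_fixations(rec: GazeRecording, cfg: Config | None = None) -> DetectionResult:
    """Run the full fixation-detection pipeline on a recording.

    Deterministic for fixed input and config.  Raises if no complete
    clustering window fits in the recording (e.g. fully missing input).
    """
    cfg = cfg or Config()
    cfg.validate(rec.fs)
    gaps = [g for name, eye in rec.eyes() for g in find_gaps(eye, rec.fs, name)]
    imputed = impute_gaps(rec, cfg)
    wL = weight_signal(imputed.left, cfg, rec.fs) if imputed.left else None
    wR = weight_signal(imputed.right, cfg, rec.fs) if imputed.right else None
    w = combine_eyes(wL, wR)
    cutoff = weight_cutoff(w, cfg)
    cands = extract_candidates(w, cutoff)
    cands = merge_candidates(cands, imputed, cfg)
    fixations = filter_short(cands, imputed, cfg)
    return DetectionResult(
        fixations=fixations,
        weight=w,
        cutoff=cutoff,
        gaps=gaps,
        recording=imputed,
        config=cfg,
    )


def fixation_table(fixations: list[Fixation]) -> pd.DataFrame:
    """Fixations as a DataFrame in the tab-separated output dialect."""
    return pd.DataFrame(
        [
            {
                "start_ms": f.start_ms,
                "end_ms": f.end_ms,
                "duration_ms": f.duration_ms,
                "x_deg": f.x,
                "y_deg": f.y,
                "rms_s2s_deg": f.rms_s2s,
                "frac_interpolated": f.frac_interpolated,
                "frac_missing": f.frac_missing,
            }
            for f in fixations
        ],
        columns=[
            "start_ms",
            "end_ms",
            "duration_ms",
            "x_deg",
            "y_deg",
            "rms_s2s_deg",
            "frac_interpolated",
            "frac_missing",
        ],
    )
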