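"""Outcome measures, ground-truth scoring and noise × loss robustness sweeps.

The outcome measures mirror those used to judge detector robustness: the
number of detected fixations, the mean fixation duration and its standard
deviation.  A robust detector keeps these measures flat as noise and data
loss are injected into the same underlying scanpath.
:func:`robustness_sweep` runs detection over a full noise × loss ×
replicate grid, scoring each run against the generator's ground truth, and
:func:`duration_histogram2d` summarizes the resulting fixation-duration
distributions per grid cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .labeling import Fixation, detect_fixations
from .precision import rms_s2s
from .recording import Config, GazeRecording
from .synth import GroundTruth, LossSpec, NoiseSpec, add_data_loss, add_noise

__all__ = [
    "OutcomeMeasures",
    "MatchResult",
    "SweepResult",
    "rms_s2s",
    "outcome_measures",
    "match_events",
    "noise_level_estimate",
    "robustness_sweep",
    "duration_histogram2d",
    "plot_sweep",
]


@dataclass
class OutcomeMeasures:
    """Fixation count, mean duration and SD of durations (sample SD, n−1)."""

    n_fixations: int
    mean_duration_ms: float  # NaN when no fixations
    sd_duration_ms: float  # NaN when fewer than 2 fixations


def outcome_measures(fixations: list[Fixation]) -> OutcomeMeasures:
    """Summarize a list of fixations into the three outcome measures."""
    durs = np.array([f.duration_ms for f in fixations], dtype=float)
    n = len(durs)
    return OutcomeMeasures(
        n_fixations=n,
        mean_duration_ms=float(durs.mean()) if n >= 1 else np.nan,
        sd_duration_ms=float(durs.std(ddof=1)) if n >= 2 else np.nan,
    )


@dataclass
class MatchResult:
    """Recovery statistics of detected fixations against ground truth."""

    hits: int
    misses: int
    splits: int  # truth fixations covered by >= 2 detections
    merges: int  # detections spanning >= 2 truth fixations
    onset_errors_ms: np.ndarray  # detected − true onset, one per hit
    offset_errors_ms: np.ndarray
    hits_within_tol: int


def match_events(
    detected: list[Fixation], truth: GroundTruth, tolerance_ms: float = 20.0
) -> MatchResult:
    """Greedy one-to-one matching of detections to truth by temporal overlap.

    Pairs are matched in order of decreasing overlap; a truth fixation
    overlapped by two or more detections counts as split, a detection
    overlapping two or more truth fixations as merge.  Onset/offset errors
    (detected − true, ms) are reported for matched pairs, and
    ``hits_within_tol`` counts hits whose boundary errors both stay within
    ``tolerance_ms``.
    """
    if tolerance_ms < 0:
        raise InputError("tolerance_ms must be non-negative")
    tfix = truth.fixations()
    nd, nt = len(detected), len(tfix)
    if nd == 0 or nt == 0:
        return MatchResult(0, nt, 0, 0, np.array([]), np.array([]), 0)
    ov = np.zeros((nd, nt))
    for i, d in enumerate(detected):
        for j, t in enumerate(tfix):
            ov[i, j] = max(0.0, min(d.end_ms, t.end_ms) - max(d.start_ms, t.start_ms))
    # one-to-one greedy matching by maximal overlap
    pairs: list[tuple[int, int]] = []
    work = ov.copy()
    while True:
        i, j = np.unravel_index(np.argmax(work), work.shape)
        if work[i, j] <= 0:
            break
        pairs.append((int(i), int(j)))
        work[i, :] = 0
        work[:, j] = 0
    onset = np.array([detected[i].start_ms - tfix[j].start_ms for i, j in pairs])
    offset = np.array([detected[i].end_ms - tfix[j].end_ms for i, j in pairs])
    matched_t = {j for _, j in pairs}
    splits = int(np.sum((ov > 0).sum(axis=0) >= 2))
    merges = int(np.sum((ov > 0).sum(axis=1) >= 2))
    within = int(
        np.sum((np.abs(onset) <= tolerance_ms) & (np.abs(offset) <= tolerance_ms))
    )
    return MatchResult(
        hits=len(pairs),
        misses=nt - len(matched_t),
        splits=splits,
        merges=merges,
        onset_errors_ms=onset,
        offset_errors_ms=offset,
        hits_within_tol=within,
    )


def noise_level_estimate(fixations: list[Fixation]) -> float:
    """Noise level of a recording: RMS-S2S of the longest detected fixation."""
    if not fixations:
        raise InputError("no fixations to estimate noise from")
    longest = max(fixations, key=lambda f: f.duration_ms)
    return longest.rms_s2s


@dataclass
class SweepResult:
    """Long-format outcome table over a noise × loss × replicate grid.

    ``table`` holds one row per grid cell per replicate; ``durations``
    maps (noise, loss) cells to the pooled detected fixation durations of
    that cell, which back the 2-D duration histograms.
    """

    table: pd.DataFrame
    durations: dict[tuple[float, float], np.ndarray] = field(default_factory=dict)
    base_seed: int = 0

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def cell_median_counts(self) -> pd.DataFrame:
        """Median detected fixation count per (noise, loss) cell."""
        return (
            self.table.groupby(["noise_rms", "loss_occurrence"])["n_fixations"]
            .median()
            .reset_index()
        )


def _child_seeds(base_seed: int, i: int, j: int, r: int) -> tuple[int, int]:
    """Two deterministic sub-2³¹ seeds for one grid cell and replicate."""
    ss = np.random.SeedSequence([int(base_seed), i, j, r])
    a, b = ss.generate_state(2)
    return int(a & 0x7FFFFFFF), int(b & 0x7FFFFFFF)


def robustness_sweep(
    rec: GazeRecording,
    truth: GroundTruth,
    noise_grid: list[float],
    loss_grid: list[float],
    replicates: int = 20,
    base_seed: int = 0,
    cfg: Config | None = None,
    noise_model: str = "white",
    loss_template: LossSpec | None = None,
    tolerance_ms: float = 20.0,
) -> SweepResult:
    """Detect fixations over the full noise × loss × replicate grid.

    For each cell and replicate, two child seeds derived from
    ``(base_seed, cell indices, replicate)`` drive noise injection and loss
    injection, the detector runs on the degraded copy of ``rec``, and the
    outcome measures plus ground-truth recovery statistics are recorded.
    Fully reproducible per ``base_seed``.
    """
    if not noise_grid or not loss_grid or replicates < 1:
        raise InputError("grids must be non-empty and replicates >= 1")
    cfg = cfg or Config()
    rows = []
    durations: dict[tuple[float, float], list[float]] = {
        (nz, lo): [] for nz in noise_grid for lo in loss_grid
    }
    for i, nz in enumerate(noise_grid):
        for j, lo in enumerate(loss_grid):
            for r in range(replicates):
                s_noise, s_loss = _child_seeds(base_seed, i, j, r)
                degraded = add_noise(rec, NoiseSpec(nz, model=noise_model), s_noise)
                if loss_template is None:
                    loss = LossSpec(occurrence=lo)
                else:
                    loss = LossSpec(
                        occurrence=lo,
                        rate_per_s=loss_template.rate_per_s,
                        median_ms=loss_template.median_ms,
                        sigma=loss_template.sigma,
                        cap_ms=loss_template.cap_ms,
                    )
                degraded = add_data_loss(degraded, loss, s_loss)
                res = detect_fixations(degraded, cfg)
                om = outcome_measures(res.fixations)
                mr = match_events(res.fixations, truth, tolerance_ms)
                durations[(nz, lo)].extend(f.duration_ms for f in res.fixations)
                rows.append(
                    {
                        "noise_rms": nz,
                        "loss_occurrence": lo,
                        "replicate": r,
                        "seed_noise": s_noise,
                        "seed_loss": s_loss,
                        "n_fixations": om.n_fixations,
                        "mean_duration_ms": om.mean_duration_ms,
                        "sd_duration_ms": om.sd_duration_ms,
                        "hits": mr.hits,
                        "misses": mr.misses,
                        "splits": mr.splits,
                        "merges": mr.merges,
                        "mean_abs_onset_err_ms": float(np.mean(np.abs(mr.onset_errors_ms)))
                        if mr.hits
                        else np.nan,
                        "mean_abs_offset_err_ms": float(np.mean(np.abs(mr.offset_errors_ms)))
                        if mr.hits
                        else np.nan,
                        "hits_within_tol": mr.hits_within_tol,
                    }
                )
    table = pd.DataFrame(rows)
    return SweepResult(
        table=table,
        durations={k: np.asarray(v) for k, v in durations.items()},
        base_seed=base_seed,
    )


def duration_histogram2d(
    sweep: SweepResult, edges: np.ndarray
) -> dict[tuple[float, float], np.ndarray]:
    """Per-cell histograms of detected fixation durations.

    Returns counts per (noise, loss) cell over the given increasing bin
    edges; when the edges cover every observed duration, each cell's total
    equals that cell's summed fixation count.
    """
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise InputError("bin edges must be strictly increasing")
    return {
        cell: np.histogram(durs, bins=edges)[0]
        for cell, durs in sweep.durations.items()
    }


def plot_sweep(sweep: SweepResult, measure: str = "n_fixations", path=None):
    """Plot a measure versus noise level, one line per data-loss level."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    med = (
        sweep.table.groupby(["noise_rms", "loss_occurrence"])[measure]
        .median()
        .reset_index()
    )
    fig, ax = plt.subplots(figsize=(5, 4))
    losses = sorted(med["loss_occurrence"].unique())
    for k, lo in enumerate(losses):
        sub = med[med["loss_occurrence"] == lo]
        shade = 0.8 * (1 - k / max(1, len(losses) - 1)) if len(losses) > 1 else 0.0
        ax.plot(sub["noise_rms"], sub[measure], "o-", color=str(shade),
                label=f"loss {lo:.0%}")
    ax.set_xlabel("added RMS-S2S noise (deg)")
    ax.set_ylabel(measure)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
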