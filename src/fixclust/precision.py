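"""Sample-to-sample RMS precision, the package's noise-amplitude measure."""

from __future__ import annotations

import numpy as np

from .errors import InputError

__all__ = ["rms_s2s"]


def rms_s2s(x: np.ndarray, y: np.ndarray) -> float:
    """RMS of consecutive-sample Euclidean gaze displacements, in degrees.

    Only adjacent sample pairs in which both members are non-missing
    (finite) contribute; pairs spanning a gap are dropped rather than
    bridged.  This is the conventional RMS-S2S precision measure: during a
    fixation it estimates the noise amplitude of the recording.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        raise InputError("rms_s2s requires at least 2 non-missing samples")
    pair = ok[1:] & ok[:-1]
    if not pair.any():
        raise InputError("rms_s2s requires at least one adjacent non-missing pair")
    dx = np.diff(x)[pair]
    dy = np.diff(y)[pair]
    return float(np.sqrt(np.mean(dx**2 + dy**2)))
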