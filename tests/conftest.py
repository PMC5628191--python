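import numpy as np
import pytest

from fixclust import EyeSignal, GazeRecording, MISSING, VALID


def make_recording(
    x,
    y=None,
    fs: float = 300.0,
    missing=None,
    binocular: bool = True,
) -> GazeRecording:
    """Build a recording from coordinate arrays; ``missing`` marks indices."""
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)

    def eye() -> EyeSignal:
        ex, ey = x.copy(), y.copy()
        status = np.full(len(x), VALID, dtype=np.uint8)
        if missing is not None:
            status[missing] = MISSING
            ex[missing] = np.nan
            ey[missing] = np.nan
        return EyeSignal(ex, ey, status)

    time = np.arange(len(x)) * 1000.0 / fs
    return GazeRecording(
        time=time, fs=fs, left=eye(), right=eye() if binocular else None
    )


@pytest.fixture
def step_recording() -> GazeRecording:
    """Two fixations separated by an instantaneous 8-degree step at sample 150."""
    x = np.zeros(300)
    x[150:] = 8.0
    return make_recording(x)
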