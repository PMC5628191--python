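"""Impute short data-loss gaps with the monotone interpolant.

Creates a smooth 1-second trace with two gaps — a 60-ms gap (eligible:
shorter than the 100-ms limit, two valid samples on each side) and a
130-ms gap (too long) — and runs gap imputation.  The report shows the
short gap filled and the long one untouched; filled samples never
overshoot the bracketing positions because the interpolant is monotone
between data points.
"""

import numpy as np

import fixclust as fc

fs = 300.0
n = 300
t = np.arange(n) * 1000.0 / fs
x = 3.0 * np.sin(t / 300.0)
status = np.zeros(n, dtype=np.uint8)
eye = fc.EyeSignal(x, np.zeros(n), status)
rec = fc.GazeRecording(time=t, fs=fs, left=eye)
for start, length in [(60, 18), (180, 39)]:  # 60 ms and 130 ms
    rec.left.status[start : start + length] = fc.MISSING
    rec.left.x[start : start + length] = np.nan
    rec.left.y[start : start + length] = np.nan

from fixclust.interpolate import gap_table

print(gap_table(rec).round(1).to_string(index=False))
out = fc.impute_gaps(rec)
filled = out.left.status == fc.INTERPOLATED
print(f"\nsamples filled: {int(filled.sum())} (the 18-sample gap only)")
print(
    f"imputed values span [{out.left.x[filled].min():.3f}, "
    f"{out.left.x[filled].max():.3f}] deg, inside the bracketing samples "
    f"[{x[59]:.3f}, {x[78]:.3f}] - no overshoot."
)
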