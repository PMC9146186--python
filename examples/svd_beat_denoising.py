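"""Rank-2 beat-matrix denoising of a periodic ECG.

Stacks R-synchronized, equal-period-interpolated beats into a matrix,
inspects the singular-value difference spectrum (its peak marks the
signal/noise boundary), truncates to rank 2 and maps back to a signal.
"""

import numpy as np

from fecgkit import build_beat_matrix, singular_spectrum, svd_estimate
from fecgkit.simulate import synth_ecg

rng = np.random.default_rng(0)
x, r, _ = synth_ecg(duration_s=30.0, hr_bpm=130.0, seed=0)
noisy = x + 0.05 * rng.standard_normal(len(x))

bm = build_beat_matrix(noisy, r, fs=1000.0)
ss = singular_spectrum(bm)
est = svd_estimate(noisy, r, k=2, fs=1000.0)

mask = est != 0
rmse_before = np.sqrt(np.mean((noisy[mask] - x[mask]) ** 2))
rmse_after = np.sqrt(np.mean((est[mask] - x[mask]) ** 2))

print(f"beat matrix      : {bm.m} beats x {bm.n} samples")
print(f"singular values  : {np.round(ss.values[:5], 2)} ...")
print(f"difference spectrum peak at index {int(np.argmax(ss.diff_spectrum))} "
      "(0-based; energy concentrates in the leading values)")
print(f"RMSE vs clean    : {rmse_before:.4f} -> {rmse_after:.4f} mV")
print("Rank-2 truncation keeps the repeating beat morphology and discards "
      "incoherent noise.")
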