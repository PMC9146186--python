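"""Blind source separation with the over-relaxed FastICA.

Mixes three known sources with a random matrix, whitens, runs the
negentropy fixed-point iteration and measures recovery quality by the best
absolute correlation per source and the Amari separation index.
"""

import numpy as np
from scipy import signal

from fecgkit import (FastICAConfig, amari_error, center_whiten,
                     fastica_overrelaxed)

N = 20000
t = np.arange(N) / 1000.0
rng = np.random.default_rng(42)
S = np.vstack([np.sin(2 * np.pi * 7 * t),
               signal.sawtooth(2 * np.pi * 5 * t),
               rng.uniform(-1, 1, N)])
S = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
A = rng.uniform(-1, 1, (3, 3))

Z, whitening, _ = center_whiten(A @ S)
res = fastica_overrelaxed(Z, FastICAConfig(overrelax_lambda=1.5, seed=0))

corr = np.abs(np.corrcoef(np.vstack([S, res.sources]))[:3, 3:]).max(axis=1)
print(f"converged        : {res.converged} after {res.n_iter} sweeps")
print(f"per-source |corr|: {np.round(corr, 4)} (1.0 = perfect recovery)")
print(f"Amari index      : {amari_error(res.unmixing @ whitening @ A):.4f} "
      "(0 = perfect separation, < 0.1 is good)")
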