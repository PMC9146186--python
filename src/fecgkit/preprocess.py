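"""Abdominal-ECG conditioning before source separation.

Three independent stages, each returning a signal of the input length:

* baseline-drift removal — subtracts a baseline estimated by two cascaded
  running-median filters (0.2 s then 0.6 s windows).  Medians pass impulsive
  QRS energy through to the residual while tracking sub-hertz drift.
* powerline notch — zero-phase second-order IIR notch at 50/60 Hz.
* pulse-artifact suppression — samples further than ``k`` MADs from the
  signal median are replaced by linear interpolation between clean neighbors.

The chain is a standard, parameter-exposed stand-in for the conditioning step
of abdominal-ECG pipelines; each stage can be disabled via its config field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .errors import DegenerateSignalError, LengthError

__all__ = ["PreprocessConfig", "remove_baseline", "notch_powerline",
           "suppress_artifacts", "preprocess"]


@dataclass
class PreprocessConfig:
    powerline_hz: float = 50.0       # mains frequency (50 or 60)
    notch_q: float = 30.0            # notch quality factor
    baseline_win1_s: float = 0.2     # first running-median window
    baseline_win2_s: float = 0.6     # second running-median window
    artifact_k: float | None = 8.0   # MAD multiples flagging artifacts;
                                     # None disables the clipping stage

    def __post_init__(self):
        if not 0 < self.baseline_win1_s < self.baseline_win2_s:
            raise ValueError("need 0 < baseline_win1_s < baseline_win2_s")
        if self.artifact_k is not None and self.artifact_k <= 0:
            raise ValueError("artifact_k must be positive (or None to disable)")


def _odd(n: int) -> int:
    return n if n % 2 else n + 1


def remove_baseline(x, fs: float, cfg: PreprocessConfig | None = None):
    """Subtract a dual running-median baseline estimate."""
    cfg = cfg or PreprocessConfig()
    x = np.asarray(x, dtype=float)
    w1 = _odd(max(3, int(round(cfg.baseline_win1_s * fs))))
    w2 = _odd(max(3, int(round(cfg.baseline_win2_s * fs))))
    if len(x) <= w2:
        raise LengthError(f"signal of {len(x)} samples shorter than the "
                          f"{w2}-sample baseline window")
    baseline = ndimage.median_filter(x, size=w1, mode="nearest")
    baseline = ndimage.median_filter(baseline, size=w2, mode="nearest")
    return x - baseline


def notch_powerline(x, fs: float, cfg: PreprocessConfig | None = None):
    """Zero-phase IIR notch at the mains frequency."""
    cfg = cfg or PreprocessConfig()
    if not fs > 2 * cfg.powerline_hz:
        raise ValueError(f"fs={fs} must exceed twice the mains frequency "
                         f"{cfg.powerline_hz}")
    x = np.asarray(x, dtype=float)
    b, a = signal.iirnotch(cfg.powerline_hz, cfg.notch_q, fs=fs)
    return signal.filtfilt(b, a, x)


def suppress_artifacts(x, fs: float, cfg: PreprocessConfig | None = None):
    """Replace samples beyond ``k``·MAD of the median by linear interpolation."""
    cfg = cfg or PreprocessConfig()
    if cfg.artifact_k is None:
        raise ValueError("artifact_k is None (stage disabled)")
    x = np.asarray(x, dtype=float)
    if len(x) < fs:
        raise LengthError("need at least one second of signal")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        mad = np.mean(np.abs(x - med))  # flat signals: fall back to mean dev
        if mad == 0:
            return x.copy()
    bad = np.abs(x - med) > cfg.artifact_k * mad
    if bad.mean() > 0.5:
        raise DegenerateSignalError(
            f"{100 * bad.mean():.0f}% of samples flagged as artifact")
    if not bad.any():
        return x.copy()
    out = x.copy()
    good = np.nonzero(~bad)[0]
    out[bad] = np.interp(np.nonzero(bad)[0], good, x[good])
    return out


def preprocess(x, fs: float, cfg: PreprocessConfig | None = None):
    """Full chain: baseline removal, artifact suppression, powerline notch."""
    cfg = cfg or PreprocessConfig()
    y = remove_baseline(x, fs, cfg)
    if cfg.artifact_k is not None:
        y = suppress_artifacts(y, fs, cfg)
    return notch_powerline(y, fs, cfg)
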