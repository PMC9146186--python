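"""Extraction- and detection-quality metrics.

Two beat-similarity SNRs computed on a matrix of time-normalized beats
(rows unit-l2-normalized internally, so both are amplitude-invariant):

* eigenvalue SNR — the leading eigenvalue of the beat Gram matrix over the
  rest: ``SNR_Eig = gamma_max / (sum(gamma) - gamma_max)``;
* cross-correlation SNR — the mean pairwise beat inner product sigma mapped
  through ``sigma / (1 - sigma)``.

Both are reported in dB (``10 log10`` of the ratio).  Identical beats give
+inf; orthogonal beats give 0 dB (eigenvalue) / -inf (cross-correlation).

Detection quality follows the usual R-peak matching scheme: greedy one-to-one
matching within a time tolerance, then Se = TP/(TP+FN), PPV = TP/(TP+FP) and
F1 = TP/(TP+FP+FN).  Note this F1 is a Jaccard-type index bounded above by
both Se and PPV — not the harmonic mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientBeatsError

__all__ = ["SNRReport", "DetectionCounts", "snr_eig", "snr_rms",
           "match_peaks", "se_ppv_f1"]


@dataclass
class SNRReport:
    snr_eig_db: float = float("nan")
    snr_rms_db: float = float("nan")
    eigenvalues: np.ndarray | None = None
    sigma: float = float("nan")
    n_beats: int = 0


@dataclass
class DetectionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    def __add__(self, other: "DetectionCounts") -> "DetectionCounts":
        return DetectionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn)


def _unit_rows(beats) -> np.ndarray:
    U = np.atleast_2d(np.asarray(beats, dtype=float))
    if U.shape[0] < 2:
        raise InsufficientBeatsError("need at least 2 beats")
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return U / norms


def _db(ratio: float) -> float:
    if ratio <= 0:
        return float("-inf")
    if np.isinf(ratio):
        return float("inf")
    return float(10.0 * np.log10(ratio))


def snr_eig(beats) -> SNRReport:
    """Eigenvalue-concentration SNR of a beat matrix (rows = beats)."""
    U = _unit_rows(beats)
    gamma = np.linalg.svd(U, compute_uv=False) ** 2
    rest = float(gamma.sum() - gamma[0])
    ratio = float("inf") if rest <= 1e-12 * gamma[0] else float(gamma[0]) / rest
    return SNRReport(snr_eig_db=_db(ratio), eigenvalues=gamma,
                     n_beats=U.shape[0])


def snr_rms(beats) -> SNRReport:
    """Mean-pairwise-correlation SNR of a beat matrix (rows = beats)."""
    U = _unit_rows(beats)
    M = U.shape[0]
    total = U.sum(axis=0)
    # sum over i<k of f(i).f(k) = (||sum f||^2 - M) / 2 for unit rows
    sigma = float((total @ total - M) / (M * (M - 1)))
    if sigma >= 1.0 - 1e-12:
        ratio = float("inf")
    elif sigma <= 0.0:
        ratio = 0.0
    else:
        ratio = sigma / (1.0 - sigma)
    return SNRReport(snr_rms_db=_db(ratio), sigma=sigma, n_beats=M)


def match_peaks(detected, reference, tol_s: float = 0.05,
                fs: float = 1000.0) -> DetectionCounts:
    """Greedy one-to-one peak matching in time order.

    A detected peak within ``tol_s`` of a still-unmatched reference peak is a
    true positive; leftover detected peaks are false positives, leftover
    reference peaks false negatives.
    """
    det = np.asarray(detected, dtype=np.int64)
    ref = np.asarray(reference, dtype=np.int64)
    for name, a in (("detected", det), ("reference", ref)):
        if np.any(np.diff(a) < 0):
            raise ValueError(f"{name} peak list is not sorted")
    tol = tol_s * fs
    i = j = tp = 0
    while i < det.size and j < ref.size:
        d = det[i] - ref[j]
        if abs(d) <= tol:
            tp += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return DetectionCounts(tp=tp, fp=int(det.size - tp), fn=int(ref.size - tp))


def se_ppv_f1(c: DetectionCounts) -> tuple[float, float, float]:
    """Sensitivity, positive predictive value and F1 as percentages.

    ``F1 = TP / (TP + FP + FN)`` — a Jaccard-type index, deliberately not the
    harmonic mean of Se and PPV.
    """
    if c.tp + c.fn == 0:
        raise ValueError("Se undefined: TP + FN = 0")
    if c.tp + c.fp == 0:
        raise ValueError("PPV undefined: TP + FP = 0")
    se = 100.0 * c.tp / (c.tp + c.fn)
    ppv = 100.0 * c.tp / (c.tp + c.fp)
    f1 = 100.0 * c.tp / (c.tp + c.fp + c.fn)
    return se, ppv, f1
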