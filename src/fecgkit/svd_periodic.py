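"""R-synchronized beat-matrix construction and rank-k SVD signal estimation.

Consecutive R-to-R segments of a single-channel ECG are linearly resampled to
a common period length n and stacked into an m x n beat matrix A.  Rows are
aligned so each begins a fixed fraction (default 0.3) of the median RR before
its R peak, which makes QRS complexes column-coherent: the periodic component
then concentrates in the leading singular values of A, and truncating to the
k largest (k = 2 by default) separates the repeating ECG from incoherent
interference.  The truncated matrix is resampled back to the original segment
lengths to yield a denoised time-domain estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientBeatsError

__all__ = ["BeatMatrix", "SingularSpectrum", "build_beat_matrix",
           "singular_spectrum", "rank_truncate", "beats_to_signal",
           "svd_estimate"]

PRE_R_FRACTION = 0.3  # row start offset before R, as a fraction of median RR


@dataclass
class BeatMatrix:
    A: np.ndarray                    # m x n equalized beats
    r_peaks: np.ndarray              # m R-peak sample indices
    seg_bounds: list[tuple[int, int]]  # half-open [start, end) per row
    n: int                           # equalized period length
    n_pre: int                       # columns before the R anchor
    fs: float
    n_samples: int                   # original signal length

    @property
    def m(self) -> int:
        return self.A.shape[0]


@dataclass
class SingularSpectrum:
    values: np.ndarray        # descending singular values
    diff_spectrum: np.ndarray  # consecutive differences (nonnegative)


def _resample_linear(seg: np.ndarray, n: int) -> np.ndarray:
    L = len(seg)
    if L == n:
        return seg.astype(float, copy=True)
    return np.interp(np.linspace(0.0, L - 1, n), np.arange(L), seg)


def _warp_row(seg: np.ndarray, split: int, n: int, n_pre: int) -> np.ndarray:
    """Resample a segment to length n, anchoring sample ``split`` at column
    ``n_pre`` (two-piece linear interpolation keeps R columns exactly
    aligned across rows despite RR variability)."""
    if n_pre <= 0 or split <= 0 or split >= len(seg):
        return _resample_linear(seg, n)
    return np.concatenate([_resample_linear(seg[:split], n_pre),
                           _resample_linear(seg[split:], n - n_pre)])


def _unwarp_row(row: np.ndarray, split: int, L: int, n_pre: int) -> np.ndarray:
    if n_pre <= 0 or split <= 0 or split >= L:
        return _resample_linear(row, L)
    return np.concatenate([_resample_linear(row[:n_pre], split),
                           _resample_linear(row[n_pre:], L - split)])


def build_beat_matrix(x, r_peaks, n_target: int | None = None,
                      fs: float = 1000.0,
                      pre_r_fraction: float = PRE_R_FRACTION) -> BeatMatrix:
    """Stack equal-period-interpolated consecutive RR segments.

    Segments run from ``r[i] - offset`` to ``r[i+1] - offset`` with
    ``offset = round(pre_r_fraction * median(RR))``; rows falling outside the
    signal are discarded.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r_peaks, dtype=np.int64)
    if r.size < 3:
        raise InsufficientBeatsError(f"need >= 3 R peaks, got {r.size}")
    rr = np.diff(r)
    if np.any(rr <= 0):
        raise ValueError("R peaks must be strictly increasing")
    if r[0] < 0 or r[-1] >= len(x):
        raise ValueError("R peaks outside the signal")
    offset = int(round(pre_r_fraction * np.median(rr)))
    starts = r - offset
    rows, bounds, kept_peaks, lengths = [], [], [], []
    for i in range(len(r) - 1):
        a, b = int(starts[i]), int(starts[i + 1])
        if a < 0 or b > len(x):
            continue  # partial first/last segment
        rows.append(x[a:b])
        bounds.append((a, b))
        kept_peaks.append(r[i])
        lengths.append(b - a)
    if len(rows) < 2:
        raise InsufficientBeatsError("fewer than 2 complete beats inside the signal")
    n = int(n_target) if n_target else int(np.median(lengths))
    n_pre = int(round(offset / np.median(lengths) * n))
    n_pre = min(max(n_pre, 0), n - 2)
    A = np.vstack([_warp_row(seg, offset, n, n_pre) for seg in rows])
    return BeatMatrix(A=A, r_peaks=np.asarray(kept_peaks), seg_bounds=bounds,
                      n=n, n_pre=n_pre, fs=fs, n_samples=len(x))


def singular_spectrum(A) -> SingularSpectrum:
    """Singular values of the beat matrix and their difference spectrum.

    A peak in the difference spectrum marks the boundary between the
    signal-bearing and noise-bearing singular values.
    """
    A = A.A if isinstance(A, BeatMatrix) else np.asarray(A, dtype=float)
    s = np.linalg.svd(A, compute_uv=False)
    return SingularSpectrum(values=s, diff_spectrum=s[:-1] - s[1:])


def rank_truncate(A, k: int) -> np.ndarray:
    """Best rank-k approximation: keep the k largest singular values."""
    A = A.A if isinstance(A, BeatMatrix) else np.asarray(A, dtype=float)
    if not 1 <= k <= min(A.shape):
        raise ValueError(f"k={k} out of range 1..{min(A.shape)}")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    s = s.copy()
    s[k:] = 0.0
    return (U * s) @ Vt


def beats_to_signal(A_prime, bm: BeatMatrix) -> np.ndarray:
    """Invert the equal-period interpolation of ``build_beat_matrix``.

    Each row is resampled back to its original segment length and written to
    its interval; samples outside every segment are zero.
    """
    A_prime = np.asarray(A_prime, dtype=float)
    if A_prime.shape != bm.A.shape:
        raise ValueError(f"shape mismatch: {A_prime.shape} vs {bm.A.shape}")
    out = np.zeros(bm.n_samples)
    for row, (a, b), r in zip(A_prime, bm.seg_bounds, bm.r_peaks):
        out[a:b] = _unwarp_row(row, int(r - a), b - a, bm.n_pre)
    return out


def svd_estimate(x, r_peaks, k: int = 2, fs: float = 1000.0,
                 n_target: int | None = None,
                 pre_r_fraction: float = PRE_R_FRACTION) -> np.ndarray:
    """Build the beat matrix, truncate to rank k, and invert."""
    bm = build_beat_matrix(x, r_peaks, n_target=n_target, fs=fs,
                           pre_r_fraction=pre_r_fraction)
    return beats_to_signal(rank_truncate(bm.A, k), bm)
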