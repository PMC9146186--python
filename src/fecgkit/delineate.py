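"""Wavelet modulus-maxima ECG delineation.

The signal is decomposed with the undecimated (a-trous) quadratic-spline
derivative filter bank of Mallat and Zhong into four scales.  Because the
wavelet is the derivative of a smoothing kernel, each wave of the ECG maps to
a pair of opposite-sign modulus maxima whose zero crossing marks the wave
peak.  R peaks are detected at scale 4 (where QRS energy dominates), with
two data-driven correction rules on the RR series: intervals shorter than
0.4x the mean RR flag a false detection (the weaker pair is dropped) and
intervals longer than 1.5x flag a missed beat (the gap is re-searched with
the threshold multiplier repeatedly halved).  Q/S peaks are the nearest
zero crossings flanking the R pair; QRS onset/offset are the flanking
modulus extrema; P and T waves are sought at scale 2 in RR-relative search
regions, with onsets shifted 3 samples right of the leading extremum and
offsets mirrored about the peak.  The ST segment runs from QRS offset to T
onset and its deviation is measured against the pre-QRS isoelectric level.

All thresholds are multiples of mean modulus-maxima magnitudes, so
delineation is invariant to positive rescaling of the input.  Detection
assumes predominantly positive R deflections; ``auto_orient`` (default on)
flips the signal when its largest deflection is negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as _sig

from .errors import InsufficientBeatsError, LengthError
from .fiducials import BeatFiducials, FiducialSet

__all__ = ["WaveletScales", "ModMaxPair", "DelineateConfig",
           "swt_quadratic_spline", "find_mod_max_pairs", "detect_r_peaks",
           "detect_qs", "detect_qrs_bounds", "detect_p_t", "delineate",
           "orient_positive"]

# Mallat-Zhong quadratic-spline bank.  The highpass is a scaled first
# difference with the sign chosen so coefficients are proportional to the
# NEGATIVE smoothed derivative: an upright peak then yields a negative
# maximum followed by a positive maximum, with the peak at the zero crossing.
_LOWPASS = np.array([0.125, 0.375, 0.375, 0.125])
_HIGHPASS = np.array([-2.0, 2.0])
_LP_DELAY = 1.5   # group delay of _LOWPASS, samples
_HP_DELAY = 0.5


@dataclass
class WaveletScales:
    """Undecimated transform coefficients, scales 1..4, plus alignment delays."""

    coeffs: np.ndarray        # (4, N)
    delays: np.ndarray        # per-scale group delay in samples (float)
    fs: float

    def aligned(self, scale: int) -> np.ndarray:
        """Scale coefficients shifted so indices line up with the signal."""
        c = self.coeffs[scale - 1]
        d = int(round(self.delays[scale - 1]))
        out = np.zeros_like(c)
        if d:
            out[:-d] = c[d:]
        else:
            out[:] = c
        return out


@dataclass
class ModMaxPair:
    """A negative/positive modulus-maximum pair bracketing one wave peak."""

    neg_idx: int
    pos_idx: int
    zero_idx: int
    scale: int
    neg_amp: float
    pos_amp: float

    @property
    def amplitude(self) -> float:
        return self.pos_amp + abs(self.neg_amp)


@dataclass
class DelineateConfig:
    r_scale: int = 4
    pt_scale: int = 2              # P/T waves are widest; strongest at scale 2
    thr_mult: float = 1.0          # multiplier on mean modulus-maxima magnitude
    pair_window_s: float = 0.1
    rr_short: float = 0.4          # RR < rr_short * mean RR => false detection
    rr_long: float = 1.5           # RR > rr_long * mean RR => missed beat
    max_passes: int = 5
    max_bisect: int = 8
    max_rate_bpm: float = 240.0    # denser rhythms trigger threshold raising
    q_window_s: float = 0.020
    s_window_s: float = 0.030
    qrs_on_window_s: float = 0.030
    qrs_off_window_s: float = 0.040
    qs_amp_frac: float = 0.05      # Q/S validity: amplitude vs R, local baseline
    fallback_half_width_s: float = 0.025
    pt_thr_mult: float = 0.25      # multiplier on region maxima means
    pt_floor_frac: float = 0.03    # absolute floor as fraction of R amplitude
    pt_pair_window_s: float = 0.12
    t_onset_shift: int = 3         # samples right of the leading extremum
    auto_orient: bool = True


# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------

def _upsample(filt: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return filt
    out = np.zeros((len(filt) - 1) * factor + 1)
    out[::factor] = filt
    return out


def swt_quadratic_spline(x, fs: float) -> WaveletScales:
    """Four-scale a-trous transform with the quadratic-spline derivative wavelet.

    Scale ``j`` coefficients approximate (minus) the derivative of the signal
    smoothed at scale ``2**j``; the recorded per-scale delays let maxima at
    different scales be compared at aligned positions.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 64:
        raise LengthError(f"need >= 64 samples, got {len(x)}")
    N = len(x)
    coeffs = np.empty((4, N))
    delays = np.empty(4)
    approx = x
    cum_delay = 0.0
    def causal_conv(a, filt):
        # causal convolution with edge-replicated history (no spurious
        # boundary response on constant signals)
        pad = np.pad(a, (len(filt) - 1, 0), mode="edge")
        return np.convolve(pad, filt, mode="valid")

    for j in range(4):
        up = 2 ** j
        g = _upsample(_HIGHPASS, up)
        h = _upsample(_LOWPASS, up)
        coeffs[j] = causal_conv(approx, g)
        delays[j] = cum_delay + _HP_DELAY * up
        approx = causal_conv(approx, h)
        cum_delay += _LP_DELAY * up
    return WaveletScales(coeffs=coeffs, delays=delays, fs=fs)


def _local_extrema(c: np.ndarray):
    """Indices of positive local maxima and negative local minima."""
    if len(c) < 3:
        return np.array([], int), np.array([], int)
    left, mid, right = c[:-2], c[1:-1], c[2:]
    pos = np.nonzero((mid > 0) & (mid >= left) & (mid > right))[0] + 1
    neg = np.nonzero((mid < 0) & (mid <= left) & (mid < right))[0] + 1
    return pos, neg


def _zero_cross(c: np.ndarray, lo: int, hi: int) -> int:
    """Leftmost sample of the negative-to-positive sign change in (lo, hi)."""
    seg = c[lo:hi + 1]
    nonneg = np.nonzero(seg >= 0)[0]
    if nonneg.size == 0:
        z = (lo + hi) // 2
    else:
        z = lo + nonneg[0] - 1
    return int(min(max(z, lo + 1), hi - 1))


def _pair_up(c: np.ndarray, pos: np.ndarray, neg: np.ndarray,
             window: int, scale: int, offset: int = 0) -> list[ModMaxPair]:
    """Greedy one-to-one pairing: nearest subsequent positive per negative."""
    cands = []
    for ni in neg:
        js = pos[(pos > ni + 1) & (pos <= ni + window)]
        for pi in js:
            cands.append((pi - ni, int(ni), int(pi)))
    cands.sort()
    used_n, used_p, pairs = set(), set(), []
    for _, ni, pi in cands:
        if ni in used_n or pi in used_p:
            continue
        used_n.add(ni)
        used_p.add(pi)
        z = _zero_cross(c, ni, pi)
        pairs.append(ModMaxPair(neg_idx=ni + offset, pos_idx=pi + offset,
                                zero_idx=z + offset, scale=scale,
                                neg_amp=float(c[ni]), pos_amp=float(c[pi])))
    pairs.sort(key=lambda p: p.zero_idx)
    return pairs


def find_mod_max_pairs(w: WaveletScales, scale: int, thr_pos: float,
                       thr_neg: float, pair_window_s: float = 0.1,
                       lo: int = 0, hi: int | None = None) -> list[ModMaxPair]:
    """Threshold the modulus maxima of one scale and pair them.

    Positive maxima above ``thr_pos`` and negative minima below ``thr_neg``
    are kept; each negative is matched to the nearest subsequent positive
    within ``pair_window_s``; unmatched extrema are dropped.  Indices are in
    delay-aligned (signal) coordinates.
    """
    if not 1 <= scale <= 4:
        raise ValueError("scale must be in 1..4")
    if not (thr_pos > 0 > thr_neg):
        raise ValueError("need thr_pos > 0 > thr_neg")
    c = w.aligned(scale)
    hi = len(c) if hi is None else hi
    seg = c[lo:hi]
    pos, neg = _local_extrema(seg)
    pos = pos[seg[pos] >= thr_pos]
    neg = neg[seg[neg] <= thr_neg]
    window = max(2, int(round(pair_window_s * w.fs)))
    return _pair_up(seg, pos, neg, window, scale, offset=lo)


# ---------------------------------------------------------------------------
# R detection
# ---------------------------------------------------------------------------

def orient_positive(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Flip the signal when its dominant deflection is negative.

    Returns ``(oriented, sign)`` with ``sign`` in {+1, -1}.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    sign = 1.0 if (x.max() - med) >= (med - x.min()) else -1.0
    return sign * x, sign


def _r_pairs(x, fs, cfg: DelineateConfig, w: WaveletScales | None = None):
    """Internal: full R detection, returning the retained scale-4 pairs."""
    if w is None:
        w = swt_quadratic_spline(x, fs)
    c = w.aligned(cfg.r_scale)
    pos_all, neg_all = _local_extrema(c)
    if pos_all.size == 0 or neg_all.size == 0:
        warnings.warn("no modulus maxima found; returning no beats",
                      RuntimeWarning)
        return [], w
    mean_pos = float(np.mean(c[pos_all]))
    mean_neg = float(np.mean(-c[neg_all]))
    window = max(2, int(round(cfg.pair_window_s * fs)))

    def detect(mult, lo=0, hi=None):
        hi_ = len(c) if hi is None else hi
        seg = c[lo:hi_]
        pos = pos_all[(pos_all >= lo) & (pos_all < hi_)] - lo
        neg = neg_all[(neg_all >= lo) & (neg_all < hi_)] - lo
        pos = pos[seg[pos] >= mult * mean_pos]
        neg = neg[seg[neg] <= -mult * mean_neg]
        return _pair_up(seg, pos, neg, window, cfg.r_scale, offset=lo)

    pairs = detect(cfg.thr_mult)

    # Too-dense detections mean the mean-of-maxima threshold sits inside the
    # noise floor; raise the multiplier by bisection rounds until the implied
    # rhythm is physiologically plausible (false-detection correction).
    mult_up = cfg.thr_mult
    for _ in range(cfg.max_bisect):
        if len(pairs) < 3:
            break
        rr = np.diff([p.zero_idx for p in pairs])
        rbar = float(np.mean(rr))
        frac_short = float(np.mean(rr < cfg.rr_short * rbar))
        if rbar >= 60.0 * fs / cfg.max_rate_bpm and frac_short <= 0.2:
            break
        mult_up *= 2.0
        new_pairs = detect(mult_up)
        if len(new_pairs) < 3:
            break
        pairs = new_pairs

    if not pairs:
        # relax the threshold before giving up entirely
        mult = cfg.thr_mult
        for _ in range(cfg.max_bisect):
            mult /= 2.0
            pairs = detect(mult)
            if pairs:
                break
        if not pairs:
            warnings.warn("no modulus-maxima pairs above threshold after "
                          "full relaxation", RuntimeWarning)
            return [], w

    for _ in range(cfg.max_passes):
        changed = False
        if len(pairs) >= 3:
            r = np.array([p.zero_idx for p in pairs])
            rr = np.diff(r)
            rbar = float(rr.mean())
            short = np.nonzero(rr < cfg.rr_short * rbar)[0]
            if short.size:
                j = int(short[0])
                drop = j if pairs[j].amplitude < pairs[j + 1].amplitude else j + 1
                del pairs[drop]
                changed = True
            else:
                margin = int(0.25 * rbar)
                for j in np.nonzero(rr > cfg.rr_long * rbar)[0]:
                    a, b = int(r[j]) + margin, int(r[j + 1]) - margin
                    if b - a < window:
                        continue
                    mult, found = cfg.thr_mult, []
                    for _ in range(cfg.max_bisect):
                        mult /= 2.0
                        found = detect(mult, lo=a, hi=b)
                        if found:
                            break
                    if found:
                        pairs.extend(found)
                        pairs.sort(key=lambda p: p.zero_idx)
                        changed = True
                        break
        if not changed:
            break

    # enforce strictly increasing, unique zero crossings
    out, last = [], -1
    for p in sorted(pairs, key=lambda p: p.zero_idx):
        if p.zero_idx > last:
            out.append(p)
            last = p.zero_idx
    return out, w


def detect_r_peaks(x, fs: float, cfg: DelineateConfig | None = None) -> np.ndarray:
    """Detect R peaks via scale-4 modulus-maxima pairs with RR correction rules."""
    cfg = cfg or DelineateConfig()
    x = np.asarray(x, dtype=float)
    if len(x) < 2 * fs:
        raise LengthError("need at least 2 s of signal")
    pairs, _ = _r_pairs(x, fs, cfg)
    return np.array([p.zero_idx for p in pairs], dtype=np.int64)


# ---------------------------------------------------------------------------
# Q/S, QRS bounds
# ---------------------------------------------------------------------------

def _scan_zero_cross(c, start, stop, step):
    """First sign change scanning from start toward stop; None if absent."""
    i = start
    while i != stop:
        j = i + step
        if c[i] == 0 or (c[i] < 0) != (c[j] < 0):
            return i if step > 0 else j
        i = j
    return None


def detect_qs(x, w: WaveletScales, pairs: list[ModMaxPair], fs: float,
              cfg: DelineateConfig | None = None):
    """Q and S peaks: nearest zero crossings flanking each R pair.

    Waves whose amplitude (relative to the local baseline) is below
    ``qs_amp_frac`` of the R amplitude are reported absent.
    """
    cfg = cfg or DelineateConfig()
    c = w.aligned(cfg.r_scale)
    x = np.asarray(x, dtype=float)
    N = len(x)
    qw = int(round(cfg.q_window_s * fs))
    sw = int(round(cfg.s_window_s * fs))
    half = int(round(0.25 * fs))
    out = []
    for p in pairs:
        r = p.zero_idx
        base = float(np.median(x[max(0, r - half):min(N, r + half)]))
        r_amp = abs(x[r] - base)
        lo = max(0, p.neg_idx - qw)
        q = None
        if p.neg_idx - 1 > lo:
            j = _scan_zero_cross(c, p.neg_idx - 1, lo, -1)
            if j is not None:
                q = int(j)
        hi = min(N - 1, p.pos_idx + sw)
        s = None
        if p.pos_idx + 1 < hi:
            j = _scan_zero_cross(c, p.pos_idx + 1, hi, +1)
            if j is not None:
                s = int(j)
        if q is not None and abs(x[q] - base) < cfg.qs_amp_frac * r_amp:
            q = None
        if s is not None and abs(x[s] - base) < cfg.qs_amp_frac * r_amp:
            s = None
        if q is not None and q >= r:
            q = None
        if s is not None and s <= r:
            s = None
        out.append((q, s))
    return out


def detect_qrs_bounds(w: WaveletScales, qs, pairs: list[ModMaxPair], fs: float,
                      cfg: DelineateConfig | None = None):
    """QRS onset/offset from flanking scale-4 modulus extrema.

    Onset: nearest extremum in the window left of Q; offset: last extremum in
    the window right of S.  Beats without Q or S fall back to R -/+ 25 ms and
    are flagged.
    """
    cfg = cfg or DelineateConfig()
    c = w.aligned(cfg.r_scale)
    onw = int(round(cfg.qrs_on_window_s * fs))
    offw = int(round(cfg.qrs_off_window_s * fs))
    fb = int(round(cfg.fallback_half_width_s * fs))
    pos_all, neg_all = _local_extrema(c)
    ext = np.sort(np.concatenate([pos_all, neg_all]))
    out = []
    for p, (q, s) in zip(pairs, qs):
        floor = 0.01 * p.amplitude  # ignore numerically flat ripples
        if q is None or s is None:
            out.append((max(0, p.zero_idx - fb),
                        min(len(c) - 1, p.zero_idx + fb), True))
            continue
        cand = ext[(ext >= q - onw) & (ext < q)]
        cand = cand[np.abs(c[cand]) >= floor]
        on = int(cand[-1]) if cand.size else max(0, p.zero_idx - fb)
        cand2 = ext[(ext > s) & (ext <= s + offw)]
        cand2 = cand2[np.abs(c[cand2]) >= floor]
        off = int(cand2[-1]) if cand2.size else min(len(c) - 1, p.zero_idx + fb)
        fallback = not (cand.size and cand2.size)
        out.append((on, off, fallback))
    return out


# ---------------------------------------------------------------------------
# P and T waves
# ---------------------------------------------------------------------------

def detect_p_t(x, w: WaveletScales, pairs: list[ModMaxPair], fs: float,
               cfg: DelineateConfig | None = None):
    """P and T fiducials from scale-2 modulus-maxima pairs.

    T search region: first half of the RR interval right of the R pair's
    trailing maximum; P region: last third of the RR interval left of the
    leading maximum.  Thresholds are ``pt_thr_mult`` times the mean maxima
    magnitude inside the region, floored at ``pt_floor_frac`` of the beat's
    scale-2 R amplitude (so a truly absent wave stays absent).  Onset =
    leading extremum + 3 samples; offset mirrored about the peak.
    """
    cfg = cfg or DelineateConfig()
    c = w.aligned(cfg.pt_scale)
    N = len(c)
    r = np.array([p.zero_idx for p in pairs])
    rr = np.diff(r)
    rbar = float(rr.mean()) if rr.size else 0.5 * fs
    window = max(2, int(round(cfg.pt_pair_window_s * fs)))
    # per-beat scale-2 R amplitude, for the absolute floor
    r_amp2 = []
    for p in pairs:
        seg = np.abs(c[max(0, p.zero_idx - int(0.02 * fs)):
                       min(N, p.zero_idx + int(0.02 * fs))])
        r_amp2.append(seg.max() if seg.size else 0.0)

    def best_pair(lo, hi):
        lo, hi = max(0, int(lo)), min(N, int(hi))
        if hi - lo < 4:
            return None
        seg = c[lo:hi]
        pos, neg = _local_extrema(seg)
        if not pos.size or not neg.size:
            return None
        return seg, pos, neg, lo

    def threshold_and_pair(region, floor):
        if region is None:
            return []
        seg, pos, neg, lo = region
        thr_p = max(cfg.pt_thr_mult * float(np.mean(seg[pos])), floor)
        thr_n = max(cfg.pt_thr_mult * float(np.mean(-seg[neg])), floor)
        pos = pos[seg[pos] >= thr_p]
        neg = neg[seg[neg] <= -thr_n]
        return _pair_up(seg, pos, neg, window, cfg.pt_scale, offset=lo)

    out = []
    for i, p in enumerate(pairs):
        rr_next = rr[i] if i < len(rr) else rbar
        rr_prev = rr[i - 1] if i > 0 else rbar
        floor = cfg.pt_floor_frac * r_amp2[i]
        t_pairs = threshold_and_pair(
            best_pair(p.pos_idx + 1, p.pos_idx + rr_next / 2), floor)
        p_pairs = threshold_and_pair(
            best_pair(p.neg_idx - rr_prev / 3, p.neg_idx - 1), floor)
        beat = {}
        if t_pairs:
            tp = max(t_pairs, key=lambda q: q.amplitude)
            t_on = min(tp.neg_idx, tp.pos_idx) + cfg.t_onset_shift
            t_peak = tp.zero_idx
            if t_on < t_peak:
                beat.update(T_on=int(t_on), T_peak=int(t_peak),
                            T_off=int(min(N - 1, 2 * t_peak - t_on)))
        if p_pairs:
            pp = max(p_pairs, key=lambda q: q.amplitude)
            p_on = min(pp.neg_idx, pp.pos_idx) + cfg.t_onset_shift
            p_peak = pp.zero_idx
            if p_on < p_peak:
                beat.update(P_on=int(p_on), P_peak=int(p_peak),
                            P_off=int(min(N - 1, 2 * p_peak - p_on)))
        out.append(beat)
    return out


# ---------------------------------------------------------------------------
# full delineation
# ---------------------------------------------------------------------------

def _resample_to(x, fs, fs_target=1000.0):
    frac = Fraction(fs_target / fs).limit_denominator(1000)
    return _sig.resample_poly(x, frac.numerator, frac.denominator)


def delineate(x, fs: float, cfg: DelineateConfig | None = None) -> FiducialSet:
    """Full single-channel delineation: R, Q, S, QRS bounds, P, T, ST.

    Inputs not sampled at 1000 Hz are resampled internally so all
    millisecond windows map to fixed sample counts; returned indices are in
    the original sampling grid.
    """
    cfg = cfg or DelineateConfig()
    x = np.asarray(x, dtype=float)
    fs_orig = fs
    if abs(fs - 1000.0) > 1e-9:
        x = _resample_to(x, fs)
        fs = 1000.0
    if cfg.auto_orient:
        x, _ = orient_positive(x)
    pairs, w = _r_pairs(x, fs, cfg)
    if len(pairs) < 2:
        raise InsufficientBeatsError(
            f"found {len(pairs)} R peaks; delineation needs >= 2")
    qs = detect_qs(x, w, pairs, fs, cfg)
    bounds = detect_qrs_bounds(w, qs, pairs, fs, cfg)
    pt = detect_p_t(x, w, pairs, fs, cfg)
    iso_a, iso_b = int(0.030 * fs), int(0.010 * fs)  # 20 ms ending 10 ms pre-QRS

    beats, durations = [], []
    for p, (q, s), (on, off, fb), waves in zip(pairs, qs, bounds, pt):
        b = BeatFiducials(R=int(p.zero_idx), Q=q, S=s,
                          QRS_on=int(on), QRS_off=int(off), qrs_fallback=fb)
        for k, v in waves.items():
            setattr(b, k, v)
        # ordering repair: optional waves must not contradict the QRS
        if b.P_off is not None and b.P_off > b.QRS_on:
            b.P_on = b.P_peak = b.P_off = None
        if b.T_on is not None and b.T_on <= b.QRS_off:
            b.T_on = b.T_peak = b.T_off = None
        b.ST_start = b.QRS_off
        b.ST_end = b.T_on
        if b.ST_end is not None and b.ST_end > b.ST_start:
            lo = max(0, b.QRS_on - iso_a)
            hi = max(lo + 1, b.QRS_on - iso_b)
            iso = float(np.mean(x[lo:hi]))
            b.st_deviation_mv = float(np.mean(x[b.ST_start:b.ST_end]) - iso)
        durations.append((off - on) / fs)
        beats.append(b)

    scale = fs_orig / fs
    if abs(scale - 1.0) > 1e-12:
        for b in beats:
            for name in ("R", "Q", "S", "QRS_on", "QRS_off", "P_on", "P_peak",
                         "P_off", "T_on", "T_peak", "T_off", "ST_start",
                         "ST_end"):
                v = getattr(b, name)
                if v is not None:
                    setattr(b, name, int(round(v * scale)))
    r = np.array([b.R for b in beats])
    rr_mean = float(np.mean(np.diff(r))) / fs_orig if len(r) > 1 else None
    return FiducialSet(beats=beats, fs=fs_orig, rr_mean_s=rr_mean,
                       qrs_durations_s=durations)
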