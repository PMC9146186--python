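"""Record and annotation I/O.

Reads multichannel ECG records from WFDB (PhysioNet) headers with format-16 or
format-212 single-segment signal files, or from plain CSV (one column per
channel, optional leading ``time`` column in seconds).  Writes and re-reads
fiducial tables as CSV.

Only the WFDB subset actually used by 1 kHz abdominal-ECG databases is
implemented: single-segment records, formats 16 and 212, with optional
MIT-format beat annotations (used as reference R-peak positions).
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, UnsupportedFormatError
from .fiducials import FIDUCIAL_COLUMNS, BeatFiducials, FiducialSet

__all__ = [
    "ECGRecord",
    "read_wfdb",
    "read_wfdb_annotation",
    "read_csv",
    "write_csv",
    "write_fiducials",
    "read_fiducials",
]


@dataclass
class ECGRecord:
    """Multichannel sampled ECG.

    Attributes
    ----------
    data : (C, N) float array
        Amplitudes in mV (or the physical unit declared by the source file).
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    ref_fetal_r, ref_maternal_r : int arrays or None
        Optional reference R-peak sample positions (sorted, 0-based).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    ref_fetal_r: np.ndarray | None = None
    ref_maternal_r: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] < 1 or self.data.shape[1] < 2:
            raise ValueError("ECGRecord needs C >= 1 channels and N >= 2 samples")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel count")
        for name in ("ref_fetal_r", "ref_maternal_r"):
            idx = getattr(self, name)
            if idx is None:
                continue
            idx = np.asarray(idx, dtype=np.int64)
            if idx.size and (idx.min() < 0 or idx.max() >= self.data.shape[1]):
                raise ValueError(f"{name} indices out of range [0, N)")
            if np.any(np.diff(idx) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            setattr(self, name, idx)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# WFDB
# ---------------------------------------------------------------------------

_ANNOTATION_EXTS = ("fqrs", "qrs", "atr", "ari")


def _parse_header(path: str):
    try:
        with open(path, "r") as fh:
            lines = [ln.strip() for ln in fh
                     if ln.strip() and not ln.startswith("#")]
    except OSError as exc:
        raise FormatError(f"cannot read WFDB header {path!r}: {exc}") from exc
    if not lines:
        raise FormatError(f"empty WFDB header {path!r}")
    head = lines[0].split()
    if len(head) < 2:
        raise FormatError(f"malformed WFDB record line in {path!r}: {lines[0]!r}")
    record_name = head[0].split("/")[0]
    if "/" in head[0]:
        raise UnsupportedFormatError(
            f"multi-segment WFDB record {path!r} is not supported")
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    # fs field may carry counter freq as "fs/cfreq(base)"
    if len(head) > 2 and "/" in head[2]:
        fs = float(head[2].split("/")[0])
    n_samp = int(head[3]) if len(head) > 3 else 0
    signals = []
    for ln in lines[1:1 + n_sig]:
        parts = ln.split()
        if len(parts) < 2:
            raise FormatError(f"malformed signal line in {path!r}: {ln!r}")
        fname, fmt = parts[0], parts[1]
        gain, baseline, adc_zero = 200.0, None, 0
        if len(parts) > 2:
            gspec = parts[2]
            unit = None
            if "/" in gspec:
                gspec, unit = gspec.split("/", 1)
            if "(" in gspec:
                gpart, bpart = gspec.split("(")
                baseline = int(bpart.rstrip(")"))
                gspec = gpart
            gain = float(gspec) if gspec else 200.0
            if gain == 0:
                gain = 200.0
        if len(parts) > 4:
            adc_zero = int(parts[4])
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(parts[8:]) if len(parts) > 8 else fname
        signals.append(dict(file=fname, fmt=fmt, gain=gain,
                            baseline=baseline, desc=desc))
    if len(signals) != n_sig:
        raise FormatError(f"header {path!r} declares {n_sig} signals, "
                          f"found {len(signals)} signal lines")
    return record_name, fs, n_samp, signals


def _read_dat(path: str, fmt: str, n_sig: int, n_samp: int) -> np.ndarray:
    try:
        raw = open(path, "rb").read()
    except OSError as exc:
        raise FormatError(f"cannot read WFDB signal file {path!r}: {exc}") from exc
    if fmt.split("x")[0].split(":")[0].split("+")[0] not in ("16", "212"):
        raise UnsupportedFormatError(f"WFDB storage format {fmt!r} not supported "
                                     "(only 16 and 212)")
    base_fmt = fmt.split("x")[0].split(":")[0].split("+")[0]
    if base_fmt == "16":
        vals = np.frombuffer(raw, dtype="<i2").astype(np.int64)
    else:  # 212: two 12-bit samples packed into 3 bytes
        usable = len(raw) - len(raw) % 3
        b = np.frombuffer(raw[:usable], dtype=np.uint8).reshape(-1, 3).astype(np.int64)
        first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        vals = np.empty(2 * len(b), dtype=np.int64)
        vals[0::2], vals[1::2] = first, second
    frames = len(vals) // n_sig
    if n_samp and frames < n_samp:
        raise FormatError(f"signal file {path!r} shorter than header declares")
    if n_samp:
        frames = n_samp
    return vals[: frames * n_sig].reshape(frames, n_sig).T


def read_wfdb_annotation(path: str) -> np.ndarray:
    """Read beat sample positions from a MIT-format annotation file.

    Returns the sorted sample indices of every annotation atom whose type code
    is a beat code (1..49); aux/meta pseudo-annotations are skipped.
    """
    try:
        raw = open(path, "rb").read()
    except OSError as exc:
        raise FormatError(f"cannot read annotation file {path!r}: {exc}") from exc
    samples, t, i = [], 0, 0
    while i + 1 < len(raw):
        low, high = raw[i], raw[i + 1]
        i += 2
        code = high >> 2
        interval = ((high & 0x03) << 8) | low
        if code == 0 and interval == 0:  # EOF
            break
        if code == 59:  # SKIP: next 4 bytes hold a long interval
            if i + 3 >= len(raw):
                raise FormatError(f"truncated SKIP atom in {path!r}")
            t += struct.unpack("<i", bytes([raw[i + 2], raw[i + 3],
                                            raw[i], raw[i + 1]]))[0]
            i += 4
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN modifiers
            continue
        if code == 63:  # AUX: interval = byte count (padded to even)
            i += interval + (interval & 1)
            continue
        t += interval
        if 1 <= code <= 49:
            samples.append(t)
    return np.asarray(sorted(samples), dtype=np.int64)


def read_wfdb(path: str, annotation: str | None = None) -> ECGRecord:
    """Read a single-segment WFDB record (formats 16/212).

    Parameters
    ----------
    path : str
        Path to the ``.hea`` header (extension optional).
    annotation : str, optional
        Annotation extension holding reference fetal R peaks.  When omitted,
        the first of ``.fqrs/.qrs/.atr/.ari`` found next to the record is used.
    """
    if path.endswith(".hea"):
        path = path[:-4]
    hea = path + ".hea"
    if not os.path.exists(hea):
        raise FormatError(f"WFDB header not found: {hea!r}")
    record_name, fs, n_samp, signals = _parse_header(hea)
    dirname = os.path.dirname(path) or "."
    by_file: dict[str, list[int]] = {}
    for k, sig in enumerate(signals):
        by_file.setdefault(sig["file"], []).append(k)
    data = np.empty((len(signals), 0))
    cols = {}
    for fname, idxs in by_file.items():
        fmts = {signals[k]["fmt"] for k in idxs}
        if len(fmts) > 1:
            raise UnsupportedFormatError(
                f"mixed storage formats within one signal file {fname!r}")
        adc = _read_dat(os.path.join(dirname, fname), fmts.pop(), len(idxs), n_samp)
        for row, k in enumerate(idxs):
            cols[k] = (adc[row] - signals[k]["baseline"]) / signals[k]["gain"]
    n = min(len(v) for v in cols.values())
    data = np.vstack([cols[k][:n] for k in range(len(signals))])
    ref = None
    exts = (annotation,) if annotation else _ANNOTATION_EXTS
    for ext in exts:
        apath = os.path.join(dirname, f"{record_name}.{ext}")
        if os.path.exists(apath):
            ref = read_wfdb_annotation(apath)
            ref = ref[(ref >= 0) & (ref < n)]
            break
    return ECGRecord(data=data, fs=fs,
                     channel_names=[s["desc"] for s in signals],
                     ref_fetal_r=ref if ref is not None and ref.size else None)


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def read_csv(path, fs: float | None = None) -> ECGRecord:
    """Read a CSV record: header row, one column per channel.

    A first column named ``time`` (case-insensitive, seconds) is used to infer
    the sampling rate when ``fs`` is not given.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse CSV {path!r}: {exc}") from exc
    if df.shape[1] < 1 or df.shape[0] < 2:
        raise FormatError(f"CSV {path!r} needs a header and >= 2 data rows")
    cols = list(df.columns)
    time = None
    if cols[0].strip().lower() == "time":
        time = df[cols[0]].to_numpy()
        cols = cols[1:]
    channels = []
    for c in cols:
        col = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        bad = np.nonzero(~np.isfinite(col))[0]
        if bad.size:
            raise FormatError(
                f"non-numeric or missing cell in CSV {path!r} at row "
                f"{bad[0] + 2}, column {c!r}")
        channels.append(col)
    if fs is None:
        if time is None:
            raise ValueError("fs not given and no 'time' column to infer it from")
        dt = np.diff(np.asarray(time, dtype=float))
        if not np.all(dt > 0):
            raise FormatError(f"time column in {path!r} is not increasing")
        fs = 1.0 / float(np.median(dt))
    return ECGRecord(data=np.vstack(channels), fs=float(fs),
                     channel_names=[str(c) for c in cols])


def write_csv(record: ECGRecord, path, time_column: bool = True) -> None:
    """Write a record as CSV (inverse of :func:`read_csv`)."""
    data = {}
    if time_column:
        data["time"] = np.arange(record.n_samples) / record.fs
    for name, row in zip(record.channel_names, record.data):
        data[name] = row
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Fiducial tables
# ---------------------------------------------------------------------------

def write_fiducials(fid: FiducialSet, path) -> None:
    """Write one CSV row per beat; empty cell = undetected wave."""
    rows = []
    for i, beat in enumerate(fid.beats):
        row = {"beat": i}
        row.update(beat.as_dict())
        rows.append(row)
    df = pd.DataFrame(rows, columns=["beat", *FIDUCIAL_COLUMNS])
    df.to_csv(path, index=False)


def read_fiducials(path, fs: float = 1000.0) -> FiducialSet:
    """Read a fiducial CSV written by :func:`write_fiducials`."""
    df = pd.read_csv(path)
    beats = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in FIDUCIAL_COLUMNS:
            v = row.get(col)
            kwargs[col] = None if pd.isna(v) else int(v)
        beats.append(BeatFiducials(**kwargs))
    return FiducialSet(beats=beats, fs=fs)
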