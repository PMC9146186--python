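"""Per-beat fiducial containers shared by the delineator and the I/O layer.

All indices are 0-based sample positions in the signal the delineator ran on.
A ``None`` entry means the corresponding wave was not detected for that beat
(absent waves are a normal outcome, not an error).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

# column order used in the fiducial CSV and in reports
FIDUCIAL_COLUMNS = (
    "P_on", "P_peak", "P_off", "Q", "QRS_on", "R", "S", "QRS_off",
    "T_on", "T_peak", "T_off", "ST_start", "ST_end",
)

# required ordering inside one beat (checked where both entries are present)
_ORDER = (
    "P_on", "P_peak", "P_off", "QRS_on", "Q", "R", "S", "QRS_off",
    "ST_start", "ST_end", "T_on", "T_peak", "T_off",
)


@dataclass
class BeatFiducials:
    """Fiducial sample indices for a single beat; ``None`` = undetected."""

    R: int | None = None
    Q: int | None = None
    S: int | None = None
    QRS_on: int | None = None
    QRS_off: int | None = None
    P_on: int | None = None
    P_peak: int | None = None
    P_off: int | None = None
    T_on: int | None = None
    T_peak: int | None = None
    T_off: int | None = None
    ST_start: int | None = None
    ST_end: int | None = None
    qrs_fallback: bool = False
    st_deviation_mv: float | None = None

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FIDUCIAL_COLUMNS}

    def ordering_ok(self) -> bool:
        """True when every pair of present indices respects the clinical order.

        Expected order: P_on <= P_peak <= P_off <= QRS_on <= Q <= R <= S <=
        QRS_off = ST_start <= ST_end = T_on <= T_peak <= T_off.
        """
        seq = [getattr(self, n) for n in _ORDER]
        present = [v for v in seq if v is not None]
        return all(a <= b for a, b in zip(present, present[1:]))


@dataclass
class FiducialSet:
    """Delineation result: one :class:`BeatFiducials` per detected beat."""

    beats: list[BeatFiducials] = field(default_factory=list)
    fs: float = 1000.0
    rr_mean_s: float | None = None
    qrs_durations_s: list[float | None] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.beats)

    @property
    def r_peaks(self) -> list[int]:
        return [b.R for b in self.beats if b.R is not None]

    def ordering_ok(self) -> bool:
        r = self.r_peaks
        strictly_increasing = all(a < b for a, b in zip(r, r[1:]))
        return strictly_increasing and all(b.ordering_ok() for b in self.beats)
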