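"""Delineate a clean fetal ECG with the wavelet modulus-maxima method.

Generates 30 s of noise-free fetal ECG with analytically known fiducials,
runs the four-scale quadratic-spline delineator and reports how well the
detected QRS durations and T peaks agree with the construction.
"""

import numpy as np

from fecgkit import delineate
from fecgkit.simulate import synth_ecg

x, r_true, truths = synth_ecg(duration_s=30.0, hr_bpm=130.0, seed=0)
fid = delineate(x, 1000.0)

durs = np.asarray(fid.qrs_durations_s)
t_err = [b.T_peak - t["T_peak"]
         for b, t in zip(fid.beats, truths) if b.T_peak is not None]
st = [b.st_deviation_mv for b in fid.beats if b.st_deviation_mv is not None]

print(f"beats detected   : {len(fid)} (true {len(r_true)})")
print(f"mean RR          : {fid.rr_mean_s * 1000:.1f} ms "
      f"-> {60 / fid.rr_mean_s:.1f} bpm")
print(f"QRS duration     : {durs.mean() * 1000:.1f} ms "
      f"(constructed {truths[0]['qrs_duration_s'] * 1000:.0f} ms)")
print(f"T-peak error     : max |err| {np.abs(t_err).max():.0f} samples")
print(f"ST deviation     : median {np.median(st) * 1000:.1f} uV "
      "(isoelectric by construction; the small positive bias is the "
      "T-wave onset tail inside the measured window)")
print(f"ordering invariant holds: {fid.ordering_ok()}")
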