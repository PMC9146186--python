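"""Detection metrics: Se, PPV and the count-ratio F1.

Evaluates R-peak detections against a reference with greedy one-to-one
matching, then shows the closed-form metrics on a published set of counts.
"""

from fecgkit import DetectionCounts, match_peaks, se_ppv_f1

# matching demo: one hit at +4 ms, one at -10 ms, one reference missed
counts = match_peaks([104, 1090], [100, 600, 1100], tol_s=0.05, fs=1000.0)
print(f"matching: TP={counts.tp} FP={counts.fp} FN={counts.fn}")

# published counts for one 5-minute abdominal record (627 correct,
# 17 missed, 2 spurious detections)
se, ppv, f1 = se_ppv_f1(DetectionCounts(tp=627, fp=2, fn=17))
print(f"Se  = {se:.2f}%   (fraction of true beats found)")
print(f"PPV = {ppv:.2f}%   (fraction of detections that are real)")
print(f"F1  = {f1:.2f}%   (TP/(TP+FP+FN), bounded by both)")
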