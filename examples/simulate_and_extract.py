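"""Simulate a 4-channel abdominal recording and extract the fetal ECG.

Builds 30 s of synthetic maternal+fetal mixture (maternal 80 bpm, fetal
130 bpm, fetal R amplitude 25% of maternal, baseline/powerline/white noise),
runs the hybrid FastICA+SVD pipeline, and compares the detected fetal R
peaks against the simulator's ground truth.
"""

from fecgkit import (ExtractConfig, SynthConfig, extract_fecg, match_peaks,
                     se_ppv_f1, synth_abdominal)

sr = synth_abdominal(SynthConfig(duration_s=30.0, seed=0))
res = extract_fecg(sr.record, ExtractConfig(seed=0))

counts = match_peaks(res.fetal_r, sr.true_fetal_r, tol_s=0.02, fs=1000.0)
se, ppv, f1 = se_ppv_f1(counts)

print(f"component labels : {res.component_labels}")
print(f"best channel     : {res.best_channel}")
print(f"fetal HR         : {res.params['fetal_hr_bpm']:.2f} bpm "
      f"(simulated 130)")
print(f"maternal HR      : {res.params['maternal_hr_bpm']:.2f} bpm "
      f"(simulated 80)")
print(f"fetal R: Se {se:.1f}%  PPV {ppv:.1f}%  at +/-20 ms")
print(f"SNR_RMS hybrid   : {res.snr_report.snr_rms_db:.2f} dB")
print(f"SNR_RMS SVD-only : {res.snr_report_svd_only.snr_rms_db:.2f} dB")
print("Higher hybrid SNR means the ICA-reference residualization removed "
      "interference the beat-matrix step alone left behind.")
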