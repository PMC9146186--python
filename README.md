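# fecgkit

Non-invasive fetal electrocardiography records a mixture of the maternal ECG
(MECG), the much weaker fetal ECG (FECG, roughly 10–30% of the maternal R
amplitude), baseline drift, powerline interference and broadband noise on
electrodes placed on the maternal abdomen. `fecgkit` extracts the fetal
signal from such multichannel recordings and delineates its waves, for
researchers and engineers working on fetal monitoring algorithms.

Three ideas do the work:

* **Negentropy FastICA with an over-relaxed Newton step.** After de-meaning
  and whitening the channels, the symmetric fixed-point iteration
  `w⁺ = E[z g(wᵀz)] − E[g′(wᵀz)] w` (logcosh contrast by default) is
  over-relaxed between consecutive orthonormal iterates,
  `W ← decorr(W + λ(W_next − W))`, λ = 1.5 by default. The recovered
  components are labelled maternal / fetal / noise by the dominant beat rate
  of their autocorrelation and serve as interference references.
* **R-synchronized rank-2 SVD beat-matrix denoising.** Consecutive R-to-R
  segments, each starting 0.3 × median RR before its R peak, are
  equal-period-interpolated to a common length and stacked into an m×n
  matrix `A = U Σ Vᵀ`. The repeating beat concentrates in the two largest
  singular values; zeroing the rest and inverting the interpolation yields a
  denoised beat train. The hybrid pipeline cancels the maternal beats this
  way, detects fetal R peaks on the residue, rank-2-denoises the fetal beat
  train, and finally removes what the ICA references can still explain by
  least squares.
* **Quadratic-spline wavelet modulus-maxima delineation.** An undecimated
  four-scale transform with the Mallat–Zhong derivative wavelet turns every
  wave into a pair of opposite-sign modulus maxima whose zero crossing marks
  the peak. R peaks are read at scale 4 with data-relative thresholds and
  RR-based correction rules (intervals < 0.4·RR̄ flag false detections,
  > 1.5·RR̄ trigger a gap re-search with bisected thresholds); Q, S, QRS
  onset/offset, P, T and the ST segment follow from windowed zero-crossing
  and extremum searches.

Extraction quality is scored by two beat-similarity SNRs computed on the
unit-normalized beat matrix: `SNR_Eig = γ_max / (Σγ − γ_max)` from the Gram
eigenvalues, and `SNR_RMS = σ/(1−σ)` with σ the mean pairwise beat inner
product, both in dB. Detection quality uses Se = TP/(TP+FN),
PPV = TP/(TP+FP) and F1 = TP/(TP+FP+FN) (a count ratio bounded by both, not
the harmonic mean).

A seeded simulator (`fecgkit.simulate`) builds abdominal records as linear
mixtures of sum-of-Gaussians maternal (80 bpm) and fetal (130 bpm) beat
trains plus drift, mains and white noise — with analytic ground truth for
every fiducial — so the whole pipeline is testable without downloading any
database. WFDB (format 16/212 + MIT annotations) and CSV records are read
via `fecgkit.io`.

## Worked example

```bash
python examples/simulate_and_extract.py
```

```
component labels : ['noise', 'noise', 'fetal', 'maternal']
best channel     : 2
fetal HR         : 129.49 bpm (simulated 130)
maternal HR      : 80.17 bpm (simulated 80)
fetal R: Se 98.4%  PPV 98.4%  at +/-20 ms
SNR_RMS hybrid   : 11.67 dB
SNR_RMS SVD-only : 2.30 dB
```

The pipeline identifies one maternal and one fetal source among the four
ICA components, recovers both heart rates to within a beat per minute, finds
over 98% of the true fetal R peaks with over 98% precision, and improves the
beat-similarity SNR by ~9 dB over rank-2 SVD denoising alone — the gain
contributed by the ICA-reference residualization. The other scripts in
`examples/` demonstrate delineation, beat-matrix denoising, FastICA source
recovery and the detection metrics in isolation; each prints the numbers it
computes and what they mean.

The same functionality is available from the shell:

```bash
fecgkit simulate --duration 60 --seed 7 -o out/
fecgkit extract out/record.csv --seed 7 -o out/
fecgkit evaluate out/detected.csv out/truth_fetal_r.csv --tol 0.05
```

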