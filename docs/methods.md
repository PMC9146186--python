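# Methods

This note documents the models, numerical choices and known limitations of
`fecgkit`. Sample indices are 0-based everywhere; conversions to 1-based
numbering happen only in human-readable reports.

## Signal model and preprocessing

An abdominal recording is modelled as an instantaneous linear mixture of a
maternal ECG, a fetal ECG and additive interference (sub-0.5 Hz baseline
drift, 50/60 Hz mains, broadband noise). Preprocessing is a deliberately
standard, fully parameterized chain rather than a reproduction of any
specific published pipeline:

* **Baseline**: the estimate is `median_0.6s(median_0.2s(x))` (odd window
  lengths); the cascade tracks drift while passing QRS impulses through to
  the residual. Windows: `baseline_win1_s = 0.2`, `baseline_win2_s = 0.6`.
* **Mains**: second-order IIR notch (`Q = 30`) at 50 Hz (60 Hz selectable),
  applied forward–backward for zero phase.
* **Pulse artifacts**: samples beyond `k` MADs of the median (default
  `k = 8`) are replaced by linear interpolation between clean neighbors;
  more than 50% flagged raises an error. **This stage is disabled inside
  the extraction pipeline** (`artifact_k=None`): the MAD of a conditioned,
  spiky ECG is set by its flat baseline, so genuine R peaks sit tens of
  MADs out and any practical `k` would clip them. The clip is meant for raw
  records with collector-displacement spikes and must be enabled
  deliberately. Note that with `k ≥ 1` at most half the samples can ever be
  flagged (the MAD is itself the median deviation), so the >50% guard only
  triggers for `k < 1`.

Each stage preserves length and is idempotent to within 1% RMS.

## FastICA with over-relaxed Newton iteration

Channels are de-meaned and whitened by eigendecomposition of the sample
covariance (error if the requested component count exceeds the numerical
rank, threshold `1e-12` relative to the largest eigenvalue). The symmetric
fixed-point update per sweep is

    W⁺ = E[g(WZ) Zᵀ] − diag(E[g′(WZ)]) W,

with contrasts logcosh (`g = tanh`, default), exp, or kurtosis. The raw
Newton step carries an arbitrary per-row scale and sign — the fixed-point
multiplier `E[s g(s)] − E[g′(s)]` is negative for sub-Gaussian sources, and
near-Gaussian rows give vanishing steps — so relaxing the raw step directly
is unstable. Instead the sweep is completed classically (symmetric
decorrelation `W ← (WWᵀ)^{-1/2}W`), the result is sign-aligned row-wise to
the current estimate, and the over-relaxation interpolates between the two
orthonormal iterates:

    W ← decorr(W + λ (W_next − W)),   λ ∈ (0, 2], default 1.5.

This preserves the classical fixed points for every λ and reduces exactly
to standard symmetric FastICA at λ = 1. Convergence: `max_row(1 − |w_newᵀ
w_old|) < 1e-6`, at most 200 sweeps; non-convergence returns a flagged
result with a warning, never an exception (with fewer non-Gaussian sources
than whitened dimensions the noise rows wander indefinitely — normal and
harmless). All randomness enters through the seeded initial `W`; runs are
bit-reproducible.

**Measured limitation:** on well-conditioned synthetic mixtures the
classical iteration converges in ~4 sweeps and λ = 1.5 *increases* the
median sweep count (~10) while reaching the same fixed point. The
over-relaxation is motivated by poorly initialized or slowly converging
cases; this implementation keeps λ = 1.5 as the default for fidelity to the
method it implements, not because it is faster here.

## R-synchronized SVD beat-matrix estimation

Given R peaks, consecutive R-to-R segments starting `0.3 × median(RR)`
before each peak are stacked; each row is linearly interpolated to the
median segment length with a **two-piece warp anchored at the R sample**
(pre-R samples to a fixed column count `n_pre`, post-R samples to the
rest). The anchor keeps QRS complexes exactly column-aligned despite RR
variability; a single uniform warp was measured to smear the R column by
± the RR jitter and visibly degrade the rank-2 reconstruction (pure-signal
correlation 0.86 vs 0.999 anchored). Truncation keeps the `k = 2` largest
singular values (the difference spectrum of the singular values is exposed
so users can re-derive `k` per record); inversion resamples each row back
to its original span, zero-filling samples outside all segments. The
Eckart–Young identity `‖A − A_k‖_F² = Σ_{i>k} δ_i²` is asserted in tests as
the optimality oracle.

## Wavelet modulus-maxima delineation

The à-trous filter bank uses the Mallat–Zhong quadratic-spline pair
(lowpass `[1,3,3,1]/8`, highpass `±[2,−2]`), filters upsampled by `2^(j−1)`
at scale j, causal convolution with edge-replicated history and recorded
fractional group delays (0.5, 2.5, 6.5, 14.5 samples at 1 kHz). The
highpass sign makes coefficients proportional to the *negative* smoothed
derivative, so an upright peak produces a negative maximum, a zero
crossing at the peak, then a positive maximum. Inputs not at 1000 Hz are
resampled internally (polyphase) and fiducials mapped back.

R detection (scale 4): positive/negative modulus maxima are thresholded at
±1.0 × the mean magnitude of their own sign's maxima — data-relative, hence
amplitude-invariant — and paired greedily (nearest subsequent positive per
negative, window 0.1 s; orphans dropped; zero crossing = leftmost sample of
the sign change). Corrections on the RR series:

* if the implied rhythm is denser than 240 bpm or over 20% of intervals are
  short, the multiplier is raised by bisection rounds (×2 each, ≤ 8) —
  a mean-of-maxima threshold sits inside the noise floor whenever noise
  extrema outnumber beats, and this global adjustment restores separation;
* isolated `RR < 0.4·RR̄`: the pair with the smaller summed modulus
  amplitude is dropped (declared tie-break);
* `RR > 1.5·RR̄`: the gap interior (0.25·RR̄ margins) is re-searched with
  the multiplier halved per round (≤ 8 rounds);
* at most 5 outer passes.

Q/S are the nearest scale-4 zero crossings within 20 ms left / 30 ms right
of the R pair's maxima, kept only if their amplitude relative to the local
baseline (median over ±0.25 s) reaches 5% of the R amplitude. QRS onset and
offset are the nearest/last scale-4 extrema within 30 ms left of Q and
40 ms right of S (extrema below 1% of the beat's pair amplitude are treated
as numerical ripple); missing Q or S falls back to R ∓ 25 ms, flagged.
P and T use scale 2 (where the slower waves still produce clean pairs):
T in the first half of the following RR interval, P in the last third of
the preceding one, thresholds 0.25 × the mean maxima magnitude *within the
search region* floored at 3% of the beat's scale-2 R amplitude — the
region-local mean makes small T waves detectable, the floor keeps a truly
absent wave absent. Onsets are the leading extremum + 3 samples; offsets
mirror the onset about the peak. The ST segment runs from QRS offset to T
onset; its deviation is the mean amplitude there minus the isoelectric
level (mean over the 20 ms ending 10 ms before QRS onset). Detection
assumes predominantly positive R deflections; `auto_orient` flips a
negative-dominant trace first. Fiducials violating the clinical ordering
(P before QRS before T) are discarded rather than reordered.

## Hybrid extraction pipeline

Per record: preprocess channels → FastICA (component count capped at the
numerical rank, so a rank-1 "fetal only" record degrades gracefully to one
component) → label components by the autocorrelation of the squared,
25 ms-smoothed source (maternal 55–105 bpm, fetal 110–180, at most one of
each, periodicity score ≥ 0.1) → per channel: subtract the rank-2 maternal
beat-matrix reconstruction (maternal R from the maternal component, capped
at 120 bpm), detect fetal R on the residue (capped at 200 bpm), rank-2
denoise the fetal beat train, then subtract the least-squares projection
onto the non-fetal sources → keep the channel with the best SNR_RMS. The
per-role rate caps are physiological priors, not tuning: they tell the
threshold-raising rule which rhythm is plausible for that trace. The
baseline "SVD-only" estimate (same fetal peaks, rank-2 on the raw
conditioned channel) is reported alongside for comparison. Heart rates are
`60 / mean RR`, rounded to two decimals in reports.

## Evaluation metrics

Beats are unit-ℓ2-normalized before both SNRs, making σ a mean cosine
similarity in [−1, 1] and both metrics amplitude-invariant (the raw ratio
is only dimensionally meaningful under some normalization). `SNR_Eig` uses
the Gram-matrix eigenvalues (equivalently squared singular values);
`SNR_RMS = σ/(1−σ)`; both reported as `10·log₁₀` in dB; degenerate cases
map to ±inf (σ ≥ 1 − 1e−12 counts as identical beats). Peak matching is
greedy one-to-one in time order with a 50 ms default tolerance
(configurable; 20 ms is used for the simulator checks). F1 is implemented
exactly as `TP/(TP+FP+FN)` — a Jaccard-type index bounded above by both Se
and PPV, deliberately not the harmonic mean.

## Simulator

Beats are sums of five Gaussian kernels. Fetal defaults: R (amp 1, σ =
QRS/8), Q/S (−0.16/−0.20, centers ∓0.3·QRS, σ = QRS/10 — so the ±2σ points
put QRS onset/offset exactly at ∓QRS/2 and the analytic duration equals the
configured `qrs_ms` = 40), P (+0.10 at −95 ms), T (+0.28 at +160 ms, σ =
24 ms). Maternal beats are wider and slower (QRS 90 ms, T at +280 ms).
Beats are placed at RR intervals jittered uniformly ±3%; mixing columns are
drawn from U(0.5, 1.5) (fetal column scaled by the amplitude ratio, default
0.25), redrawn until the condition number is below 50; per-channel noise
adds a 0.3 Hz sinusoid (0.1 mV), 50 Hz mains (0.05 mV) and white noise
(0.02 mV). `record = mixing @ sources + noise` holds exactly and everything
is bit-reproducible per seed.

What the simulator does *not* emulate: volume-conduction filtering
(mixing is instantaneous and linear — the model ICA assumes), fetal
movement and electrode motion, morphology variability between beats, and —
importantly — the positive-only mixing columns are nearly collinear
(cosine 0.91–0.97), so the fetal source is only weakly recoverable by any
linear unmixing. Passing tests therefore demonstrate the pipeline's
mechanics (maternal cancellation, beat-matrix denoising, residualization)
under realistic amplitude ratios and noise, not performance on real
abdominal geometry or pathological rhythms.

## Problem sizes and tolerances in the checks

The acceptance script and tests use 30 s simulated records (10 seeds) for
the hybrid-vs-SVD comparison, 60 s noise-free fetal traces (20 seeds) for
delineation (R matching at ±20 ms; mean QRS-duration error ≤ 10 ms), 10
random 3×3 mixings at N = 20 000 for FastICA recovery (|corr| ≥ 0.95), and
50 random matrices for the Eckart–Young identity (≤ 1e−8). These sizes are
the package's own choices for fast, stable checks; the algorithms carry no
intrinsic limit near them.

## Known limitations

* Component labelling relies on distinct maternal/fetal rate bands; rhythms
  outside 55–105 / 110–180 bpm (e.g. severe fetal bradycardia) defeat it.
* The delineator's ms-windows assume 1 kHz-class sampling; very low rates
  lose Q/S resolution even after resampling.
* `SNR_Eig`/`SNR_RMS` require ≥ 2 detected beats and presume the beat
  matrix rows are comparable beats; gross misdetection inflates them
  meaninglessly.
* WFDB support covers single-segment format-16/212 records with MIT beat
  annotations — the subset used by 1 kHz abdominal databases.
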