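# Methods

`ppgloss` implements a complete, testable pipeline for discriminating
hypovolemia (blood loss, **BL**) from euvolemia (no blood loss, **NBL**)
in multi-channel photoplethysmographic (PPG) recordings. This note
documents the models, the numeric choices, and what the synthetic
experiments do and do not show.

## Physiological premise

Progressive blood loss reduces the pulsatile blood-volume excursion that a
pulse oximeter sees, so the spectral amplitude of the PPG in the
heart-rate (HR) frequency band declines over time in a bleeding subject,
while it stays roughly level in a euvolemic one. The pipeline turns that
premise into four per-recording features — the slope and goodness of fit
(r²) of the HR-band-amplitude trend line, and the percentage and signed
absolute change between the first and last amplitude estimates — and
classifies the feature vectors with a soft-margin RBF-kernel SVM.
Positive slope/changes indicate euvolemia; negative ones hypovolemia.

## Channel selection

Multi-channel sensors record several PPG signals at once; one channel per
recording is analyzed. Selection minimizes histogram Shannon entropy
(`-Σ p_b log2 p_b`, 50 amplitude bins) as an inverse signal-quality
proxy: additive noise spreads the amplitude distribution over more bins.
The histogram spans the central 90% of the amplitude distribution
(5th–95th percentile; samples outside are excluded) rather than the raw
min–max range. The robust range matters: Gaussian noise stretches the
min–max extremes, squeezes the signal bulk into fewer bins and can
*lower* min–max entropy for noisier channels, inverting the selection.
With the robust range the estimator is exactly affine-invariant, gives 0
for a constant signal and log2(n_bins) for a uniform histogram, and is
monotone in noise SD in the operating regime. Because the estimator is
bounded by log2(n_bins) and the uniform distribution is its maximum,
*no* bounded affine-invariant histogram entropy can grow with noise
indefinitely: it saturates once noise dominates (SD beyond roughly 0.3 of
the pulse amplitude). Ties break to the lowest channel index; entropy is
computed over the whole recording because one channel serves the whole
recording.

## VFCDM time-frequency spectra

The HR-band amplitude is estimated with variable-frequency complex
demodulation (VFCDM), a two-stage procedure:

1. **Fixed-frequency stage.** The signal (decimated 80 → 20 Hz with a
   zero-phase FIR anti-alias filter, cutoff 0.45·fs_d) is demodulated at
   fixed centers f_c ∈ {Fw, 3Fw, 5Fw, …, f_max − Fw}: multiply by
   exp(−j2πf_c t) and low-pass at cutoff Fw with a zero-phase FIR
   (length 4·fs_d/Fw rounded odd = 161 taps, Hamming). Bands of width
   2·Fw tile [0, f_max] without overlap, which makes the stage-1
   components sum back to the band-limited signal (verified to <5%
   relative RMS). Instantaneous amplitude is 2·|filtered|; instantaneous
   frequency is the central-difference derivative of the unwrapped total
   phase, clipped to f_c ± Fw.
2. **Variable-frequency stage.** The *original* signal is re-demodulated
   along each band's instantaneous-frequency trajectory (cumulative
   trapezoidal phase) and low-passed at the narrower Fv. Because the
   carrier now tracks the band's content, the component sits near zero
   offset where the filter gain is ≈1 — this restores amplitude
   calibration even for content at a stage-1 band edge, where the stage-1
   gain alone would be −6 dB.

Defaults: fs_d = 20 Hz, Fw = 0.5 Hz, Fv = 0.15 Hz, 161 taps,
f_max = 10 Hz, spectrum grid step 0.05 Hz (nearest-bin deposition,
max-combine on collision, since the downstream statistic is a band
maximum). Fw = 0.5 Hz keeps respiration (< 0.5 Hz) out of the HR band;
Fv < Fw provides the high-resolution second stage. All parameters are
configurable, and the tone/chirp oracle suite (ridge amplitude within 5%,
ridge frequency within 0.1 Hz, chirp RMS tracking error < 0.1 Hz)
validates any setting. The first and last `filter_len // 2` samples of
every window carry filter transients and are excluded from all downstream
statistics.

## Windowing and the AM_HR statistic

Recordings are cut into consecutive non-overlapping 2-minute sequences
(custom start times supported, since clinical recordings use irregular
instants); each sequence holds seven 1-minute windows shifted by 10 s.
Per window, the maximum spectrum amplitude over the HR band
(default 0.66–3.0 Hz = 40–180 bpm, configurable) is taken at every
interior time sample and averaged over time; the seven window values are
averaged into the sequence's mean AM_HR. Averaging all seven windows
(rather than only the last) uses all the data and halves the estimator
variance; the band maximum follows the ridge of the HR fundamental, which
the generator's 1/(k+1) harmonic weights keep dominant.

A recording must span at least two full sequences (240 s), otherwise no
trend line exists and the pipeline raises an error. The early-detection
variant analyzes `truncate_record(record, max_duration_s)` — the leading
portion of each recording — with identical downstream processing.

## Trend features

Ordinary least squares of AM_HR versus sequence-center time gives the
slope and r² = 1 − SS_res/SS_tot. A constant series (SS_tot = 0) carries
no trend evidence: slope and r² are defined as 0. `abs_change` is the
*signed* difference between the last and first AM_HR values (the sign
carries the classification information); `pct_change` is
100·abs_change/first value and raises an explicit error when the first
value is 0 (rather than emitting NaN). Time-reversal negates slope and
abs_change exactly; pct_change flips sign but not magnitude (its
denominator is the first point of whichever orientation is analyzed).

## Classification protocol

With N_BL < N_NBL, the majority class is undersampled (uniform, without
replacement) to the minority size. Both the subsample and the row order
influence 4-fold cross-validation on a small dataset, so the protocol
draws `n_resamples = 10` balanced datasets, permutes each one
`n_permutations = 10` times, and cross-validates every (γ, C) cell of the
grid (γ ∈ {0.001, 0.005, 0.01, 0.05, 0.1, 0.15, 0.2};
C ∈ {0.01} ∪ {1, 2, 5}·10^i, i = 0…18; 7 × 58 = 406 cells) in each of
the 100 runs. Folds are stratified (preserving the deliberate balance;
a non-stratified mode exists). Overall accuracy, sensitivity (true-BL
rate) and specificity (true-NBL rate) are computed per run and averaged
per cell; the optimal cell maximizes mean OA with ties broken toward
smaller C, then smaller γ (the simpler model). With balanced classes and
stratified folds, OA = (sensitivity + specificity)/2 per run by
construction.

Features enter the SVM unscaled by default — the trend features carry
meaningful, commensurate scales (pct_change dominates separation) and the
small optimal γ accommodates them; per-fold standardization (statistics
from the training folds only) is available. The SVM itself is the
standard soft-margin solver (libsvm via scikit-learn); each fit is capped
at 200 000 working-set iterations to bound worst-case solver time at
extreme C values — on the 4-dimensional, ≤ 58-record datasets involved
the cap is never reached in practice. Inside the grid search the RBF Gram
matrix is precomputed once per run per γ and passed to the solver as a
precomputed kernel; this is algebraically identical to the per-fit kernel
(verified exactly against the direct `run_cv` path) and ~7× faster.

All randomness (parameter draws, per-record noise, subsampling,
permutations, folds) derives from master seeds via `numpy.SeedSequence`
spawning, so every cohort and every experiment is a pure function of its
configuration.

## Synthetic data generator

Each simulated channel is

    a(t)·(1 + m·sin(2π f_r t))·Σ_k c_k sin(2π (k+1) f_hr t)
      + m·a(t)·sin(2π f_r t) + w·sin(2π f_w t) + ε_ch(t)

with linear envelope a(t) = A₀·(1 − d·t/T): the linear decay matches the
linear trend-line model downstream. The multiplicative respiratory term
creates the f_hr ± f_r sidebands of real PPG; the additive term creates
the strong sub-0.5 Hz spectral component; the harmonic weights
c_k = 1/(k+1) (phases 0) give a plausible pulse shape whose largest line
stays at the fundamental. Channels share the waveform and differ only in
additive white-noise SD, giving the entropy selector real work.

Defaults (the study conditions): 80 Hz sampling, 600 s records, heart
rate drawn from 0.9–1.5 Hz, A₀ = 1, m = 0.1, f_r = 0.3 Hz, 2 harmonics,
wander 0.2 at 0.05 Hz, 3 channels with noise SDs (0.02, 0.1, 0.3). The
cohort preset mirrors the clinical imbalance — 29 BL records with decay
fraction d ∈ [0.3, 0.6] (a strong bleed loses a third to two thirds of
its pulsatile amplitude over the recording) and 65 NBL records with drift
d ∈ [−0.05, +0.05]. The class separation is a free parameter, not a
calibrated one: no quantitative effect size for the HR-band decline at a
given withdrawn volume is available, so the BL range was chosen once as a
plausible strong-bleed contrast.

**What passing synthetic tests show — and don't.** The generator
exercises every mechanism the method relies on (HR-band ridge, respiratory
contamination, wander, channel-quality contrast, envelope trends), so
green tests demonstrate that the pipeline recovers known envelope trends
and classifies a separable cohort through the *entire* advertised
protocol. They do not certify clinical performance: real PPG contains
motion artifacts, beat-to-beat morphology variation, non-stationary heart
rates, and adjudication noise in the labels, none of which are modeled.
Accuracies on the synthetic cohort (typically ≥ 95% at the optimal cell)
are therefore upper bounds tied to the chosen class separation, not
forecasts.

## Numerical and degenerate-input choices

- Decimation requires an integer rate ratio; anything else is an error.
- Signals must exceed the FIR length; shorter inputs raise an error
  naming the minimum.
- Constant AM_HR series → all-zero features (r² ≔ 0, documented above).
- A truncation request longer than the record is a warned no-op, flagged
  in the record metadata.
- Readers reject (never impute) missing values, non-uniform time bases
  (tolerance 1e−6 s per step) and duplicate record ids; record and
  feature-table round-trips are lossless at double precision (17
  significant digits).
- Empty test folds (possible only for datasets smaller than the fold
  count) are skipped rather than predicted on.

## Problem sizes used in the shipped experiments

The packaged experiments run the full protocol at its native size: 94
synthetic recordings of 600 s, the full 7 × 58 grid with 100 runs per
cell for the headline experiment, a reduced 7 × 8 grid for the 20-seed
robustness sweep, and 180 cross-validations for the label-permutation
null. These sizes reproduce the protocol exactly while keeping a full
desk-scale rerun in the minutes range.
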