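# Methods

## Problem and data model

The task is binary classification of single-channel EEG segments — seizure
(ictal) versus non-seizure — in the regime of the Bonn epilepsy corpus:
23.6 s segments sampled at 173.61 Hz (4097 samples), one amplitude value per
time point. EDF recordings (CHB-MIT style) are supported by extracting one
named channel and windowing it into epochs of the same duration; an epoch is
labelled ictal when it overlaps a supplied seizure interval. The EDF path is
a capability for applying the trained pipeline to other corpora, not a
reproduction of any particular published split.

## Synthetic data generator

All tests and the acceptance run use synthetic segments, so the study
conditions are explicit:

* **Background** — exact fractional Gaussian noise with Hurst exponent
  `hurst_bg` (default 0.7), generated by circulant embedding of the analytic
  autocovariance γ(k) = ½σ²(|k+1|²ᴴ − 2|k|²ᴴ + |k−1|²ᴴ) (Davies–Harte).
  The embedding reproduces the prescribed covariance to floating-point
  accuracy, which is what makes the Hurst-recovery tests sound; a dense
  Cholesky factorisation covers very short series. Ensemble lag-0/1/2
  autocovariances were verified against the analytic values within
  Monte-Carlo error. Default H = 0.7 reflects the persistent (H > 0.5)
  behaviour reported for both healthy and epileptic resting EEG.
* **Alpha rhythm** — a 10 Hz sinusoid with random phase at amplitude
  `alpha_amp` × background SD. Default 0.5, i.e. the sine carries ≈ 11 % of
  total signal power — a typical share for a visible posterior alpha peak.
  (An early draft used 1.0, a single spectral line holding a third of all
  power, which is physiologically excessive.)
* **Seizure morphology** — a 3 Hz train of asymmetric biphasic transients
  (a sharp ~60 ms Gaussian spike followed by a slower negative half-sine
  wave), the classical generalized spike-and-wave discharge shape, at
  amplitude `sw_amp` × background SD (default 4) covering `burst_fraction`
  of the segment (default 0.5) as one contiguous run with randomised onset.
  No claim of physiological realism beyond "high-amplitude rhythmic ictal
  transients": the morphology exists to give the wavelet bands something
  with the right rate, sharpness and amplitude statistics.
* **Measurement noise** — additive white Gaussian noise, SD 0.2 (relative to
  a unit-SD background).
* **Seeding** — per-segment seeds derive from `SeedSequence(master, index,
  label)`, so datasets are bit-reproducible while segments stay independent.
  Background, alpha phase, noise and burst placement use separate spawned
  streams; with `burst_fraction = 0` the two classes coincide exactly under
  the same seed.

What the generator does **not** emulate: multi-channel structure, EMG/EOG
artifacts, electrode drift, non-stationary background (sleep stages,
medication effects), or the inter-patient variability of real corpora.
Passing tests therefore demonstrate that the pipeline's mathematics and
plumbing are correct and that it separates classes whose difference is
burst-like excess power — they do not certify clinical performance.

## Preprocessing

Fixed order: screen (NaN / all-zero / constant / flat-window report) →
impute-or-drop (isolated NaNs below 1 % linearly interpolated, otherwise the
segment is rejected with a reason) → 0.53–40 Hz band-pass → per-segment
min–max scaling to [0, 1] → class balancing (optional random undersampling).

* **Filter realisation**: 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`), i.e. zero-phase, which preserves spike morphology; the
  magnitude response is applied twice, so the effective attenuation is the
  squared design response. Order and band are configurable.
* **Scaling scope**: per segment. This makes every downstream feature
  invariant to recording gain — necessary when a model trained on one corpus
  is applied to another — at the price of turning absolute amplitude into
  relative distribution shape (see "What the features measure" below).
  Configurable (`scale_mode: none` to skip).
* **Class balancing** is off by default (the synthetic sets are balanced by
  construction) and undersamples the majority class deterministically when
  enabled.

## Hurst features

`rescaled_range` uses the population SD (the classical formulation; the
sample-SD variant is a config switch). `estimate_hurst` averages R/S over
disjoint blocks for each window size on a dyadic grid from `min_window`
(default 16) upward, fits log(mean R/S) against log n by least squares, and
reports H = slope, C = exp(intercept) (natural logs; the base only rescales
C, and the choice is recorded on the fit object). Estimates outside (0, 1)
are flagged, never clipped — strong trends legitimately push H toward 1.

**Fit-range cap for band-limited signals.** The estimator default keeps the
spec-classical grid up to half the series length. The *feature path*
(`hurst_features`) caps the largest window at `fs / low_cut` samples
(~330 at 0.53 Hz): a high-pass filter removes all fluctuations slower than
its cutoff, so R/S growth beyond one cutoff period measures the filter's
roll-off, not the signal. Measured local log–log slopes on preprocessed
H = 0.7 fGn: ≈ 0.66–0.67 per octave for windows 16–256, collapsing to
≈ 0.30 beyond ~330 samples. Restricting the fit to in-band scales recovers
the generating exponent (mean Ĥ ≈ 0.65); fitting across the knee yields a
meaningless average of signal and filter (~0.5). `low_cut_hz=None` restores
the full grid for unfiltered series.

Recovery at the defaults (n = 4096, 30 seeds each): mean absolute error
≤ 0.07 for H ∈ {0.3, 0.5, 0.7, 0.8}, with the known small-sample R/S biases
(upward below H = 0.5 — iid noise estimates near 0.54 — and slightly
downward above H = 0.7).

## Wavelet features

db4, level 4, five coefficient sets [cA4, cD4, cD3, cD2, cD1]. Boundary
handling: `symmetric` is the pipeline default (the common EEG choice);
`periodization` makes the pyramid orthonormal and is used in energy tests.
Note that periodized orthonormality (Parseval) is exact only when 2⁴
divides the signal length; pywt pads odd intermediate lengths, which
perturbs total energy (~1 % at n = 4097) while reconstruction stays exact.
Energy-conservation checks therefore use lengths divisible by 16.

Per set, nine statistics in fixed order: n5, n25, n75, n95 (linear-
interpolated percentiles), median, mean, std, var (population convention,
matching the Hurst module), rms. The approximation band is included by
default (5 × 9 = 45 features); `include_approx=False` drops it. The full
47-name layout (hurstex, hurstc, cA4_n5 … cD1_rms) is versioned and frozen
by a golden test.

**What the features measure.** Because segments are min–max scaled first,
all amplitude statistics are relative to the segment's own range. In a
seizure segment the bursts dominate that range, so the *normalized*
broadband detail statistics shrink while the slow-band (cA4) spread grows —
the classes are separated by the redistribution of the unit range across
bands, not by absolute µV amplitude. This is the intended consequence of
gain-invariant scaling.

## Feature selection

Disabled by default: the complete 47-feature vector feeds the classifier,
the configuration found to perform best; selection is an opt-in comparison
stage. ANOVA uses the explicit two-group F = MS_between/MS_within with
(1, N−2) df (constant features score 0); the random-forest selector uses
impurity importances of a 100-tree regressor on the 0/1 label; k defaults
to 20 for both. Importance reporting fits an L2 logistic regression on
internally standardized features and ranks |coefficient| (top 15), so
magnitudes are comparable across features.

## Models

Defaults are the study hyperparameters:

| family | settings |
|---|---|
| svm  | linear kernel, probability=True, class_weight=balanced, C=1 |
| rf   | n_estimators=100, max_depth=5, max_features=sqrt, min_samples_split=5 |
| lstm | 50 units → dropout 0.1 → dense(1, sigmoid); RMSProp (lr 10⁻³), binary cross-entropy, 50 epochs, batch 72 |

Two documented source ambiguities were resolved in favour of the explicit
hyperparameter lists: 100 trees (not the narrative 150) and
min_samples_split = 5 (not 2).

The LSTM is a compact NumPy implementation (single layer, BPTT, RMSProp
with decay 0.9, forget-gate bias 1, gradient-norm cap 5). It accepts the
feature vector as a single timestep or raw segments as one-feature
timesteps; raw-mode epoch length is configurable. Being trained by
stochastic mini-batches, its accuracy is asserted only with tolerance
bands, though it is bit-deterministic given the seed.

**SVM scores.** The class-1 score returned by `predict` is a logistic
squashing of the signed margin, so the documented 0.5 threshold coincides
exactly with the (class-weighted) decision boundary. Platt-calibrated
probabilities — which re-fit a sigmoid and thereby shift the 0.5 point away
from the weighted boundary, silently undoing `class_weight=balanced` at the
label level — remain available on the fitted estimator for anyone who needs
calibrated values. RF scores are class-1 probabilities; LSTM scores the
sigmoid output.

`grid_search` is exhaustive over the supplied grid, scored by stratified
k-fold mean accuracy, validates hyperparameter names before any training,
and breaks ties in favour of the earlier grid point.

## Evaluation

Seizure (1) is the positive class throughout: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), FPR = FP/(FP+TN) = 1 − specificity. The k-fold
summary is the plain arithmetic fold mean (no size weighting; stratified
folds differ by at most one row). When one number per metric is needed,
macro-averaging over the two classes is used. AUC is the trapezoidal area
under the empirical ROC with rank-averaged ties (equivalently the
normalised Mann–Whitney U count, the oracle it is tested against).

Bootstrap CIs resample (label, prediction) pairs of the evaluated set with
replacement at the original size, B = 1000 by default; models are never
refitted (the interval quantifies sampling variability of the measurement,
at desk-scale cost). Replicates on which the metric is undefined (a single
class drawn) are redrawn and counted. Both interval styles are reported:
the 2.5/97.5 percentile interval and the normal approximation μ ± 1.96σ of
the replicate distribution.

Cohen's d uses the pooled *sample* SD,
S = √(((n₀−1)s₀² + (n₁−1)s₁²)/(n₀+n₁−2)). The default operand is the
model's class-1 score grouped by true class (any feature can be substituted).
Sign is preserved; equal-mean constant groups give d = 0, unequal-mean
constant groups set an infinite-effect flag. On cleanly separated synthetic
data |d| is huge (hundreds) — a degenerate regime worth knowing about when
reading reports.

Timing instrumentation (wall time + peak traced memory per stage) is
report-only; nothing asserts on it, and it can be disabled in config.

## Orchestration and reproducibility

A single validated config (unknown keys rejected) drives
data → preprocess → features → optional selection → cross-validation →
final fit → report. The resolved config and its hash are embedded in every
report; one master seed fans out via `SeedSequence` to the data, balancing,
selection, model and bootstrap sub-seeds, so reruns reproduce every
non-timing number. Stage failures abort with the stage name, preserving the
artifacts already written.

## Problem sizes used in the test and acceptance runs

Chosen as the package's own desk-scale conditions: fGn ensemble checks use
200 series of n = 2048; Hurst recovery 30 seeds per H at n = 4096; the
acceptance run estimates H on 50 preprocessed segments of 4097 samples; the
end-to-end check trains on 100 segments per class with 10-fold CV and
B = 1000 bootstrap replicates.

## Known limitations

* R/S estimation carries its classical small-sample biases; no bias
  correction (Anis–Lloyd/Peters) is applied, and only the R/S estimator is
  provided (no DFA/Whittle/wavelet alternatives).
* The fit-range cap ties the Hurst feature to the preprocessing band; two
  pipelines with different low cutoffs produce `hurstex` values that are not
  directly comparable.
* Per-segment scaling discards absolute amplitude, which for some corpora is
  itself discriminative.
* The synthetic generator's separability at default settings is high; real
  corpora are harder, and reported perfect CV scores on synthetic data say
  nothing about clinical accuracy.
* The NumPy LSTM is adequate for the feature-vector input mode; raw-mode
  training on full 4097-sample epochs is functional but slow, and no GPU
  path exists.
* EDF support covers standard EDF with a simple start/end-seconds seizure
  CSV; EDF+ embedded annotations, BDF and proprietary formats are out of
  scope.
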