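# Methods

## Problem and pipeline

`sleepcascade` classifies 30-second epochs of single-channel EEG (Fpz-Cz,
100 Hz in the reference setup) into the five AASM sleep stages W, N1, N2,
N3, R.  The pipeline is:

1. **Wavelet-threshold denoising (WTD)** of each raw epoch.
2. **Wavelet-packet transform (WPT)** band extraction of six characteristic
   waves: alpha (8–13 Hz), beta (12–30 Hz), theta (4–8 Hz), delta
   (0.5–2 Hz), sleep spindle (12–14 Hz), sawtooth (2–6 Hz).
3. A **51-feature vector** per epoch spanning time, energy, frequency and
   nonlinear-dynamics domains.
4. **MIQ (mRMR) feature ranking** and top-k subset selection.
5. A **cascaded one-vs-one SVM**: stage I separates W / REM-LS / N3 (REM-LS
   merges the mutually confusable R, N1, N2); stage II resolves R / N1 / N2
   on epochs routed to REM-LS, trained on a rebalanced subset.
6. **Evaluation**: repeated stratified 90/10 holdout, confusion-matrix
   metrics, and TOPSIS scoring of candidate nonlinear features.

## Denoising

Each epoch is decomposed to 7 levels with db8 and the detail coefficients
soft-thresholded.  The noise scale is the robust MAD estimate
`median(|d1|)/0.6745` from the finest detail level (25–50 Hz), where
oscillatory EEG content is weakest.  The default per-level threshold is the
SURE-optimal one (SureShrink), capped by the universal threshold
`sigma * sqrt(2 ln N)`.  We chose SURE over a plain universal threshold
because the universal rule, at the amplitudes sleep rhythms actually have,
biases or removes the rhythms themselves: on a 10 Hz unit sinusoid with
sigma = 0.1 white noise, universal thresholding *increases* the RMSE against
the clean signal (0.10 to 0.21; with a per-level noise estimate, 0.71),
while SURE reduces it (to 0.06).  Levels carrying strong rhythms receive a
near-zero threshold and survive shrinkage.  `threshold_rule` accepts
`sure`, `universal`, `none`.  Approximation coefficients are never touched.

## Band extraction

A full 7-level wavelet packet tree splits [0, Nyquist) into 128 uniform
tiles of 0.390625 Hz at 100 Hz.  Terminal nodes are taken in frequency
(sequency) order — the natural tree order does not map monotonically to
frequency.  A wave is reconstructed by inverse-transforming exactly the
nodes whose half-open tile [k·w, (k+1)·w) overlaps the band with positive
measure; a band edge on a tile boundary therefore assigns the tile to the
band containing it from below.  Overlapping bands (alpha/beta/spindle)
share nodes; reconstruction is linear and a node-aligned tiling of
[0, Nyquist) reconstructs the input to machine precision.

The packet wavelet defaults to db20 rather than the db8 used for denoising:
db8's short support leaks badly across tile edges at level 7 (a pure 10 Hz
tone retains only ~89% of its energy in the alpha-band reconstruction, with
sidelobes near 15 Hz and DC), while db20 retains >97% and stays in the same
family.  Both wavelets, the level counts, the extension mode (symmetric)
and the band table are configurable.

## Features (51)

With the epoch's six waves w and the denoised epoch x (3000 samples):

* **6 standard deviations**, computed literally as
  `sqrt(sum_i (w_i - mean)^2)` with no 1/n factor, matching the printed
  definition; `normalized=True` restores the conventional estimator.
* **17 auxiliary time-domain features** of x: mean, median, variance, mean
  absolute value, RMS, peak-to-peak, skewness, kurtosis, zero crossings,
  Hjorth activity/mobility/complexity, line length, IQR, 75th percentile,
  min, max.  The registry is a documented stand-in for an unavailable
  published list and is configurable.  Hjorth derivatives use the first
  difference scaled by the sampling rate, so the mobility of a sinusoid at
  frequency f approaches 2*pi*f.
* **6 energies** `sum w_i^2` plus the **alpha/theta and delta/theta energy
  ratios** (theta is N1's marker; alpha marks R-ish, delta N2/N3-ish
  content, so the ratios target the N1 boundary).
* **6 powers** (sum of the one-sided rectangular-window periodogram of each
  wave), the **mean frequency** (spectral centroid) of x, and the
  **alpha/theta, delta/theta power ratios**.
* **6 order-2 Renyi entropies** `-ln(sum p_k^2)` of the normalized wave
  spectra (natural log; the order is fixed by the squared exponent of the
  printed form).
* **5 nonlinear features of x**: Lempel–Ziv complexity, multi-scale
  entropy, spectral entropy, sample entropy, fuzzy entropy.

Nonlinear conventions: LZC binarizes at the median (value >= median maps to
1), parses with the exhaustive-history LZ76 scan, and normalizes the phrase
count as `c(n) log2(n) / n`; the raw count is also exposed.  Sample entropy
is Richman–Moorman: `-ln(A/B)` over Chebyshev template matches with
distance < r, self-matches excluded, m = 2, r = 0.2 SD.  Multi-scale
entropy is sample entropy of the tau = 11 coarse-grained series with r
taken from the *original* epoch's SD (standard multi-scale convention); the
literal sum-over-blocks form, which only multiplies by the block count at
fixed tau, is available via `literal_sum=True`.  Scales 9–13 preserve the
R/N1 distinction that motivates the feature; tau is configurable.  Fuzzy
entropy uses mean-subtracted templates and exponential membership
`exp(-(d/r)^2)`, hence is invariant to mean shifts.  All entropy kernels
are numba-compiled and are verified against brute-force counting oracles on
short sequences (tolerance 1e-9).

## Feature selection

Features are quantile-discretized (default 10 bins; codes are invariant to
monotone transforms) and scored once against the whole set:
`MIQ(f_i) = I(f_i, g) / ((1/|F|) sum_{j != i} I(f_i, f_j))` with plug-in
mutual information in nats.  This is the one-shot quotient form — every
feature scored against the full set and sorted — not the incremental greedy
variant; ties break by canonical feature order.  Stage I uses the top 32
features, stage II the top 30.  In pipeline mode the ranking is computed on
the training split only, to avoid selection leakage.

## Classifier

Features are standardized with training-set mean and *population* standard
deviation (the convention is documented because the source is silent;
zero-variance columns are dropped with a warning).  Binary machines solve
the soft-margin dual with the quadratic polynomial kernel `(x.z)^2` (libsvm
backend; multipliers, support vectors and bias are surfaced and KKT-checked
in tests).  The decision rule maps a decision value of exactly zero to the
positive class.  One-vs-one ensembles vote with equal weight; ties break by
the largest sum of absolute decision values over the machines involving
each tied class, then by class order.

The stage-II training set keeps every N1 epoch and samples, without
replacement, as many R epochs and twice as many N2 epochs (all available,
with a warning, when a stage falls short).  Stage II reports a stratified
10-fold cross-validation accuracy vector as a training diagnostic and is
then refit on the whole rebalanced subset.  The regularization constant
defaults to Const = 1 (unstated in the source); an optional grid search
over `const_grid` uses the stage-II cross-validation.  Stage I is trained
on the full, imbalanced training set — only stage II is rebalanced.

The flat baseline (`train_single_ovo`) is a five-class one-vs-one SVM on
the stage-I feature subset, used for the cascade-vs-single comparison.

## Evaluation

Accuracy is trace/total of the 5x5 confusion matrix; precision and recall
are per predicted/true stage, reported as NaN when a column/row is empty.
The repeated holdout draws stratified 90/10 splits (stratification keeps
the rare N1 present in both parts; `stratify=False` restores plain random
splits), ranks on the training part, trains cascade and baseline, and
reports mean and SD over repeats.

TOPSIS normalizes computing time (cost) and the two accuracies (benefits)
to [0,1] by min-max, so the ideal and anti-ideal points are (1,1,1) and
(0,0,0); distances are weighted Euclidean *with* the square root (the
rootless variant is available via `sqrt_distances=False`) and the score is
`D- / (D+ + D-)` with default weights 1/3 each.

## Synthetic data

The generator emulates the classical stage-to-rhythm mapping at 100 Hz over
1/f background noise (sigma 10 µV): W = alpha 45 µV + beta 18 µV; N2 =
13 Hz spindle bursts (Gaussian envelopes, 0.25/s) + sparse K-complex-like
1 Hz transients + light theta; N3 = 100 µV delta; R = theta + 3 Hz
sawtooth-shaped waves + weak alpha/beta.  N1 is modeled as a *transition
continuum*: a per-epoch depth u ~ U(0,1) interpolates all its component
amplitudes from a wake-like endpoint (alpha 40, beta 15) to a drowsy
endpoint (theta 22, sawtooth 12, alpha 8), reflecting sleep onset, whose
shallow epochs genuinely resemble wake and whose deep epochs resemble
R/N2.  Every component gets per-epoch lognormal amplitude jitter
(sigma 0.5), frequency jitter (±5%) and random phase.  A single
`separation` knob scales oscillation amplitude against the noise floor.

What this emulates — and what it does not: the per-band energy structure,
the N1 transition ambiguity, and spindle transientness are present; real
EEG nonstationarity, artifacts, inter-subject variability, and true
waveform morphology are not.  Passing tests therefore demonstrate that the
pipeline mechanics recover stage structure from band-limited signals with
realistic overlap, not clinical-grade performance on real recordings.

## Problem sizes and numerical choices

The default test/acceptance runs use 200 epochs per stage (1000 epochs,
8.3 h of signal), 5 holdout repeats at 10% test fraction, and 10 quantile
bins; these sizes give stable accuracy estimates while a full run completes
in a few minutes on one core.  Degenerate inputs fail loudly: constant
series make r = 0.2 SD vanish (sample/fuzzy entropy raise), zero theta
energy/power makes the ratios undefined, and an all-zero spectrum has no
entropy.  EDF output quantizes to the 16-bit grid (0.1 µV step with the
default ±3276.8 µV range); round-trip tests compare against the quantized
signal.

## Known limitations

* Appendix-level details of the source feature list (auxiliary time
  features) are stand-ins; the registry is configurable precisely so a
  known list can replace it.
* The cascade-vs-flat N1 advantage on *balanced* synthetic data is small
  (the rebalancing mechanism targets the strong class imbalance of real
  nights); on the default conditions it is directionally positive but
  within a few percentage points.
* Real-data headline accuracies are not reproduced here; they require the
  original recordings.
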