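# Methods

This note documents the models, parameter choices and numerical decisions
behind `ecgemotion`, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## Signal model and the synthetic generator

A beat is modelled as the sum of five Gaussian bumps,

    b(t) = Σ_w a_w · exp(−(t − μ_w)² / (2 σ_w²)),   w ∈ {P, Q, R, S, T},

with amplitudes `a_w` (signal units), centre offsets `μ_w` (seconds relative
to the R apex) and widths `σ_w` (seconds). The default morphology is a
normal-looking adult beat: P at −160 ms (0.12 units), Q at −40 ms (−0.10),
R at 0 (1.00), S at +40 ms (−0.15), T at +200 ms (0.30). This is a
simplification of the McSharry dynamical ECG model chosen because every
landmark location is analytically known, which turns fiducial detection into
a measurable recovery problem.

The R–R process is

    rr_i = mean_rr + Σ_j A_j sin(2π f_j t_i) + ε_i,   ε_i ~ N(0, σ_jitter²),

a deterministic mean plus sinusoidal modulators plus white jitter. A
modulator at 0.1 Hz creates LF spectral power in the HRV series and one at
0.3 Hz HF power, with closed-form expectations (the sampled-sinusoid R–R
standard deviation is A/√2), so the HRV stage can be tested against known
truth. Corruption adds a polynomial baseline trend, white broadband noise
and an optional powerline tone. Windows default to 20 s at 1000 Hz, the
acquisition geometry the pipeline targets.

The four-class study conditions (`emotion_class_specs`) encode the autonomic
caricature of the arousal–valence quadrants: high-arousal classes get short
mean R–R (0.65 / 0.72 s), low-arousal long (0.85 / 0.95 s); LF- vs
HF-leaning modulation and mild T/S/P amplitude differences separate valence;
all classes share 0.03-unit noise, a slow trend and R–R jitter. These
defaults are fixed; they are the conditions under which the end-to-end
learning checks run.

**What the generator does not emulate:** muscle artifact and electrode
motion, baseline wander correlated with respiration, ectopic beats and
arrhythmia, morphology drift within a window, inter-subject variability
beyond the parameter ranges drawn in the property tests. Passing tests
demonstrate correctness of the algorithms against controlled ground truth —
not clinical-grade detection performance, and not that the synthetic class
separations transfer to real emotion-labelled ECG (the published recordings
this pipeline targets are not publicly deposited, so real-data accuracy is
out of reach here).

## Pre-processing

* **Band-pass:** Butterworth 0.05–100 Hz. The filter order is not dictated
  by the method description, so order 4 applied forward–backward
  (`sosfiltfilt`, zero phase) is used: zero-phase filtering leaves PQRST
  latencies unbiased, which the R-shift invariant (≤ 2 samples after the
  full chain) verifies.
* **De-trending:** the window is split into K = 8 contiguous segments (the
  last absorbs the remainder when N is not divisible by K) and an ordinary
  least-squares polynomial of degree 2 in the local sample index (scaled to
  [0, 1] for conditioning) is subtracted per segment. The operator is a
  projection: it annihilates any global quadratic exactly and is idempotent,
  both tested.
* **Smoothing:** unit-area Gaussian kernel, σ = 4 ms, truncated at 4σ,
  reflect boundary handling (constants pass through unchanged). 4 ms
  suppresses broadband noise while attenuating the R apex by < 10%.

## Welch PSD and band power

The estimator is the classic averaged periodogram: segments of `lseg`
samples advanced by `lseg − lover` (trailing partial segment discarded),
tapered (periodic Hann by default) and transformed; squared magnitudes are
averaged and scaled by `1/(fs·Σw²)` with interior bins doubled, the standard
one-sided density normalisation under which the integral of the PSD equals a
zero-mean signal's mean square. No per-segment de-trending is applied.

Band power is the integral of the piecewise-linear interpolant of the PSD
over the half-open band `[f_lo, f_hi)`, with linear interpolation at the
edges. This convention makes band powers exactly additive, so the ten TFB
bands partition [0, 100) Hz with machine-precision additivity.

**Grid resolution.** The spectrum is evaluated on a 4× zero-padded FFT grid
(`WelchConfig.oversample = 4`). On the raw `lseg` grid (3.9 Hz bins at
fs = 1000, lseg = 256) the trapezoidal integral cannot resolve the Hann main
lobe of an off-bin tone: a unit 25 Hz sinusoid integrates to ≈ 0.473 over
[20, 30) Hz with ≈ 0.015 apparently in [30, 40). Zero-padding refines the
integration grid without changing the estimator's resolution or
normalisation (the Parseval identity is preserved exactly) and recovers
0.488 in-band with < 0.007 elsewhere.

## PQRST detection

R peaks are local maxima above `rel_threshold × (99th percentile of the
signal)` (default 0.5 — robust against isolated spikes) with a refractory
period `min_rr` (default 0.3 s) that keeps the taller of two conflicting
candidates. Landmarks are then localized per beat: Q is the minimum within
60 ms before R, S the minimum within 80 ms after, P the maximum between
280 ms before R and the Q point, T the maximum between S and 360 ms after R.
These search windows span normal adult interval ranges and are
configuration parameters. Beats whose search ranges cross the window bounds
or a neighbouring R are dropped rather than padded.

Recovery is scored on clean synthetic windows with a ±10 ms match tolerance;
beats whose R apex lies within 50 ms of a window edge are excluded from the
precision/recall denominators, since a boundary-truncated beat has most of
its waveform outside the window and cannot be scored against any
local-extremum detector. Measured performance under these conditions:
precision = recall = 1.0, median landmark error ≈ 1 ms.

## HRV

NN intervals are R–R differences in ms; the HRV series is a cubic spline
through (cumulative time, interval) resampled at 4 Hz (standard practice;
configurable). `sdnn`/`rmssd`/`sd1`/`sd2` use sample (n−1) normalisation;
`nn50` counts successive differences strictly greater than 50 ms. Frequency
features integrate the Welch PSD of the mean-removed series over
VLF (0.0033–0.04), LF (0.04–0.15) and HF (0.15–0.4 Hz); when the series is
shorter than the configured segment length, the segment shrinks to the
series length (logged). `hf` is computed and available through the API but
excluded from the exported vector so the HRV block holds exactly 14
features; `lf_hf` is reported as NaN when HF power is zero (logged).
`total_power` is defined as vlf + lf + hf over the analysed range.
Poincaré axes come from successive differences/sums: sd1 = SD(d)/√2,
sd2 = SD(s)/√2, with the identity sd1 = rmssd/√2 (up to sample-vs-population
SD) used as a cross-check.

## EMD and Hilbert features

Classic sifting: cubic-spline envelopes through the strict local maxima and
minima (end extrema mirrored about the signal boundaries to tame the
splines), envelope mean subtracted, iterated until the Cauchy criterion
`Σ(h_prev − h)² / Σh_prev² < 0.2` or 100 iterations; IMFs are subtracted
from a running residual until it is near-monotone or 8 IMFs are extracted.
The residual is maintained by exact subtraction, so reconstruction is exact
to machine precision by construction — the tests verify ~1e−16 relative
error. The extrema/zero-crossing balance that defines an IMF holds
approximately (within a few percent) under this finite sifting tolerance;
exhaustive sifting would tighten it but distorts amplitude modulation.

Per IMF (first six; missing slots zero-filled so the block is always 24):
`spec_p` is the mean squared value; `mean_if` the mean of the Hilbert
instantaneous frequency (finite-difference phase derivative, length N−1)
over the interior 90% of samples, since the analytic signal is unreliable
near the edges; `ins_p` the power of the instantaneous-frequency series
after mean removal — without mean removal it would duplicate `mean_if²` and
carry no independent information (a config flag restores the raw variant).

`spec_pf` integrates the IMF's Welch PSD over the full frequency range. By
default this uses a **single full-length untapered segment**: slow IMFs span
only a few cycles per 20 s window, and short tapered segments (e.g. the TFB
stage's 256-sample Hann) spread their power into the half-weighted DC bin of
the trapezoidal integral, losing up to ~30%. With the full-length untapered
segment the time-domain and frequency-domain powers agree within a few
percent for every IMF (the Parseval consistency the tests enforce at 10%).

## TFB

Welch PSD of the fully pre-processed window with lseg = 256, lover = 128 and
the Hann taper; spectral power in ten half-open 10 Hz bands covering
[0, 100) Hz. Because the band-pass edge sits at 100 Hz, `band_10` content is
attenuated by the filter roll-off; this is faithful to the pipeline order
(filtering precedes feature extraction). The band count and width are
configuration parameters rather than re-derived from a band-width sweep.

## Feature assembly

Vector order is fixed: 14 HRV, 24 EMD, 15 WIB, 10 TFB. If beat detection
fails (fewer than two usable beats), the HRV and WIB blocks carry NaN
sentinels and the vector is still 63 long; `build_table` drops such rows
(logged) rather than imputing, mirroring the practice of discarding
anomalous recordings.

## Classification

All estimators are scikit-learn. Evaluation is stratified 10-fold
cross-validation with a fixed seed (stratification protects small per-class
counts; the plain variant would differ only in fold composition). The
pipeline `RobustScaler → selector → learner` is fitted inside each training
fold, so scaling statistics, selection masks and (when a grid is supplied)
hyperparameters never see test-fold data; grid search runs nested within
each training fold. Reported: mean and SD of fold accuracies (percent), the
hyperparameters chosen on the full data, and the features selected on the
full data.

Selection methods: RFE to a fixed feature count using the downstream
learner's importances; a χ² filter on per-column min-shifted features
(robust-scaled features can be negative, which χ² cannot accept); a
univariate ANOVA-F filter that by default retains features with p-value
below the threshold (a `keep_above` flag provides the literal
"p > threshold" reading, whose intent is ambiguous); and model-based
selection keeping features with importance above the mean importance of a
fitted random-forest / extra-trees / linear-SVM selector. AdaBoost uses the
current scikit-learn API (SAMME boosting; the SVM base learner runs with
probability estimates enabled).

## Problem sizes and numerical conventions

* Default window 20 s × 1000 Hz = 20 000 samples; acceptance-scale runs use
  20 windows for EMD checks, 50 for PQRST recovery, and a 200-window
  four-class dataset (50 per class) for the learning sanity checks.
* 0-based sample indices, half-open window ranges, seconds for time,
  milliseconds for intervals, signal-units² for powers (ms² for HRV bands).
* Medians of even-length samples are the mean of the central pair; all
  SD-like statistics use the n−1 normalisation.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / `SeedSequence`); identical seeds give
  bit-identical windows, datasets, fold splits and results.

## Known limitations

* The R-peak detector assumes upright (positive) R waves; inverted-polarity
  signals raise an explicit error rather than being auto-corrected.
* Wave onsets/offsets (P onset, T end, QT) are not delineated — intervals
  are peak-to-peak.
* EMD is the plain algorithm; mode mixing on intermittent signals is not
  addressed (no EEMD/CEEMDAN).
* The classifier stage evaluates windows independently; no subject-wise
  blocking is applied, which on real multi-subject data would be needed to
  rule out identity leakage.
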