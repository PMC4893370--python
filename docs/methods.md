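# Methods

## Problem and model

Selective retina therapy (SRT) ruptures retinal pigment epithelium (RPE)
cells with a train of short laser pulses (30 pulses at 100 Hz, 250 ns each)
while leaving the neural retina intact — which also means a successful
lesion is invisible to the ophthalmologist.  When an OCT beam is co-aligned
with the treatment laser, the M-Scan (a depth × time raster of repeated
A-Scans at the treated spot) records transient high-frequency intensity
variations around the RPE whenever microbubbles form, i.e. whenever the
treatment succeeded.

The package frames outcome assessment as binary classification.  An M-Scan
`X ∈ R^{L×T}` is mapped by a feature extractor `g : R^{L×T} → R^d` to a
descriptor `u`, and a 200-tree random forest `f : R^d → {0,1}` predicts the
outcome label `y` (1 = RPE rupture).  The descriptor concatenates four
families computed from pulse-synchronized blocks:

* **Blockwise M-Scan features `u_bm`.** The scan is cut into `N` blocks of
  `L_b × T_b = 300 × 353` pixels centered on the RPE: per 700-column pulse
  period, one block starts at the pulse onset (and contains the
  application) and one immediately after it; the reference block `B_0`
  occupies the `T_b` columns before the first onset.  For each analysis
  block the reference is subtracted, `B'_n = B_n − B_0`, and
  `u_bm(n) = sqrt( Σ_{l,t} (B'_n(l,t) − μ'_n)² / (L_b T_b − 1) )`.
  The maximum first difference of this vector is appended.
* **Blockwise speckle features `u_bs`.** `R_n(t)` is the rms over the
  block's rows at column `t`; `v_n` its sample variance over the block's
  columns; `u_bs(n) = v_n − v_0`, with the maximum appended.
* **Speckle-variance count `u_sv`.** The column sum `S(t) = Σ_l X(l,t)` is
  standardized, its moving average (window = one pulse period, mirrored
  edges) standardized and subtracted, and the count of columns exceeding a
  threshold `s_th = 3` robust z-scores is recorded (see numerical notes).
* **Spectrogram features `u_sp`.** The whole-scan columnwise rms `R(t)` is
  short-time-Fourier transformed (Hamming window 189, hop 21 = window/9),
  the magnitude median-filtered (3×3), converted to dB (floor 1e−12),
  summed over frequency per window, and min-max normalized to `Ẑ ∈ [0,1]`.
  The crest factor `max(Ẑ)/rms(Ẑ) = 1/rms(Ẑ) ≥ 1` and the sum `Σ_τ Ẑ`
  form the two features.

With 30 pulses the trailing inter-pulse block of the last period falls past
the 300 ms train window, so `N = 60` blocks (59 analysis + reference) and
`d = 2N + 3 = 123`.

## Preprocessing

* **Axial motion correction.** Each A-Scan is aligned to a reference
  A-Scan (column 0 by default) by the circular lag, bounded to ±L/4, that
  maximizes their cross-correlation.  Correlation is computed on
  mean-subtracted `log1p` intensities: on a linear scale the exponential
  speckle tail lets a handful of bright RPE pixels dominate the estimate,
  while the log scale weights all depth rows comparably.  Because bulk
  axial motion is slow relative to the A-Scan rate, the per-column lag
  estimates are median-filtered over 9 columns before the (circular, hence
  lossless) shifts are applied.
* **Pulse detection.** Laser onsets are rising-edge crossings of the
  photodetector trace (1 MHz) at the min/max midpoint with a 10%-of-range
  hysteresis band, mapped to M-Scan columns by `round(t · f_ascan)`.
* **Cropping.** The scan is cropped to the 300 ms pulse-train window
  *plus* a pre-train margin of one block length before the first onset, so
  the reference block always exists.  At 70 kHz this yields 353 + 21000
  columns.  Cropping is pure slicing and idempotent.
* **Temporal subsetting.** The train window divides into three exact
  100 ms segments (start/middle/end; start+middle = first 200 ms).  A
  segment's sub-raster carries its own one-block margin before its first
  onset, and features recompute identically on it (10 pulses → N = 20 →
  43 features).

## Classification and evaluation

Scores are the forest's class-1 vote fractions.  ROC curves use the full
threshold sweep with trapezoidal AUC (equal to the Mann–Whitney pair
statistic, ties at half credit).  Clinical operating points are chosen on
candidate thresholds at midpoints between consecutive distinct scores,
with the strict rule "positive iff score > threshold": for 100%/95%
specificity the smallest feasible threshold (maximal sensitivity subject
to the constraint); for 100% sensitivity the largest threshold that still
calls every positive.  Generalization is estimated by 50 stratified random
subsampling splits at train fraction 102/153 (matching a 102-train /
51-test split of a 153-scan cohort), reporting per-split AUCs, their
mean/sd, and the pooled held-out AUC.  Accuracy against a reference
labeling (clinically: FFA leakage) is the agreement fraction, printed as a
percentage rounded half-away-from-zero to one decimal (15/16 → 93.8).
Feature-family ablation retrains on column subsets of the named segments
with all other settings unchanged; temporal analysis retrains on
per-segment features.

## Synthetic data

No public time-resolved SRT M-Scan data exist, so the generator emulates
the acquisition statistically:

* a layered mean-reflectivity depth profile with a dominant Gaussian RPE
  band (~20× background) plus dimmer inner-retina bands;
* fully developed speckle: per-pixel intensity `m(l)·|g|²` with `g` a unit
  complex Gaussian, so the marginal is exponential with mean = s.d.  A
  power fraction `static_speckle = 0.5` of `g` is frozen over time
  (stationary scatterers), giving columns the shared texture that
  cross-correlation alignment relies on; a Rayleigh-amplitude variant is
  available;
* 30 pulses at 100 Hz after a 20 ms lead-in, with a 1 MHz photodetector
  trace carrying 250 µs rectangles at the true onsets;
* for positive outcomes, a multiplicative burst `1 + a·|N(0,1)|`
  (independent per pixel, hence broadband) applied for 3 ms after each
  onset to a band of rows around the RPE.  The default effect size
  `a = 2` is a strong, clearly separable effect; `a = 0` produces a scan
  statistically identical to a negative one.  `burst_pulses` can confine
  bursts to the first pulses of the train (early melanin-cluster breakup);
* optional axial jitter: a bounded ±1 random walk stepping with
  probability 0.005 per column (bulk eye/sample motion is slow relative to
  the A-Scan rate), applied as circular row shifts so that motion
  correction can invert it exactly.

What the generator does **not** model: coherent field propagation and
phase, the OCT point-spread function, depth-dependent attenuation and
shadowing under the RPE, B-scan geometry, detector noise floors, and any
physiological variability between eyes.  Passing simulation-based tests
therefore demonstrates the internal consistency and statistical power of
the pipeline under the stated phenomenology — not clinical performance on
real scans.

## Numerical choices and conventions

* `u_sv` thresholding: `S' = standardize(S) − standardize(S_mov.avg.)` is
  exactly zero-mean but not unit-variance (its variance depends on the
  correlation between signal and trend, and bursts inflate a plain s.d.
  estimate).  The count therefore uses robust z-scores — median removed,
  scaled by the normal-consistent median absolute deviation — anchoring
  `s_th = 3` to the quiescent noise level.  This keeps the null exceedance
  rate at the Gaussian tail level and the count monotone in effect size.
* Constant signals: a constant `S(t)` or a constant spectrogram profile
  yields `u_sv = 0` and `Ẑ ≡ 0` with crest factor 1 (logged conventions).
* Degenerate partitions: the gradient feature needs at least two analysis
  blocks; fewer is an error.  Blocks extending past the scan end are
  dropped with a warning (this is what removes the 60th analysis block of
  the last period).
* RPE localisation: argmax of the time-averaged depth profile, ties to the
  smallest row, clamped so the block band fits the raster.
* "Hop factor 9" is realized as hop = ⌊window/9⌋ = 21 columns; a direct
  hop-in-columns override is available in `FeatureConfig`.
* The dB conversion floors magnitudes at 1e−12 to avoid −∞.
* Shift invariance: adding a constant to every pixel leaves `u_bm` exactly
  unchanged (reference subtraction).  No such exact law holds for `u_bs` —
  the columnwise rms is nonlinear in an additive offset — so only the
  `u_bm` law is asserted.
* All randomness flows from explicit integer seeds; per-sample and
  per-split seeds derive from a master seed via `SeedSequence`.  Same seed
  ⇒ bit-identical rasters, features and predictions.

## Problem sizes

Cohort-level studies (classification power, ablation, temporal analysis)
run at a reduced acquisition scale — time axis divided by 4 (17.5 kHz,
175-column period, 88-column blocks, Hamming 47/hop 5) and depth halved to
300 rows — which preserves the block-count arithmetic (N = 60, d = 123)
while keeping a 153-scan cohort simulation to tens of seconds.  The
descriptor-arithmetic checks run at the full clinical scale (600 × 21353
cropped raster).  Both presets live in `srtoct.presets`.

## Known limitations

* The operating points stored with a trained model are selected on the
  training scores; a clinical deployment would calibrate them on held-out
  data.
* The generator's effect phenomenology (burst amplitude/duration) is
  qualitative; no public measurements exist to calibrate it against, so
  absolute simulated AUCs should not be read as predictions of clinical
  accuracy.
* Phase-resolved and polarization-sensitive features are out of scope, as
  is any real-time laser-cease control loop.
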