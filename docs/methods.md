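# Methods

This note documents the models, parameter choices and numerical
decisions behind the package, and what the synthetic validation does —
and does not — establish about real recordings.

## Forward model (synthetic cohorts)

Each simulated subject is generated forward through the physics that
the preprocessing chain inverts.

**Cortical signal.** Per channel and chromophore (micromolar):

* *Evoked component*: a canonical double-gamma haemodynamic impulse
  response (gamma shapes 7 and 17 at unit scale — response peak near
  6 s, undershoot near 16 s — mixing ratio 1:6, unit peak) convolved
  with the stimulus boxcar. The kernel is normalised so that a single
  15 s block produces unit peak response, making the amplitude
  parameter interpretable as peak micromolar. Auditory blocks drive the
  temporal channels, visual blocks the occipital channels. Default
  peak: 0.4 µM HbO in controls; the tinnitus group's amplitude is
  reduced by 0.15 µM by default. HbR evoked responses are −⅓ of HbO
  (typical inverse coupling), configurable.
* *Resting network*: four latent signals (left seed, right seed,
  frontal, occipital) are AR(1) processes (coefficient 0.95 at the
  native 7.8125 Hz rate) whose **sample** correlation matrix is imposed
  exactly by whitening and Cholesky recolouring. Exact imposition is
  what makes the generator's correlation targets testable to ±0.02 on
  360-sample resting segments; because all latents share the same AR
  coefficient, any mixture remains AR(1), so prewhitening recovers the
  imposed correlation. Seed channels carry their side's seed latent,
  ROI channels their ROI latent; remaining long channels get
  independent latents. Default latent scale 0.5 µM HbO, HbR scaled by
  ⅓ with its own correlation targets (a single −⅓ coupling would make
  per-chromophore connectivity targets unreachable; the evoked
  component keeps the −⅓ coupling). Default seed–seed correlation 0.3,
  frontal–occipital 0.1; non-positive-definite target sets are
  rejected with a descriptive error.
* *Group effects* (defaults in `CohortConfig`, all configurable):
  tinnitus adds +0.20 to right-seed frontal HbO connectivity, +0.15 to
  left, +0.20 to right-seed occipital HbR; occipital HbR connectivity
  grows with loudness at 0.036 per rating point and frontal HbO with
  duration at 0.021 per year (both centred at the cohort means).
  Effect magnitudes are free parameters of the generator, chosen to
  yield clearly detectable contrasts at n = 18 + 25; they are not
  calibrated to any real dataset.

**Physiology and artefacts.** A per-channel cardiac sinusoid
(1.1 ± 0.05 Hz, 0.2 µM — inside the 0.2–2.5 Hz scalp-coupling band), and
a single shared superficial signal per subject: slow AR(1) drift
(coefficient 0.995, 1.2 µM) plus respiration (0.25 Hz, 0.2 µM) and a
Mayer wave (0.1 Hz, 0.25 µM — deliberately at the evoked band edge).
The superficial signal enters every short channel at full amplitude and
every long channel scaled by `superficial_frac` (default 0.5); HbR
receives 0.3 of the HbO systemic signal. Per-channel AR(1) noise
(coefficient 0.4, 0.2 µM HbO, ⅓ for HbR) and white per-wavelength
optical-density measurement noise (5 × 10⁻⁷ OD) complete the model.
Bad channels (13% of channels per subject by default) receive
acquisition gain 8 and no cardiac component; good channels draw gains
1–7.

**Optics.** Concentrations map to optical density through the modified
Beer-Lambert relation with extinction coefficients from a standard
haemoglobin compilation (760 nm: 1486.59 / 3843.71; 850 nm: 2526.39 /
1798.64 M⁻¹cm⁻¹ for HbO/HbR), adult differential pathlength factors
6.4 / 5.75, and geometric separations 3.0 cm (long) / 1.1 cm (short);
intensity is `I = 10^(-dOD)` with unit baseline. All round-trip tests
are independent of the specific constant values, and the constants are
config-overridable.

**Covariates.** THI scores are drawn with fixed severity-band counts
(18 in 4–36, 7 in 37–60 for the default 25-subject tinnitus group) so
the severity classification task has a deterministic 18 / 7 split;
loudness and annoyance ratings (1–10) are noisy monotone functions of
THI; duration, age and 4/8 kHz hearing thresholds are drawn from
plausible clipped normals with matching distributions across groups
(hearing and age carry no injected signal).

## Preprocessing decisions

* **QC order**: gain first, then SCI; the first trigger is recorded as
  the rejection reason. SCI uses a zero-phase 4th-order Butterworth
  band-pass (0.2–2.5 Hz) and zero-lag Pearson correlation; a filtered
  signal with variance below 1e-12 yields SCI 0 with a warning.
* **Optical density** uses log base 10 with the channel temporal mean
  as reference, so intensity rescaling cancels exactly.
* **Resting resampling** to 1 Hz uses polyphase anti-aliased resampling
  (up 16 / down 125) with line padding; a 360 s segment yields exactly
  360 samples.
* **Short-channel regression** is per long channel and per wavelength:
  the OLS scaling of the (centred) nearest short channel onto the long
  channel, subtracted from the raw series; the fitted fraction is
  recorded in provenance. If a region's short channel fails QC the
  nearest surviving short channel substitutes; with none, the step is
  skipped with a warning. On the resting branch the correction runs
  after resampling (both series resampled identically); on the evoked
  branch it runs between motion correction and band-pass filtering.
* **Beer-Lambert inversion** solves the per-sample 2x2 linear system;
  it is exactly linear, so stage order with other linear filters only
  matters for the nonlinear steps around it.
* **Evoked chain order** is fixed and recorded in provenance: wavelet
  motion correction → short-channel regression → high-pass (0.01 Hz)
  then low-pass (0.12 Hz), both zero-phase 8th-order Butterworth
  cascades → Beer-Lambert → epoching → rejection → window means. The
  band-pass uses generous reflection padding (3 / f_low seconds)
  because an 8th-order 0.01 Hz high-pass rings for minutes.
* **Wavelet motion correction**: db4 at maximum depth; per detail
  level, coefficients outside `[q1 - 3 IQR, q3 + 3 IQR]` are zeroed.
  Boundary coefficients are never zeroed and levels with fewer than 20
  coefficients or zero IQR are left untouched: robust fences are
  meaningless there, and spikes do not live at those scales. On smooth
  signals the step is a near-identity; on an *exactly* noise-free
  signal the fences are degenerate, which is why the pipeline-vs-oracle
  equality test excludes this step.
* **Epoching**: onset mapped to the nearest sample, window closed at
  −5 s and +30 s (274 samples at 7.8125 Hz), linear detrend then
  subtraction of the −5..0 s baseline mean. Rejection is per-epoch:
  max > mean + 2.5 SD over that epoch's own samples (the literal
  reading); a cross-epoch variant is available via configuration.

## Connectivity estimator

Each series is demeaned and fitted with AR(p), p ≤ ⌈4 log₁₀ n⌉ chosen
by AIC with all orders scored on a common sample span (one QR
factorisation gives every nested model's residual sum of squares).
Innovations are correlated with bisquare weights (tuning constant
4.685 on MAD-standardised values, weights multiplied across the two
series). Two calibration corrections make the estimator usable for
inference:

1. **Gaussian consistency.** Down-weighting the tails attenuates the
   weighted correlation below the true ρ of a bivariate Gaussian (the
   bivariate analogue of MAD's 1.4826 factor); the asymptotic
   attenuation curve g(ρ) is computed once by Gauss-Hermite quadrature
   and inverted. Without this the estimator is ~12% biased at ρ = 0.6
   and group-difference estimates inherit the bias.
2. **Null critical values.** The corrected estimator's null
   distribution is still not Pearson's; significance thresholds are the
   1 − α quantile of |r| over a seeded Monte-Carlo null (4000
   independent Gaussian pairs, cached per sample size). Using Pearson
   critical values instead makes the test conservative (measured
   false-positive rate ≈ 0.02 instead of 0.05).

Seed averaging happens on the haemodynamic series before whitening;
ROI averages are arithmetic means of surviving member channels' r
values (no Fisher-z by default, configurable); rejected channels are
omitted, never imputed; a side with no surviving seed channel is
flagged missing.

## Statistics and classification

Group contrasts are pooled-variance independent t-tests (df =
n₁+n₂−2), paired t-tests within subject for left-vs-right auditory
amplitudes, all p-values uncorrected by default with an optional,
flagged Benjamini-Hochberg column. Severity regressions are OLS within
the tinnitus group on {THI, age, duration, 4 kHz and 8 kHz hearing,
loudness, annoyance}; zero-variance covariates are dropped with a
warning and ill-conditioned designs raise a condition-number warning.

Information gain discretises each feature by equal-frequency binning
(5 bins by default; bins are degenerate-safe via quantile deduplication)
and normalises weights by the maximum so thresholds of 0.45 / 0.56
operate on a [0, 1] scale. Note that a perfectly separating feature
attains the full label entropy only when a bin boundary coincides with
the class split (e.g. a median split for balanced classes).
Selection keeps features strictly above threshold, best first; the
workflow falls back to the ten best-weighted features when nothing
clears the threshold (logged). Feature ranking is performed on the full
table before cross-validation — mirroring the reference workflow, and a
known source of optimism that the effect-placement experiment sidesteps
by comparing feature sets under identical protocol.

Classifiers: Gaussian Naive Bayes; KNN with k = 1 (inputs
standardised); a RIPPER-style separate-and-conquer rule learner
(threshold literals grown by FOIL gain, reduced-error pruning on a held
out third, rules for the minority class); and a single-hidden-layer
network (10 logistic units, seeded adam gradient descent, max 800
iterations — sized for desk-scale determinism). Cross-validation uses a
seeded stratified partition that deals class members cyclically across
folds, continuing the deal between classes so fold sizes differ by at
most one even when a class is smaller than the fold count (e.g. 7
moderate/severe subjects in 10 folds). Confusion counts are pooled over
folds; missing features are mean-imputed from the training fold.
Severity classes follow the THI bands (≤16 slight, ≤36 mild, ≤56
moderate, ≤76 severe, else catastrophic); the binary severity task
splits at THI 36.

## Validation experiments and problem sizes

The acceptance suite runs: design-count construction; 1000
Beer-Lambert round-trips (≤1e-9 relative error); whitened-correlation
false-positive calibration on 1000 independent AR(1) (φ = 0.95,
n = 360) pairs against naive Pearson; superficial-correction MSE
reduction (≥5x at superficial fraction 0.5, 5 subjects); brute-force
information-gain agreement on >100 small tables (1e-12); the
connectivity group contrast at Δρ = 0.3 and n = 20/group (100 replicate
cohorts for power, 200 for the null rejection rate — resting-only
recordings); the effect-placement experiment (30 replicate tinnitus
cohorts, n = 25); and a full run-all smoke test at 6 subjects/group
with a 2-minute resting period. The acceptance script reports the same
quantities at reduced replicate counts (600 null pairs; 40 power / 60
null cohorts; 12 placement cohorts), keeping a single-CPU run to a few
minutes; replicate counts are stated in its output (`n` fields).

## What the synthetic validation does not show

The generator emulates the *structure* of resting and evoked fNIRS
signals, not their full empirical messiness: no motion artefacts beyond
what the wavelet test constructs, no optode-position or photon-transport
modelling, sinusoidal rather than broadband physiology, stationary
noise, and effect sizes chosen rather than estimated from data. Passing
tests therefore demonstrate that the pipeline recovers what its own
forward model injects — correctness of the inversion chain and
calibration of the statistics — not that real cohorts of this size
would yield the same contrasts or classification accuracies. Evoked
window-mean contrasts in particular are small relative to in-band
physiological noise at the default settings, so group-level evoked
effects are detectable only at favourable noise levels; the power
consistency test states the reduced-noise operating point it uses.
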