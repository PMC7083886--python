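# Methods

This note records the scientific and numerical choices behind the
package: what each stage computes, what the synthetic cohort generator
does and does not emulate, and where the design was genuinely open.

## Cohort design emulated by the generator

Two patient cohorts and a control group, mirroring the study design the
analysis assumes: cohort #1 (right- and left-hemisphere damaged, default
15 + 5) and the controls (default 6) are tested 3 times per day on 2 days
with a 5x5 search grid (4 target repeats per cell, 100 trials); cohort #2
(13 right-hemisphere damaged) once per day on 10 days with a 7x7 grid
(3 repeats, 147 trials). Each session is a 6-minute, 32-channel
(extended 10-20 Biosemi layout), 128-Hz eyes-open resting EEG segment plus
one search-trial table. All of these are `CohortConfig` fields; analyses
and tests scale the session counts and durations down (see *Problem
sizes*), never the effect parameters.

Severity s in [0, 1] is the single latent driving both modalities. Its
default distribution is a three-stratum mixture (centers 0.1 / 0.5 / 0.9,
SD 0.05), reflecting the no/mild/severe structure the staging analysis
targets; uniform and fixed modes exist for null and recovery experiments.
Left-hemisphere-damaged patients receive near-zero severity (mean 0.05),
matching the clinical asymmetry of neglect. A session-level jitter
(SD 0.05) makes repeated sessions of one subject correlated but not
identical.

## EEG source model

A session is `E = M s(t) + noise`, re-referenced to the common average:

- **Maps** M: K_true = 5 orthonormal columns drawn once per cohort seed,
  constrained to zero channel-mean so they are invariant under average
  referencing (QR of a channel-demeaned Gaussian matrix, largest loading
  oriented positive).
- **Sources**: per component, a sum over the four canonical bands of
  constant-modulus carriers - a tone at a fixed random frequency inside
  the band (drawn in the middle 80%) - with sinusoidal envelope
  modulation `1 + d sin(2 pi f_m t)`, f_m = 0.25 Hz. The band-power CV of
  one carrier is analytically `(2 d^2 + d^4/8) / (1 + d^2/2)` times the
  carrier power: exactly zero at depth 0 and strictly increasing in d,
  which gives closed-form recovery targets. A stochastic (noise) carrier
  was rejected because its intrinsic envelope fluctuations put a large
  depth-independent floor under the CV and destroy the depth-0 limit.
- **Depths**: d = control baseline + group slope x severity x
  per-component pattern, clipped to [0, 0.95). Defaults: baselines
  delta 0.15, theta 0.25, alpha 0.55, beta 0.35; patient slopes
  delta +0.55, theta +0.15, alpha -0.35, beta -0.15 - slow-band
  variability rises and fast-band variability falls with severity, the
  canonical post-stroke spectral asymmetry, distributed over components
  by a fixed pattern (delta loads all five).
- **Noise**: spatially white Gaussian, 1 uV RMS against component
  amplitudes of 8/6/5/4/3 uV (SNR well above 5, the regime in which the
  split-half reproducibility checks are specified).

What the generator does **not** emulate: volume conduction/leadfields,
1/f background spectra, ocular or muscle artifacts (beyond optional
amplitude spikes injectable for rejection tests), non-stationary state
switching, or electrode drift. Passing tests therefore certify the
pipeline's statistical machinery - decomposition, feature extraction,
cross-validation hygiene, calibration of permutation nulls - not its
robustness to real-world recording pathology.

One caveat discovered while validating the depth-0 limit: with 3-cycle
Morlet wavelets the four band carriers of one source leak into each
other's bands and beat, adding a deterministic power variance that is a
property of the transform, not the envelope. The constant-envelope limit
is therefore asserted per band-limited carrier (`modulated_tone`); group
contrasts and monotonicity are unaffected.

## Behavior model

RT for a target at column c is lognormal with median
`500 + 400 * s * leftness(c)` ms and shape `0.25 * (1 + 0.6 * s *
leftness(c))`, where leftness is the normalized leftward eccentricity -
severe patients are slower *and* more variable for left-sided targets,
which drives LI down and F up. Draws beyond the 3000 ms deadline become
misses; an attentional lapse adds misses with probability
`0.02 + 0.3 * s * leftness` (the position-dependent miss rate is a free
parameter, not an asserted value); 1% of trials are false alarms, which
are counted but enter no downstream metric. Target onset is uniform in
[700, 2100] ms. Ground truth stores the analytic per-hemispace means and
variances (deadline truncation and lapses ignored - both rare at
defaults), hence each subject's expected LI and F.

## Statistical-feature mode

Experiments at the study's ~150-session scale (canonical-correlation
recovery, null calibration, staging comparisons) would waste hours
synthesizing time series, so `simulate_cohort(..., eeg_mode="statistical")`
draws session-level feature rows directly from the equivalent
single-latent-factor Gaussian model: X = (LI, F) and Y (20 CVs) both load
on the standardized severity latent, with isotropic noise scaled so that
`alpha' Sigma^-1 alpha = rho/(1-rho)` on each side, making the population
first canonical correlation equal the configured target. Because the
sample CCA maximizes over m = 20 directions it is biased upward; the
planted coupling is shrunk by a first-order Lawley-type correction at the
cohort's patient-session count so the *expected sample* rho_1 matches the
configured value (default 0.67). P3/P4 features are mixtures of the
component CVs with squared mixing weights (from the squared map loadings
at those electrodes) plus channel noise: in a channel, independent
component power fluctuations average out, so a spatially distributed CV
effect is intrinsically diluted at single electrodes - the mechanism
behind the mild-neglect blind spot of the two-electrode variant. Feature
values in this mode are Gaussian surrogates on the CV scale and may be
negative; the full EEG mode remains the reference implementation.

## Preprocessing

Fixed order, enforced and logged per session: band-pass -> resample ->
interpolate bad channels -> common average reference -> ocular ICA ->
artifact rejection (optional montage mapping first).

- Band-pass 1-40 Hz: Butterworth designed at order 8 and applied
  forward-backward (`sosfiltfilt`), i.e. the literal zero-phase 8th-order
  filter; this keeps stopband attenuation at 1.5x the upper edge above
  40 dB (a 4th-order-per-pass variant realizing an 8th-order *net*
  magnitude is available but attenuates only ~38 dB there).
- Resampling to 128 Hz by polyphase filtering (anti-alias built in).
- Spherical spline interpolation of listed bad channels: Perrin kernel,
  stiffness m = 4, regularization 1e-5, 50 Legendre terms; bad-channel
  *detection* is deliberately manual.
- Ocular removal is a pluggable contract: FastICA, components with
  |r| > 0.8 against any EOG trace zeroed before back-projection;
  decomposition failure passes data through with a logged warning.
- Artifact rejection drops fixed 1-s windows (length configurable; the
  "period" granularity was an open choice) in which any channel exceeds
  80 uV, concatenates the survivors and records the join positions so
  spectral estimation never straddles a cut.

## Decomposition and features

The group SVD is computed directly (LAPACK `gesdd`) on the concatenated
channel x time matrix; channels are not mean-centered first (the data are
1-Hz high-passed and average-referenced already; a centering flag exists)
and subjects contribute their natural, unequal sample counts. Component
sign is fixed by orienting the largest loading positive. Selection is
fixed K = 5 by default, with the cumulative >= 80% variance rule
available; explained variance is per-component S_i^2-normalized, its
running sum is the cumulative form the 80% rule uses.

Morlet power uses `mne.time_frequency.tfr_array_morlet`, 3 cycles, on a
geometric grid of 8 voices per octave from 1 to 64 Hz (the printed band
edges nearly double from band to band, suggesting log spacing; a linear
grid is accepted anywhere a grid is a parameter). Samples within one
wavelet half-support (5 sigma_t) of a record edge or concatenation join
are invalid per frequency and excluded; a band needs >= 100 valid samples.
Band membership compares grid center frequencies against the printed
edges inclusively. The CV is the *literal* variance over mean of the
band-power series (population variance) - it carries power units and
scales as c^2 under amplitude scaling by c, both asserted in tests; the
conventional SD/mean is a flag away for sensitivity analyses.

## Behavioral metrics

Outlier removal is a single non-iterative pass with the population SD
(neither iteration nor SD flavor was fixed by the published description);
the center column is excluded from lateralized RT statistics but counts
toward Hit. LMRT/RMRT are means and LVRT/RVRT sample variances of the
kept hits; a hemispace with fewer than 3 kept hits marks the session
incomplete. If both hemispace variances are exactly zero (degenerate
identical RTs) F is defined as its symmetric limit 1. Group contrasts are
one-tailed Welch t-tests; test-retest reliability is the Pearson r per
measure over all unordered day pairs with >= 3 common subjects (which
day pairs enter was unspecified for the 10-day cohort; all pairs is the
default).

## Classification

"LDA accounting for different covariance matrices per class" describes a
quadratic boundary; the default is exactly that (per-class covariances),
with a pooled mode for the classical linear reading. Covariances are
Ledoit-Wolf shrunk toward scaled identity (closed form, cross-checked
against scikit-learn) because folds can hold very few control sessions;
class priors are equal by default since session counts are a design
artifact, not prevalence. Features are ranked per training fold by the
absolute standardized Mann-Whitney U (midranks, tie-corrected variance;
ties in |z| broken by input column order) and z-scored with training
means/SDs - ranking inside the fold is the anti-leakage default even
though the published description is ambiguous about it. LOSO folds are
subjects; in EEG mode the group maps are refit per fold from training
recordings only, and each fold's basis checksum is recorded so leakage
can be audited mechanically. The sequential feature curve reports pooled
AUC vs number of top-ranked features; accuracy is the mean of per-fold
session accuracies. Permutation nulls permute labels at the subject
level (sessions move with their subject), 95th percentile, with a
fixed-feature-count fast path for calibration experiments. Transfer
evaluation drops subjects present in both sets from training and carries
training normalization and ranking to the untouched test set.

## Severity analysis

CCA (patients only, sessions as observations, subject identity used for
permutation blocks and folds) is the classical Cholesky-whitened SVD with
a logged ridge fallback for rank-deficient blocks; weights act on
standardized columns and U, V have unit variance. The sign of the first
component is fixed so U correlates non-negatively with -LI (higher U =
more severe), which stabilizes the no/mild/severe label order.
Permutation significance shuffles whole subjects' Y blocks against X,
99th percentile of the null rho_1. Staging is k-means, k = 3, 50
k-means++ restarts at a fixed seed, clusters labeled by centroid order on
U; external validation tests the held-out paper-test covariate (an affine
function of severity plus noise standing in for the clinical battery)
across stages with one-tailed Welch tests. In the three-class LOSO the
held-out patient's reference stage comes from projecting its *behavior*
onto the training fold's canonical axis and taking the nearest training
centroid - the published procedure does not say how left-out sessions
received labels, and this construction keeps the held-out brain data out
of every fitted object. Brain features are ranked by |b| of the first
canonical component; folds whose training staging leaves a class with
fewer than 2 sessions are skipped with a warning.

## Orchestration

One global seed fans out to per-stage seeds by stage-name hashing
(seed x 1000003 + CRC32(stage), mod 2^31), so stages rerun independently
and the whole pipeline is byte-reproducible. A stage failure aborts the
run with the stage name while preserving completed stages on the raised
error. Reports are deterministic markdown + JSON with explicit "not run"
markers.

## Problem sizes

The committed analysis runs use a working cohort of 19 subjects
(8 + 2 RHD/LHD cohort #1, 5 RHD cohort #2, 4 controls), 76 sessions of
20-s EEG - sizes chosen so the full sequence completes in a few minutes
on one CPU while keeping >= 4 sessions per subject and >= 22 patient
sessions (the CCA needs more sessions than brain features plus two).
End-to-end test experiments use 100 Monte-Carlo replicates where a
probability is asserted; permutation counts are 100-1000 depending on the
experiment, with observed and null statistics always computed by the same
procedure when calibration is the claim. The canonical-correlation
recovery and staging experiments run in statistical-feature mode at the
study's ~150-session scale.

## Known limitations

- The generator's sources are deterministic-envelope tones: ideal for
  closed-form checks, unrealistically clean in spectrum; absolute CV
  values are not comparable to real EEG, only their ordering and
  contrasts are meaningful.
- Statistical-feature mode is Gaussian and can produce negative CV
  surrogates; it shares only first- and second-order structure with the
  full EEG mode.
- Staging quality is bounded by the noise of the behavior-derived labels:
  when the brain-behavior coupling is weak, both reference and predicted
  stages approach chance and per-replicate model comparisons lose power.
- The ocular-ICA stage is a contract around FastICA and is only as good
  as the EOG correlation heuristic; no attempt is made to model blink
  topographies.
- EDF input/output is not implemented; recordings interchange as
  delimited matrices with JSON sidecars.
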