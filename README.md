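# neglect-eeg

Resting-state EEG topography biomarkers for unilateral spatial neglect
(USN) after stroke. The package reimplements, as a tested pipeline, an
analysis in which a few minutes of eyes-open resting EEG are summarized by
group-level spatial topographies and their band-power variability, and
those summaries are used to (i) discriminate patients from healthy
controls, (ii) remain stable across recording days and patient samples,
and (iii) stage the severity of spatial neglect as measured by a
computerized visual-search task. It is aimed at methods researchers in
clinical neurophysiology and neurorehabilitation who want every stage -
preprocessing, decomposition, features, statistics, cross-validation -
reproducible and leak-proof, and testable without patient data: a
first-class synthetic cohort generator plants known topographies,
band-power effects and behavioral deficits so each stage can be checked
against ground truth.

## The model

**Topographies.** Preprocessed EEG sessions (1-40 Hz zero-phase
Butterworth, 128 Hz, common average reference, |amplitude| > 80 uV windows
rejected) are concatenated in time into a channel x time matrix E and
factorized by singular value decomposition,

    E = M S N^T,

whose left-singular vectors (columns of M) are the group-level EEG-SVD
topographical maps, ranked by explained variance VAR_i = S_i^2 / sum_j
S_j^2 x 100. The first K = 5 maps are retained and each subject-session is
projected onto them, E~ = M_{1..K}^T E, giving subject-specific component
time courses. Reproducibility is measured by refitting M on random halves
of the subject pool and matching components with the Hungarian algorithm
on |Pearson r|.

**Spectral features.** Each component time course is convolved with a
3-cycle complex Morlet wavelet (1-64 Hz); band power p(t) is averaged over
the canonical bands (delta 1-3.8, theta 4.1-7.6, alpha 8.2-12.4, beta
15.3-30.6 Hz) and summarized by the coefficient of variation in the
variance-over-mean sense, CV = Var_t[p] / Mean_t[p] (K x 4 = 20 features
per session). A single-channel variant uses theta/alpha CVs at P3/P4.

**Behavior.** The Starry Night visual-search task yields per-session hit
rate and left/right reaction-time statistics (2-SD outlier rule per
hemispace, center column excluded), condensed into the laterality index
LI = (RMRT - LMRT)/(RMRT + LMRT) and the variability ratio
F = (LVRT/|LMRT|) / (RVRT/|RMRT|).

**Statistics.** Patients vs controls: features ranked by the absolute
standardized Mann-Whitney U, z-scored with training statistics, classified
by a Gaussian discriminant with class-specific covariances, evaluated by
leave-one-subject-out cross-validation in which the SVD basis itself is
refit per fold without the held-out subject; significance via 1000
subject-level label permutations (95th percentile of the null AUC).
Severity: canonical correlation analysis between (LI, F) and the 20 CVs on
patients only, permutation-thresholded at the 99th percentile; k-means
(k = 3) on the behavioral canonical scores defines no/mild/severe stages,
validated against a held-out paper-test score; a three-class discriminant
on |b|-ranked CVs stages unseen patients with the whole CCA -> k-means ->
classifier chain refit per fold.

## Worked example

The numbered scripts under `analysis/` run the full sequence on a
simulated working cohort (19 subjects, 76 sessions, 20-s EEG segments;
sizes in `analysis/common.py`) and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_eeg.py
python analysis/03_svd_topographies.py
...
python analysis/07_severity_cca.py
```

Output of the runs committed here:

```
First 5 components explain 95.5% of variance (the study's 5-component cut).
Planted-map recovery |r| per component: [1. 1. 1. 1. 1.]
Split-half reproducibility over 10 random subject splits: mean |r| = 1.000 +/- 0.000
...
Behavior LOSO: AUC 0.89 at 6 features (perm. threshold 0.72); accuracy 0.78 +/- 0.24.
EEG-SVD LOSO (per-fold basis refit): AUC 1.00 at 1 features; accuracy 1.00.
Day 1 -> day 2 transfer (behavior): AUC 0.83.
...
CCA on 60 patient sessions: rho1 = 0.95 (99th-pct permutation threshold 0.81; significant).
Stage session counts (no/mild/severe): [28, 17, 15]
Three-class LOSO mean per-class accuracy: EEG-SVD 0.86 vs P3/P4 0.49 (chance 0.33);
mild-class recall 0.79 vs 0.29.
```

Reading: the five planted maps are recovered exactly and are perfectly
reproducible across subject halves at this signal-to-noise ratio; the
behavioral classifier separates patients from controls well above its
permutation threshold, and the EEG-SVD classifier - with the basis refit
per fold, so no information from the held-out subject leaks in - separates
them perfectly on this strongly planted effect. The first canonical
correlation between laterality indices and band CVs clears its
permutation threshold, the three behavioral-score clusters differ in the
held-out paper-test covariate, and the single-channel P3/P4 variant loses
precisely the mild-neglect class, whose spatially distributed signature
the two parietal electrodes dilute.

A one-call version of the same sequence is
`neglect_eeg.pipeline.run_full_pipeline(PipelineConfig(seed=...))`.

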