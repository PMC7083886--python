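"""Severity staging: CCA, permutation significance, k-means, 3-class LOSO.

Patients only. On the working cohort: CCA between (LI, F) and the 20
EEG-SVD band CVs, 99th-percentile permutation threshold, k = 3 staging of
the behavioral canonical scores validated against the held-out paper-test
covariate, and the per-fold CCA -> k-means -> discriminant severity
classifier for both feature sources (topographies vs P3/P4). A
statistical-mode cohort at the study's ~150-session scale checks recovery
of the planted canonical correlation.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import joblib
import numpy as np
import pandas as pd
from common import RESULTS, SCRATCH, SEED, ensure_dirs, study_scale_config

from neglect_eeg.cca import (
    fit_cca,
    loso_severity_classification,
    permutation_significance,
    stage_severity,
    validate_clusters_external,
)
from neglect_eeg.synthetic import P3P4_FEATURE_NAMES, simulate_cohort, svd_feature_names

SVD_FEATURES = svd_feature_names(5)


def main():
    ensure_dirs()
    ds = joblib.load(SCRATCH / "cohort.joblib")
    feats = joblib.load(SCRATCH / "cv_features.joblib")
    behavior = joblib.load(SCRATCH / "behavior.joblib")

    merged = feats.merge(
        behavior[behavior["complete"]][["session", "LI", "F"]], on="session"
    )
    pats = merged[merged["diagnosis"] != "control"].reset_index(drop=True)
    x = pats[["LI", "F"]].to_numpy(float)
    y = pats[SVD_FEATURES].to_numpy(float)

    model = fit_cca(x, y)
    thr, significant, _ = permutation_significance(
        x, y, pats["subject"].to_numpy(), n_perm=1000, seed=SEED
    )
    stages = stage_severity(model.u[:, 0], seed=SEED)
    patient_stage = (
        pd.Series(stages.labels, index=pats["subject"])
        .groupby(level=0)
        .agg(lambda s: int(np.bincount(s, minlength=3).argmax()))
    )
    validation = validate_clusters_external(patient_stage, ds.ppt)
    validation.to_csv(RESULTS / "07_cluster_validation.csv", index=False)

    grid = [1, 2, 3, 4, 6, 8, 10]
    loso_eeg = loso_severity_classification(
        pats[["subject", "LI", "F"]], pats[["subject"] + SVD_FEATURES],
        brain_cols=SVD_FEATURES, n_features_grid=grid, seed=SEED,
    )
    loso_p34 = loso_severity_classification(
        pats[["subject", "LI", "F"]], pats[["subject"] + P3P4_FEATURE_NAMES],
        brain_cols=P3P4_FEATURE_NAMES, n_features_grid=[1, 2, 3, 4], seed=SEED,
    )

    big = simulate_cohort(study_scale_config(), eeg_mode="statistical")
    bigf = big.features.merge(big.sessions[["session", "diagnosis"]], on="session")
    bigp = bigf[bigf["diagnosis"] != "control"]
    rho_big = fit_cca(
        bigp[["LI", "F"]].to_numpy(), bigp[SVD_FEATURES].to_numpy()
    ).rhos[0]

    out = {
        "working_cohort": {
            "n_patient_sessions": int(len(pats)),
            "rho1": float(model.rhos[0]),
            "rho1_threshold_99": thr,
            "rho1_significant": bool(significant[0]),
            "stage_session_counts": stages.counts.tolist(),
            "three_class": {
                "eeg": {
                    "mean_per_class_accuracy": loso_eeg.mean_per_class_accuracy,
                    "per_class": loso_eeg.per_class_accuracy.tolist(),
                    "confusion": loso_eeg.confusion.tolist(),
                    "best_n": loso_eeg.best_n,
                },
                "p3p4": {
                    "mean_per_class_accuracy": loso_p34.mean_per_class_accuracy,
                    "per_class": loso_p34.per_class_accuracy.tolist(),
                    "confusion": loso_p34.confusion.tolist(),
                },
            },
        },
        "study_scale_statistical": {
            "n_patient_sessions": int(len(bigp)),
            "planted_rho": 0.67,
            "sample_rho1": float(rho_big),
        },
    }
    (RESULTS / "07_severity.json").write_text(json.dumps(out, indent=1))

    print(
        f"CCA on {len(pats)} patient sessions: rho1 = {model.rhos[0]:.2f} "
        f"(99th-pct permutation threshold {thr:.2f}; "
        f"{'significant' if significant[0] else 'not significant'})."
    )
    print(f"Stage session counts (no/mild/severe): {stages.counts.tolist()}")
    print(
        "Three-class LOSO mean per-class accuracy: "
        f"EEG-SVD {loso_eeg.mean_per_class_accuracy:.2f} vs "
        f"P3/P4 {loso_p34.mean_per_class_accuracy:.2f} (chance 0.33); "
        f"mild-class recall {loso_eeg.per_class_accuracy[1]:.2f} vs "
        f"{loso_p34.per_class_accuracy[1]:.2f}."
    )
    print(
        f"Study-scale statistical cohort ({len(bigp)} sessions): sample rho1 = "
        f"{rho_big:.2f} for planted 0.67."
    )


if __name__ == "__main__":
    main()
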