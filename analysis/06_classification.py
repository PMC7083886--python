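"""Patient-vs-control discrimination with anti-leakage cross-validation.

Leave-one-subject-out classification of right-hemisphere-damaged patients
vs controls from (a) behavioral measures and (b) EEG-SVD band CVs with the
group maps refit per fold; subject-level permutation thresholds; and a
day-1 -> day-2 transfer check.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import joblib
from common import RESULTS, SCRATCH, SEED, ensure_dirs

from neglect_eeg.behavior import BEHAVIOR_FEATURES
from neglect_eeg.classify import (
    loso_cross_validate,
    loso_cross_validate_eeg,
    permutation_null,
    transfer_evaluate,
)


def main():
    ensure_dirs()
    ds = joblib.load(SCRATCH / "cohort.joblib")
    clean = joblib.load(SCRATCH / "clean.joblib")
    behavior = joblib.load(SCRATCH / "behavior.joblib")

    usable = behavior[behavior["complete"] & (behavior["diagnosis"] != "LHD")]
    beh = loso_cross_validate(usable, BEHAVIOR_FEATURES)
    beh_thr, _ = permutation_null(
        usable, BEHAVIOR_FEATURES, n_perm=200, seed=SEED, n_features=beh.best_n
    )

    eeg = loso_cross_validate_eeg(
        ds, recordings=clean, n_features_grid=[1, 2, 3, 4, 6, 8, 12, 16, 20]
    )

    day1 = usable[usable["day"] == 1]
    day2 = usable[usable["day"] == 2]
    day2 = day2.assign(subject=day2["subject"] + "*")  # same people, later day
    transfer = transfer_evaluate(
        day1, day2, BEHAVIOR_FEATURES, n_features=beh.best_n, allow_overlap=True
    )

    out = {
        "behavior": {
            "auc": beh.auc,
            "best_n_features": beh.best_n,
            "mean_accuracy": beh.mean_accuracy,
            "sd_accuracy": beh.sd_accuracy,
            "confusion": beh.confusion.tolist(),
            "permutation_threshold_95": beh_thr,
            "auc_by_n": beh.auc_by_n,
        },
        "eeg_svd": {
            "auc": eeg.auc,
            "best_n_features": eeg.best_n,
            "mean_accuracy": eeg.mean_accuracy,
            "confusion": eeg.confusion.tolist(),
            "auc_by_n": eeg.auc_by_n,
        },
        "day_transfer_behavior": {
            "auc": transfer.auc,
            "accuracy": transfer.accuracy,
            "confusion": transfer.confusion.tolist(),
        },
    }
    (RESULTS / "06_classification.json").write_text(json.dumps(out, indent=1))

    print(
        f"Behavior LOSO: AUC {beh.auc:.2f} at {beh.best_n} features "
        f"(perm. threshold {beh_thr:.2f}); accuracy {beh.mean_accuracy:.2f} "
        f"+/- {beh.sd_accuracy:.2f}."
    )
    print(
        f"EEG-SVD LOSO (per-fold basis refit): AUC {eeg.auc:.2f} at "
        f"{eeg.best_n} features; accuracy {eeg.mean_accuracy:.2f}."
    )
    print(f"Day 1 -> day 2 transfer (behavior): AUC {transfer.auc:.2f}.")


if __name__ == "__main__":
    main()
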