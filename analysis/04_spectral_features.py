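"""Wavelet band-power CV features per session.

Projects each clean session onto the 5 group-level maps, computes the
Morlet (3-cycle, 1-64 Hz) coefficient-of-variation features per component
and frequency band, plus the single-channel P3/P4 theta/alpha variant.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import joblib
import pandas as pd
from common import RESULTS, SCRATCH, ensure_dirs

from neglect_eeg.spectral import compute_cv_features, single_channel_cv_features
from neglect_eeg.svd import project_subject


def main():
    ensure_dirs()
    ds = joblib.load(SCRATCH / "cohort.joblib")
    clean = joblib.load(SCRATCH / "clean.joblib")
    basis = joblib.load(SCRATCH / "basis_k5.joblib")

    rows = []
    for sid, rec in clean.items():
        svd_feats = compute_cv_features(project_subject(rec, basis)).to_series()
        chan_feats = single_channel_cv_features(rec).to_series()
        row = pd.concat([svd_feats, chan_feats])
        row["subject"], row["session"] = rec.subject, sid
        rows.append(row)
    feats = pd.DataFrame(rows).reset_index(drop=True)
    feats = feats.merge(ds.sessions[["session", "diagnosis", "label", "day"]], on="session")
    feats.to_csv(RESULTS / "04_cv_features.csv", index=False)
    joblib.dump(feats, SCRATCH / "cv_features.joblib")

    delta_cols = [c for c in feats.columns if c.endswith("_delta") and c.startswith("svd")]
    by_group = feats.groupby("label")[delta_cols].mean().mean(axis=1)
    print(f"Wrote {len(feats)} sessions x {len(feats.columns) - 4} CV features.")
    print(
        "Mean delta-band CV: patients "
        f"{by_group['patient']:.1f} vs controls {by_group['control']:.1f} "
        "(power units; elevation mirrors post-stroke slow-wave abnormality)."
    )


if __name__ == "__main__":
    main()
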