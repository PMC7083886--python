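"""Simulate the working cohort: EEG sessions + visual-search trial tables.

Writes the session manifest and ground-truth summary under results/ and
caches the full dataset (raw EEG included) under scratch/ for the later
stages.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import joblib
from common import RESULTS, SCRATCH, ensure_dirs, working_config

from neglect_eeg.synthetic import simulate_cohort


def main():
    ensure_dirs()
    cfg = working_config()
    ds = simulate_cohort(cfg)
    joblib.dump(ds, SCRATCH / "cohort.joblib")

    ds.sessions.to_csv(RESULTS / "01_sessions.csv", index=False)
    ds.trials.to_csv(SCRATCH / "trials.csv", index=False)
    truth = ds.truth.subjects[
        ["subject", "diagnosis", "cohort", "severity", "expected_li", "expected_f"]
    ]
    truth.to_csv(RESULTS / "01_ground_truth_subjects.csv", index=False)

    n_pat = (truth["diagnosis"] != "control").sum()
    print(
        f"Simulated {len(truth)} subjects ({n_pat} patients), "
        f"{len(ds.sessions)} sessions, {len(ds.trials)} search trials."
    )
    print(
        "Planted severities span "
        f"{truth['severity'].min():.2f}-{truth['severity'].max():.2f}; "
        f"expected LI down to {truth['expected_li'].min():.3f}."
    )
    print(f"Dataset checksum {ds.checksum()[:12]} cached in scratch/cohort.joblib")


if __name__ == "__main__":
    main()
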