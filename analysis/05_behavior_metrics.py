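"""Visual-search behavior: session metrics, group contrasts, reliability.

Computes Hit, LMRT/RMRT, LVRT/RVRT, LI and F per session, contrasts RHD
patients with controls (one-tailed Welch), and quantifies day-to-day
test-retest reliability of each measure.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import joblib
import pandas as pd
from common import RESULTS, SCRATCH, ensure_dirs

from neglect_eeg.behavior import (
    BEHAVIOR_FEATURES,
    behavior_table,
    group_compare,
    retest_reliability,
)


def main():
    ensure_dirs()
    ds = joblib.load(SCRATCH / "cohort.joblib")
    tables = []
    for g, sub in ds.sessions.groupby("grid_size"):
        tr = ds.trials[ds.trials["session"].isin(sub["session"])]
        tables.append(behavior_table(tr, (int(g), int(g))))
    table = pd.concat(tables, ignore_index=True)
    table = table.merge(
        ds.sessions[["session", "day", "diagnosis", "cohort", "label"]], on="session"
    )
    table.to_csv(RESULTS / "05_behavior_metrics.csv", index=False)
    joblib.dump(table, SCRATCH / "behavior.joblib")

    usable = table[table["complete"]]
    contrasts = []
    for measure, direction in (("LI", "greater"), ("F", "less"), ("Hit", "greater")):
        ctl = usable[usable["diagnosis"] == "control"][measure]
        rhd = usable[usable["diagnosis"] == "RHD"][measure]
        t, dof, p = group_compare(ctl, rhd, direction)
        contrasts.append(
            {"measure": measure, "direction": f"control {direction} RHD",
             "t": t, "df": dof, "p": p,
             "mean_control": ctl.mean(), "mean_RHD": rhd.mean()}
        )
    contrasts = pd.DataFrame(contrasts)
    contrasts.to_csv(RESULTS / "05_group_contrasts.csv", index=False)

    per_day = (
        usable.groupby(["subject", "day"])[BEHAVIOR_FEATURES].mean().reset_index()
    )
    retest = retest_reliability(per_day)
    retest.to_csv(RESULTS / "05_test_retest.csv", index=False)

    li = contrasts[contrasts["measure"] == "LI"].iloc[0]
    print(
        f"LI: controls {li['mean_control']:+.3f} vs RHD {li['mean_RHD']:+.3f} "
        f"(Welch t = {li['t']:.2f}, p = {li['p']:.2e})"
    )
    print(
        "Mean test-retest r across behavioral measures: "
        f"{retest.groupby('measure')['r'].mean().mean():.2f}"
    )


if __name__ == "__main__":
    main()
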