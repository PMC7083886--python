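"""Behavioral measures of the Starry Night visual-search task.

From trial tables (target grid cell, hit/miss/false-alarm, reaction time)
the per-session measures are: hit rate, left/right mean RT and RT variance
(center column excluded from the lateralized statistics), the laterality
index LI = (RMRT - LMRT)/(RMRT + LMRT), and the variability ratio
F = (LVRT/|LMRT|) / (RVRT/|RMRT|) - the ratio of left to right RT
coefficients of variation in the variance-over-mean sense. RTs deviating
by more than 2 SD from their hemispace mean are discarded first.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

RESPONSES = ("hit", "miss", "fa")


class OutlierResult(NamedTuple):
    kept: np.ndarray
    n_removed: int
    warning: bool


def remove_rt_outliers(rts, k: float = 2.0) -> OutlierResult:
    """Drop RTs deviating more than ``k`` population SDs from the mean.

    A single pass over the full input list (no iteration). With fewer than
    3 RTs the list is returned unchanged with a warning flag.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 3:
        return OutlierResult(rts, 0, True)
    mean = rts.mean()
    sd = rts.std()  # population SD
    keep = np.abs(rts - mean) <= k * sd
    return OutlierResult(rts[keep], int((~keep).sum()), False)


def laterality_index(lmrt: float, rmrt: float) -> float:
    """LI = (RMRT - LMRT) / (RMRT + LMRT); negative when left targets are slower."""
    if lmrt <= 0 or rmrt <= 0:
        raise ValueError("mean reaction times must be positive")
    return (rmrt - lmrt) / (rmrt + lmrt)


def variability_ratio(lmrt: float, lvrt: float, rmrt: float, rvrt: float) -> float:
    """F = (LVRT/|LMRT|) / (RVRT/|RMRT|), the left/right CV ratio (variance/mean)."""
    if min(lmrt, lvrt, rmrt, rvrt) <= 0:
        raise ValueError("all reaction-time means and variances must be positive")
    return (lvrt / abs(lmrt)) / (rvrt / abs(rmrt))


@dataclass
class SessionBehavior:
    subject: str
    session: str
    hit: float
    lmrt: float | None
    rmrt: float | None
    lvrt: float | None
    rvrt: float | None
    li: float | None
    f: float | None
    n_outliers_left: int
    n_outliers_right: int
    n_false_alarms: int
    complete: bool

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "Hit": self.hit,
                "LMRT": self.lmrt,
                "RMRT": self.rmrt,
                "LVRT": self.lvrt,
                "RVRT": self.rvrt,
                "LI": self.li,
                "F": self.f,
            },
            name=(self.subject, self.session),
        )


BEHAVIOR_FEATURES = ["Hit", "LMRT", "RMRT", "LVRT", "RVRT", "LI", "F"]


def compute_session_metrics(trials: pd.DataFrame, grid: tuple[int, int]) -> SessionBehavior:
    """Per-session behavior from one session's trial table.

    ``grid`` is (rows, cols) with an odd column count; columns left of the
    center column form the left hemispace, those right of it the right one.
    The center column contributes to Hit but not to the lateralized RT
    statistics. Outlier removal is applied per hemispace before computing
    LMRT/RMRT (means) and LVRT/RVRT (sample variances).
    """
    n_rows, n_cols = grid
    if n_cols % 2 == 0:
        raise ValueError("grid must have an odd number of columns")
    center = n_cols // 2
    if trials["col"].max() >= n_cols or trials["row"].max() >= n_rows:
        raise ValueError("trial grid indices exceed the configured grid")
    subject = str(trials["subject"].iloc[0])
    session = str(trials["session"].iloc[0])

    targets = trials[trials["response"].isin(("hit", "miss"))]
    n_fa = int((trials["response"] == "fa").sum())
    hit_pct = 100.0 * (targets["response"] == "hit").mean()

    stats_by_side: dict[str, dict] = {}
    complete = True
    for side, mask in (
        ("left", targets["col"] < center),
        ("right", targets["col"] > center),
    ):
        hits = targets[mask & (targets["response"] == "hit")]
        rts = hits["rt_ms"].to_numpy(dtype=float)
        kept, n_removed, _ = remove_rt_outliers(rts)
        if kept.size < 3:
            stats_by_side[side] = {"mean": None, "var": None, "n_removed": n_removed}
            complete = False
        else:
            stats_by_side[side] = {
                "mean": float(kept.mean()),
                "var": float(kept.var(ddof=1)),
                "n_removed": n_removed,
            }
    li = f = None
    lmrt = stats_by_side["left"]["mean"]
    rmrt = stats_by_side["right"]["mean"]
    lvrt = stats_by_side["left"]["var"]
    rvrt = stats_by_side["right"]["var"]
    if complete:
        li = laterality_index(lmrt, rmrt)
        if min(lvrt, rvrt) > 0:
            f = variability_ratio(lmrt, lvrt, rmrt, rvrt)
        elif lvrt == 0 and rvrt == 0:
            f = 1.0  # symmetric degenerate limit (identical RTs on both sides)
        else:
            complete = False
    return SessionBehavior(
        subject=subject,
        session=session,
        hit=float(hit_pct),
        lmrt=lmrt,
        rmrt=rmrt,
        lvrt=lvrt,
        rvrt=rvrt,
        li=li,
        f=f,
        n_outliers_left=stats_by_side["left"]["n_removed"],
        n_outliers_right=stats_by_side["right"]["n_removed"],
        n_false_alarms=n_fa,
        complete=complete,
    )


def behavior_table(trials: pd.DataFrame, grid: tuple[int, int]) -> pd.DataFrame:
    """Per-session behavior metrics for a multi-session trial table."""
    rows = []
    for (subject, session), tr in trials.groupby(["subject", "session"], sort=True):
        m = compute_session_metrics(tr, grid)
        row = m.to_series()
        row["subject"], row["session"] = subject, session
        row["complete"] = m.complete
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


def group_compare(values_a, values_b, direction: str = "greater"):
    """One-tailed Welch (unequal-variance) t-test of group a vs group b.

    ``direction='greater'`` tests a > b. Returns (t, df, p) with the
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=direction)
    return float(res.statistic), float(res.df), float(res.pvalue)


def retest_reliability(values: pd.DataFrame, measures: list[str] | None = None) -> pd.DataFrame:
    """Test-retest Pearson correlation between days, per measure.

    ``values`` needs columns 'subject', 'day' and one column per measure
    (per-subject per-day values; multiple sessions per day should be
    averaged beforehand). All unordered day pairs with >= 3 common subjects
    are correlated; one row per (measure, day pair).
    """
    if measures is None:
        measures = [c for c in values.columns if c not in ("subject", "day")]
    wide = values.set_index(["subject", "day"])
    days = sorted(values["day"].unique())
    rows = []
    for d1, d2 in combinations(days, 2):
        for m in measures:
            a = wide.xs(d1, level="day")[m]
            b = wide.xs(d2, level="day")[m]
            common = a.index.intersection(b.index)
            common = [s for s in common if np.isfinite(a[s]) and np.isfinite(b[s])]
            if len(common) < 3:
                continue
            r = stats.pearsonr(a[common], b[common]).statistic
            rows.append({"measure": m, "day_a": d1, "day_b": d2, "r": float(r), "n": len(common)})
    return pd.DataFrame(rows)
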