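import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neglect_eeg.behavior import (
    behavior_table,
    compute_session_metrics,
    group_compare,
    laterality_index,
    remove_rt_outliers,
    retest_reliability,
    variability_ratio,
)
from neglect_eeg.synthetic import CohortConfig, make_ground_truth, simulate_snt_session


class TestOutlierRemoval:
    def test_single_pass_removes_exactly_the_outlier(self):
        rts = [500, 510, 490, 505, 495, 2000]
        kept, n_removed, warn = remove_rt_outliers(rts)
        assert n_removed == 1
        assert 2000 not in kept and len(kept) == 5
        assert not warn

    def test_identical_values_untouched(self):
        kept, n_removed, _ = remove_rt_outliers([500.0] * 10)
        assert n_removed == 0 and len(kept) == 10

    def test_infinite_k_is_identity(self):
        kept, n_removed, _ = remove_rt_outliers([1.0, 2.0, 100.0], k=np.inf)
        assert n_removed == 0

    def test_too_few_values_pass_through_with_warning(self):
        kept, n_removed, warn = remove_rt_outliers([400.0, 900.0])
        assert warn and n_removed == 0 and len(kept) == 2


class TestLateralityIndex:
    def test_symmetry_gives_zero(self):
        assert laterality_index(500.0, 500.0) == 0.0

    def test_control_group_worked_example(self):
        # healthy-control hemispace means: LMRT 470 ms, RMRT 484 ms
        assert round(laterality_index(470.0, 484.0), 2) == 0.01

    def test_patient_group_worked_example(self):
        # right-hemisphere-damage hemispace means: LMRT 919 ms, RMRT 695 ms
        assert abs(laterality_index(919.0, 695.0) - (-0.1388)) < 5e-5

    @given(
        a=st.floats(1.0, 5000.0, allow_nan=False),
        b=st.floats(1.0, 5000.0, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetry(self, a, b):
        assert laterality_index(a, b) == pytest.approx(-laterality_index(b, a))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            laterality_index(0.0, 500.0)


class TestVariabilityRatio:
    def test_symmetric_inputs_give_one(self):
        assert variability_ratio(500.0, 120.0, 500.0, 120.0) == 1.0

    def test_hand_arithmetic(self):
        assert variability_ratio(100.0, 200.0, 100.0, 100.0) == 2.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            variability_ratio(100.0, 200.0, 100.0, 0.0)

    @given(
        lm=st.floats(100.0, 1000.0),
        lv=st.floats(1.0, 1e5),
        rm=st.floats(100.0, 1000.0),
        rv=st.floats(1.0, 1e5),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_swap_reciprocity(self, lm, lv, rm, rv):
        f = variability_ratio(lm, lv, rm, rv)
        assert variability_ratio(rm, rv, lm, lv) == pytest.approx(1.0 / f)


def toy_trials(rt_by_col, misses=(), subject="S01", session="S01-d1s1"):
    rows = []
    idx = 0
    for r in range(5):
        for c in range(5):
            rt = rt_by_col(c)
            response = "miss" if (r, c) in misses else "hit"
            rows.append(
                {
                    "subject": subject,
                    "session": session,
                    "day": 1,
                    "trial_index": idx,
                    "row": r,
                    "col": c,
                    "onset_ms": 1000.0,
                    "response": response,
                    "rt_ms": rt if response == "hit" else np.nan,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


class TestSessionMetrics:
    def test_uniform_rts_give_symmetric_metrics(self):
        m = compute_session_metrics(toy_trials(lambda c: 500.0), (5, 5))
        assert m.hit == 100.0
        assert m.li == 0.0
        assert m.f == 1.0

    def test_left_slower_hand_arithmetic(self):
        rng = np.random.default_rng(0)
        jitter = {c: rng.normal(0, 1e-9) for c in range(5)}
        m = compute_session_metrics(
            toy_trials(lambda c: (800.0 if c < 2 else 400.0) + jitter[c]), (5, 5)
        )
        assert m.li == pytest.approx((400.0 - 800.0) / 1200.0, abs=1e-6)

    def test_center_column_excluded_from_lateral_statistics(self):
        base = compute_session_metrics(toy_trials(lambda c: 500.0), (5, 5))
        wild = compute_session_metrics(
            toy_trials(lambda c: 500.0 if c != 2 else 2900.0), (5, 5)
        )
        assert wild.lmrt == base.lmrt and wild.rmrt == base.rmrt
        assert wild.hit == 100.0

    def test_hit_conservation(self):
        m = compute_session_metrics(
            toy_trials(lambda c: 500.0, misses=((0, 0), (1, 4), (2, 2))), (5, 5)
        )
        assert m.hit == pytest.approx(100.0 * 22 / 25)

    def test_even_column_grid_rejected(self):
        t = toy_trials(lambda c: 500.0)
        with pytest.raises(ValueError, match="odd"):
            compute_session_metrics(t[t["col"] < 4], (5, 4))


class TestGroupCompare:
    def test_identical_groups_give_half(self):
        t, df, p = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 0.5

    def test_welch_hand_example(self):
        t, df, p = group_compare([10.0, 11.0, 12.0], [0.0, 1.0, 2.0], "greater")
        assert t == pytest.approx(10.0 * np.sqrt(3.0 / 2.0) / 1.0, rel=1e-9)
        assert p < 0.01

    def test_reversed_direction_is_complement(self):
        _, _, p1 = group_compare([10.0, 11.0, 12.0], [0.0, 1.0, 2.0], "greater")
        _, _, p2 = group_compare([10.0, 11.0, 12.0], [0.0, 1.0, 2.0], "less")
        assert p2 >= 0.99 and p1 + p2 == pytest.approx(1.0)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0], [1.0, 2.0])


class TestTestRetest:
    def frame(self, day2):
        day1 = np.arange(10.0)
        return pd.DataFrame(
            {
                "subject": [f"S{i}" for i in range(10)] * 2,
                "day": [1] * 10 + [2] * 10,
                "m": np.concatenate([day1, day2]),
            }
        )

    def test_identical_days_correlate_perfectly(self):
        table = retest_reliability(self.frame(np.arange(10.0)))
        assert table["r"].iloc[0] == pytest.approx(1.0)

    def test_negated_days_anticorrelate(self):
        table = retest_reliability(self.frame(-np.arange(10.0)))
        assert table["r"].iloc[0] == pytest.approx(-1.0)

    def test_attenuation_under_measurement_noise(self):
        # day2 = day1 + noise at amplitude SNR 3 -> r ~ 1/sqrt(1 + 1/9) = 0.949
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(100):
            day1 = rng.standard_normal(30)
            day2 = day1 + rng.standard_normal(30) / 3.0
            df = pd.DataFrame(
                {
                    "subject": [f"S{i}" for i in range(30)] * 2,
                    "day": [1] * 30 + [2] * 30,
                    "m": np.concatenate([day1, day2]),
                }
            )
            rs.append(retest_reliability(df)["r"].iloc[0])
        assert abs(np.mean(rs) - 1.0 / np.sqrt(1 + 1.0 / 9.0)) < 0.05


def test_estimated_li_recovers_generator_expectation():
    """Mean estimated LI over 200 simulated sessions tracks the planted value."""
    cfg = CohortConfig(
        seed=9, n_rhd_cohort1=1, n_lhd_cohort1=0, n_rhd_cohort2=0, n_controls=1,
        severity_mode="fixed", fixed_severity=0.6, miss_base=0.0, fa_rate=0.0,
        cohort1_days=1, cohort1_sessions_per_day=1,
    )
    truth = make_ground_truth(cfg)
    expected = truth.subjects.set_index("subject").loc["P01", "expected_li"]
    lis = []
    for s in range(200):
        t = simulate_snt_session(cfg, "P01", 1, s, truth)
        m = compute_session_metrics(t, (5, 5))
        lis.append(m.li)
    assert abs(np.mean(lis) - expected) < 0.02


def test_behavior_table_one_row_per_session():
    cfg = CohortConfig(
        seed=2, n_rhd_cohort1=2, n_lhd_cohort1=0, n_rhd_cohort2=0, n_controls=2,
        cohort1_days=1, cohort1_sessions_per_day=2,
    )
    from neglect_eeg.synthetic import simulate_cohort

    ds = simulate_cohort(cfg, eeg_mode="none")
    table = behavior_table(ds.trials, (5, 5))
    assert len(table) == len(ds.sessions)
    assert set(table.columns) >= {"Hit", "LMRT", "RMRT", "LVRT", "RVRT", "LI", "F"}
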