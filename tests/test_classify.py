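import numpy as np
import pandas as pd
import pytest

from neglect_eeg.classify import (
    GaussianDiscriminant,
    ledoit_wolf_covariance,
    loso_cross_validate,
    loso_cross_validate_eeg,
    permutation_null,
    pooled_loso_auc,
    rank_features,
    roc_auc,
    standardized_u,
    transfer_evaluate,
)


class TestStandardizedU:
    def test_hand_arithmetic(self):
        z = standardized_u([1, 2, 3], [4, 5, 6])
        assert abs(z - 4.5 / np.sqrt(9 * 7 / 12.0)) < 1e-12
        assert abs(z - 1.964) < 1e-3

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(8), rng.standard_normal(12)
        assert standardized_u(a, b) == pytest.approx(-standardized_u(b, a))

    def test_null_distribution_is_standard_normal(self):
        # under exchangeability z ~ N(0, 1): mean near 0, |z| < 2 in ~95%
        rng = np.random.default_rng(1)
        zs = np.array(
            [standardized_u(rng.standard_normal(50), rng.standard_normal(50)) for _ in range(200)]
        )
        assert abs(zs.mean()) < 0.2
        assert np.mean(np.abs(zs) < 2.0) >= 0.9

    def test_tie_correction_with_midranks(self):
        # all values tied -> zero variance -> z defined as 0
        assert standardized_u([1, 1, 1], [1, 1, 1]) == 0.0


class TestRanking:
    def test_separating_feature_ranked_first(self):
        rng = np.random.default_rng(2)
        first = 0
        for _ in range(100):
            y = np.repeat([0, 1], 20)
            x = np.column_stack([y + 0.1 * rng.standard_normal(40), rng.standard_normal(40)])
            first += rank_features(x, y, ["signal", "noise"])[0] == "signal"
        assert first >= 99

    def test_constant_feature_ranked_last(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 10)
        x = np.column_stack([np.ones(20), y + 0.1 * rng.standard_normal(20)])
        assert rank_features(x, y, ["const", "signal"]) == ["signal", "const"]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1], 15)
        x = rng.standard_normal((30, 5))
        perm = rng.permutation(30)
        names = list("abcde")
        assert rank_features(x, y, names) == rank_features(x[perm], y[perm], names)


class TestDiscriminant:
    def test_well_separated_classes_learned(self):
        rng = np.random.default_rng(5)
        x = np.vstack([rng.standard_normal((100, 3)), rng.standard_normal((100, 3)) + 6.0])
        y = np.repeat([0, 1], 100)
        model = GaussianDiscriminant().fit(x, y)
        assert (model.predict(x) == y).mean() >= 0.99

    def test_per_class_reduces_to_pooled_when_covariances_equal(self):
        rng = np.random.default_rng(6)
        x = np.vstack([rng.standard_normal((500, 2)), rng.standard_normal((500, 2)) + [2, 0]])
        y = np.repeat([0, 1], 500)
        qda = GaussianDiscriminant("per_class").fit(x, y)
        lda = GaussianDiscriminant("pooled").fit(x, y)
        test = rng.standard_normal((2000, 2)) + [1, 0]
        assert (qda.predict(test) == lda.predict(test)).mean() >= 0.95

    def test_uninformative_feature_is_chance(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((400, 1))
        y = np.repeat([0, 1], 200)
        model = GaussianDiscriminant().fit(x, y)
        assert abs((model.predict(x) == y).mean() - 0.5) < 0.05

    def test_agrees_with_reference_quadratic_discriminant(self):
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        rng = np.random.default_rng(8)
        x = np.vstack(
            [rng.standard_normal((300, 3)), rng.standard_normal((300, 3)) * 2.0 + 1.0]
        )
        y = np.repeat([0, 1], 300)
        ours = GaussianDiscriminant().fit(x, y)
        ref = QuadraticDiscriminantAnalysis(store_covariance=True).fit(x, y)
        agree = (ours.predict(x) == ref.predict(x)).mean()
        assert agree >= 0.98

    def test_matches_sklearn_ledoit_wolf(self):
        from sklearn.covariance import ledoit_wolf

        rng = np.random.default_rng(9)
        for n, d in [(10, 3), (25, 7), (100, 5)]:
            x = rng.standard_normal((n, d)) @ rng.standard_normal((d, d))
            assert np.allclose(ledoit_wolf_covariance(x), ledoit_wolf(x)[0], atol=1e-10)


class TestROC:
    def test_perfect_and_inverted_ordering(self):
        y = np.repeat([0, 1], 10)
        _, auc = roc_auc(np.arange(20.0), y)
        assert auc == 1.0
        _, auc = roc_auc(-np.arange(20.0), y)
        assert auc == 0.0

    def test_auc_equals_normalized_mann_whitney(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            n0, n1 = rng.integers(5, 30, 2)
            y = np.concatenate([np.zeros(n0), np.ones(n1)])
            scores = rng.integers(0, 8, n0 + n1).astype(float)  # with ties
            _, auc = roc_auc(scores, y)
            from scipy.stats import rankdata

            ranks = rankdata(scores)
            u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
            assert auc == pytest.approx(u / (n0 * n1), abs=1e-12)


def feature_frame(rng, n_subjects=8, sessions=3, effect=3.0):
    rows = []
    for i in range(n_subjects):
        label = "patient" if i < n_subjects // 2 else "control"
        shift = effect if label == "patient" else 0.0
        for s in range(sessions):
            feats = rng.standard_normal(5)
            feats[0] += shift
            rows.append(
                {
                    "subject": f"S{i:02d}",
                    "session": f"S{i:02d}-{s}",
                    "label": label,
                    **{f"f{j}": feats[j] for j in range(5)},
                }
            )
    return pd.DataFrame(rows)


FEATURES = [f"f{j}" for j in range(5)]


class TestLOSO:
    def test_strong_effect_classified_and_deterministic(self):
        df = feature_frame(np.random.default_rng(11))
        res = loso_cross_validate(df, FEATURES)
        res2 = loso_cross_validate(df, FEATURES)
        assert res.auc >= 0.95
        assert res.confusion.sum() == len(df)
        assert res.auc_by_n == res2.auc_by_n and res.best_n == res2.best_n

    def test_confusion_rows_match_class_counts(self):
        df = feature_frame(np.random.default_rng(12))
        res = loso_cross_validate(df, FEATURES)
        n_ctl = (df["label"] == "control").sum()
        assert res.confusion[0].sum() == n_ctl
        assert res.confusion[1].sum() == len(df) - n_ctl

    def test_single_informative_feature_monotone_information(self):
        df = feature_frame(np.random.default_rng(13), n_subjects=12, sessions=4)
        res = loso_cross_validate(df, FEATURES)
        assert res.auc_by_n[1] >= max(res.auc_by_n.values()) - 0.05

    def test_fast_path_agrees_with_engine(self):
        df = feature_frame(np.random.default_rng(14), effect=1.0)
        subjects = sorted(df["subject"].unique())
        codes = df["subject"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
        x = df[FEATURES].to_numpy()
        y = (df["label"] == "patient").astype(int).to_numpy()
        for n in (1, 3, 5):
            engine = loso_cross_validate(df, FEATURES, n_features_grid=[n]).auc
            fast = pooled_loso_auc(x, y, codes, n)
            assert fast == pytest.approx(engine, abs=1e-12)

    def test_too_few_subjects_rejected(self):
        df = feature_frame(np.random.default_rng(15), n_subjects=3)
        with pytest.raises(ValueError, match="4 subjects"):
            loso_cross_validate(df, FEATURES)


class TestPermutationNull:
    def test_deterministic_threshold_and_error_on_zero(self):
        df = feature_frame(np.random.default_rng(16), effect=0.0)
        t1, null1 = permutation_null(df, FEATURES, n_perm=30, seed=3, n_features=2)
        t2, _ = permutation_null(df, FEATURES, n_perm=30, seed=3, n_features=2)
        assert t1 == t2
        assert 0.0 <= null1.min() and null1.max() <= 1.0
        with pytest.raises(ValueError, match="n_perm"):
            permutation_null(df, FEATURES, n_perm=0)

    def test_null_centred_at_chance(self):
        df = feature_frame(np.random.default_rng(17), n_subjects=10, effect=0.0)
        _, null = permutation_null(df, FEATURES, n_perm=60, seed=0, n_features=2)
        assert abs(np.mean(null) - 0.5) < 0.1


class TestTransfer:
    def test_sanity_mode_equals_training_accuracy(self):
        df = feature_frame(np.random.default_rng(18))
        res = transfer_evaluate(df, df, FEATURES, n_features=2, allow_overlap=True)
        assert res.accuracy >= 0.9
        assert res.excluded_subjects == []

    def test_overlapping_subjects_dropped_from_training(self):
        rng = np.random.default_rng(19)
        train = feature_frame(rng, n_subjects=8)
        test = feature_frame(rng, n_subjects=8)
        test.loc[:, "subject"] = test["subject"].str.replace("S0", "T0")
        test.iloc[:3, test.columns.get_loc("subject")] = "S00"
        res = transfer_evaluate(train, test, FEATURES, n_features=2)
        assert res.excluded_subjects == ["S00"]

    def test_exchangeable_days_transfer_like_loso(self):
        diffs = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            day1 = feature_frame(rng, n_subjects=10, sessions=3, effect=2.0)
            day2 = feature_frame(rng, n_subjects=10, sessions=3, effect=2.0)
            day2["subject"] = day2["subject"].str.replace("S", "T")
            loso_auc = loso_cross_validate(day1, FEATURES, n_features_grid=[2]).auc
            tr = transfer_evaluate(day1, day2, FEATURES, n_features=2)
            diffs.append(tr.auc - loso_auc)
        assert abs(np.mean(diffs)) < 0.05


class TestEEGLeakage:
    def test_per_fold_basis_ignores_held_out_subject(self, strong_cohort):
        """Corrupting the held-out subject's EEG leaves its training fold's
        SVD basis checksum untouched (anti-leakage sentinel)."""
        res = loso_cross_validate_eeg(strong_cohort, n_features_grid=[1, 3])
        target = sorted(strong_cohort.sessions["subject"])[0]
        corrupted = dict(strong_cohort.recordings)
        for sid, rec in list(corrupted.items()):
            if rec.subject == target:
                corrupted[sid] = rec.with_data(
                    np.random.default_rng(0).standard_normal(rec.data.shape) * 50.0
                )
        res2 = loso_cross_validate_eeg(
            strong_cohort, n_features_grid=[1, 3], recordings=corrupted
        )
        assert (
            res.fold_extras[target]["basis_checksum"]
            == res2.fold_extras[target]["basis_checksum"]
        )
        # folds that train on the corrupted subject do change
        others = [s for s in res.fold_extras if s != target]
        assert any(
            res.fold_extras[s]["basis_checksum"] != res2.fold_extras[s]["basis_checksum"]
            for s in others
        )
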