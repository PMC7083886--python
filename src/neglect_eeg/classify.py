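"""Patient-vs-control discriminant classification.

Features (behavioral measures or EEG-SVD band CVs) are ranked per training
fold by the absolute standardized Mann-Whitney statistic, z-scored with
training statistics, and fed to a Gaussian discriminant with class-specific
covariances ("LDA accounting for different covariance matrices per class",
i.e. a quadratic boundary; a pooled-covariance linear mode is available).
Cross-validation is leave-one-subject-out: every session of one subject
forms the test fold, and everything fitted - including the group-level SVD
basis in EEG mode - is recomputed from the training subjects only.
Significance of the pooled AUC comes from a subject-level label-permutation
null (95th percentile).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score, roc_curve

from .spectral import DEFAULT_BANDS, compute_cv_features
from .svd import fit_group_svd, project_subject, select_components


def standardized_u(x0, x1) -> float:
    """Standardized two-sample Mann-Whitney statistic.

    z = (U - n0 n1 / 2) / sqrt(var), where U counts pairs with x1 > x0
    (midrank ties) and the variance carries the usual tie correction.
    Positive when ``x1`` tends to exceed ``x0``.
    """
    return float(
        standardized_u_matrix(
            np.asarray(x0, dtype=float)[:, None], np.asarray(x1, dtype=float)[:, None]
        )[0]
    )


def standardized_u_matrix(x0: np.ndarray, x1: np.ndarray) -> np.ndarray:
    """Column-wise standardized U for two feature matrices (n0 x d, n1 x d)."""
    n0, n1 = x0.shape[0], x1.shape[0]
    if n0 < 1 or n1 < 1:
        raise ValueError("both samples must be non-empty")
    n = n0 + n1
    z = np.vstack([x0, x1])
    ranks = rankdata(z, axis=0)
    r1 = ranks[n0:].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    srt = np.sort(z, axis=0)
    has_ties = np.any(srt[1:] == srt[:-1], axis=0)
    tie_term = np.zeros(z.shape[1])
    for j in np.flatnonzero(has_ties):
        _, counts = np.unique(z[:, j], return_counts=True)
        tie_term[j] = np.sum(counts**3 - counts)
    var = n0 * n1 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    out = np.zeros(z.shape[1])
    nz = var > 0
    out[nz] = (u[nz] - n0 * n1 / 2.0) / np.sqrt(var[nz])
    return out


def rank_features(x: np.ndarray, y: np.ndarray, names: list[str]) -> list[str]:
    """Features sorted by |standardized U| descending.

    Ties are broken by the (fixed) input column order. ``y`` is binary with
    1 = patient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if (y == 0).sum() < 2 or (y == 1).sum() < 2:
        raise ValueError("need at least 2 rows per class to rank features")
    zvals = standardized_u_matrix(x[y == 0], x[y == 1])
    order = np.argsort(-np.abs(zvals), kind="stable")
    return [names[i] for i in order]


class _ZScaler:
    def fit(self, x: np.ndarray) -> "_ZScaler":
        self.mean_ = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        self.sd_ = sd
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean_) / self.sd_


class GaussianDiscriminant:
    """Gaussian class-conditional classifier with shrunk covariances.

    ``covariance_mode='per_class'`` (default, matching the study's wording)
    yields a quadratic boundary; ``'pooled'`` yields classical LDA. Class
    covariances are Ledoit-Wolf shrunk toward scaled identity, which keeps
    them well-conditioned in folds with few control sessions. Priors are
    equal by default (session counts are imbalanced by design, not by
    prevalence).
    """

    def __init__(self, covariance_mode: str = "per_class", priors: str = "equal"):
        if covariance_mode not in ("per_class", "pooled"):
            raise ValueError("covariance_mode must be 'per_class' or 'pooled'")
        self.covariance_mode = covariance_mode
        self.priors = priors

    def fit(self, x: np.ndarray, y: np.ndarray) -> "GaussianDiscriminant":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        d = x.shape[1]
        means, covs, counts = [], [], []
        for c in self.classes_:
            xc = x[y == c]
            if xc.shape[0] < 2:
                raise ValueError("need at least 2 rows per class")
            means.append(xc.mean(axis=0))
            if xc.shape[0] <= 2 and d > 1:
                cov = np.diag(np.maximum(xc.var(axis=0), 1e-12))
            else:
                cov = ledoit_wolf_covariance(xc)
            covs.append(cov)
            counts.append(xc.shape[0])
        if self.covariance_mode == "pooled":
            pooled = sum(w * c for w, c in zip(counts, covs)) / sum(counts)
            covs = [pooled for _ in covs]
        self.means_ = np.asarray(means)
        self._chol = []
        self._logdet = []
        for cov in covs:
            cov = cov + 1e-9 * np.trace(cov) / d * np.eye(d) + 1e-12 * np.eye(d)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    "singular class covariance after regularization; "
                    "reduce the number of features"
                ) from err
            self._chol.append(chol)
            self._logdet.append(2.0 * np.sum(np.log(np.diag(chol))))
        if self.priors == "equal":
            self.log_priors_ = np.full(len(self.classes_), -np.log(len(self.classes_)))
        else:
            p = np.asarray(counts, dtype=float) / sum(counts)
            self.log_priors_ = np.log(p)
        return self

    def log_likelihood(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.empty((x.shape[0], len(self.classes_)))
        for i, (mu, chol, logdet) in enumerate(zip(self.means_, self._chol, self._logdet)):
            diff = x - mu
            w = np.linalg.solve(chol, diff.T)
            out[:, i] = -0.5 * (np.sum(w**2, axis=0) + logdet)
        return out

    def decision_score(self, x: np.ndarray) -> np.ndarray:
        """Posterior log-ratio of the last class over the first (binary)."""
        ll = self.log_likelihood(x)
        return ll[:, -1] - ll[:, 0]

    def predict(self, x: np.ndarray) -> np.ndarray:
        ll = self.log_likelihood(x) + self.log_priors_
        return self.classes_[np.argmax(ll, axis=1)]


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """Empirical ROC curve and trapezoidal AUC (ties at midpoint).

    The AUC equals the normalized Mann-Whitney U of the scores.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(labels, scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return curve, float(roc_auc_score(labels, scores))


@dataclass
class CVResult:
    """Leave-one-subject-out result bundle."""

    auc_by_n: dict[int, float]
    best_n: int
    auc: float
    mean_accuracy: float
    sd_accuracy: float
    confusion: np.ndarray  # rows: true (control, patient); cols: predicted
    scores: pd.DataFrame  # per-session scores/predictions at best_n
    skipped_folds: list[str] = field(default_factory=list)
    fold_extras: dict[str, dict] = field(default_factory=dict)
    permutation_threshold: float | None = None
    null_aucs: np.ndarray | None = None


def _loso_engine(
    subjects: list[str],
    provider,
    n_features_grid: list[int] | None,
    covariance_mode: str,
) -> CVResult:
    """Generic LOSO loop over a per-fold feature provider.

    ``provider(held_out)`` returns (x_train, y_train, x_test, y_test,
    feature_names, test_sessions, extras); everything fold-specific (SVD
    basis, features, normalization, ranking) happens inside it or here,
    never on the held-out subject's data.
    """
    per_n_scores: dict[int, list] = {}
    per_fold_rows = []
    skipped = []
    extras_by_subject = {}
    for held_out in subjects:
        x_tr, y_tr, x_te, y_te, names, test_sessions, extras = provider(held_out)
        extras_by_subject[held_out] = extras
        if len(np.unique(y_tr)) < 2:
            skipped.append(held_out)
            continue
        grid = n_features_grid or list(range(1, len(names) + 1))
        order = rank_features(x_tr, y_tr, names)
        name_idx = {nm: i for i, nm in enumerate(names)}
        for n in grid:
            cols = [name_idx[nm] for nm in order[:n]]
            scaler = _ZScaler().fit(x_tr[:, cols])
            model = GaussianDiscriminant(covariance_mode=covariance_mode).fit(
                scaler.transform(x_tr[:, cols]), y_tr
            )
            z_te = scaler.transform(x_te[:, cols])
            per_n_scores.setdefault(n, []).append(
                (held_out, test_sessions, y_te, model.decision_score(z_te), model.predict(z_te))
            )
    if not per_n_scores:
        raise ValueError("no usable folds")
    auc_by_n = {}
    for n, folds in per_n_scores.items():
        y_all = np.concatenate([f[2] for f in folds])
        s_all = np.concatenate([f[3] for f in folds])
        auc_by_n[n] = float(roc_auc_score(y_all, s_all)) if len(np.unique(y_all)) == 2 else np.nan
    best_n = min(auc_by_n, key=lambda n: (-auc_by_n[n], n))
    folds = per_n_scores[best_n]
    accs = [float(np.mean(f[4] == f[2])) for f in folds]
    confusion = np.zeros((2, 2), dtype=int)
    rows = []
    for held_out, sessions, y_te, sc, pred in folds:
        for sess, yt, s, p in zip(sessions, y_te, sc, pred):
            confusion[int(yt), int(p)] += 1
            rows.append(
                {"subject": held_out, "session": sess, "y_true": int(yt),
                 "score": float(s), "pred": int(p)}
            )
    y_all = np.concatenate([f[2] for f in folds])
    s_all = np.concatenate([f[3] for f in folds])
    return CVResult(
        auc_by_n=auc_by_n,
        best_n=best_n,
        auc=float(roc_auc_score(y_all, s_all)),
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs)),
        confusion=confusion,
        scores=pd.DataFrame(rows),
        skipped_folds=skipped,
        fold_extras=extras_by_subject,
    )


def _label_vector(df: pd.DataFrame, label_col: str) -> np.ndarray:
    labels = df[label_col].to_numpy()
    if labels.dtype.kind in "OU":
        return (labels == "patient").astype(int)
    return labels.astype(int)


def loso_cross_validate(
    features: pd.DataFrame,
    feature_cols: list[str],
    label_col: str = "label",
    subject_col: str = "subject",
    session_col: str = "session",
    n_features_grid: list[int] | None = None,
    covariance_mode: str = "per_class",
) -> CVResult:
    """LOSO classification on a precomputed per-session feature table.

    Suitable for behavioral measures (which involve no cross-subject
    fitting); z-scoring and feature ranking are still refit per fold from
    the training rows only.
    """
    subjects = sorted(features[subject_col].unique())
    if len(subjects) < 4:
        raise ValueError("need at least 4 subjects for LOSO")
    y = _label_vector(features, label_col)
    x = features[feature_cols].to_numpy(dtype=float)
    sess = features[session_col].to_numpy()
    subj = features[subject_col].to_numpy()

    def provider(held_out):
        te = subj == held_out
        return (
            x[~te], y[~te], x[te], y[te], list(feature_cols), list(sess[te]), {}
        )

    return _loso_engine(subjects, provider, n_features_grid, covariance_mode)


def loso_cross_validate_eeg(
    dataset,
    k: int = 5,
    bands=DEFAULT_BANDS,
    freqs=None,
    min_valid: int = 100,
    n_features_grid: list[int] | None = None,
    covariance_mode: str = "per_class",
    include_lhd: bool = False,
    recordings: dict | None = None,
) -> CVResult:
    """LOSO on EEG-SVD CV features with per-fold basis refit.

    For every fold the group-level topographies are refit on the training
    subjects' recordings only; training and test CV features are then
    recomputed by projection onto that fold's basis, so the held-out
    subject's EEG never influences the maps (each fold's basis checksum is
    recorded for leakage audits).
    """
    sessions = dataset.sessions
    if not include_lhd:
        sessions = sessions[sessions["diagnosis"] != "LHD"]
    recs = recordings if recordings is not None else dataset.recordings
    sess_ids = list(sessions["session"])
    subj_of = dict(zip(sessions["session"], sessions["subject"]))
    y_of = {
        s: int(d != "control")
        for s, d in zip(sessions["session"], sessions["diagnosis"])
    }
    subjects = sorted(sessions["subject"].unique())
    if len(subjects) < 4:
        raise ValueError("need at least 4 subjects for LOSO")

    def provider(held_out):
        train_ids = [s for s in sess_ids if subj_of[s] != held_out]
        test_ids = [s for s in sess_ids if subj_of[s] == held_out]
        basis = select_components(fit_group_svd([recs[s] for s in train_ids]), k=k)

        def feat(sid):
            cv = compute_cv_features(
                project_subject(recs[sid], basis), bands=bands, freqs=freqs, min_valid=min_valid
            )
            return cv.to_series()

        tr = pd.DataFrame([feat(s) for s in train_ids])
        te = pd.DataFrame([feat(s) for s in test_ids])
        names = list(tr.columns)
        return (
            tr.to_numpy(),
            np.array([y_of[s] for s in train_ids]),
            te.to_numpy(),
            np.array([y_of[s] for s in test_ids]),
            names,
            test_ids,
            {"basis_checksum": basis.checksum()},
        )

    return _loso_engine(subjects, provider, n_features_grid, covariance_mode)


def ledoit_wolf_covariance(x: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf covariance: empirical cov shrunk toward scaled identity.

    Closed-form optimal shrinkage intensity; agrees with
    sklearn.covariance.ledoit_wolf (cross-checked in the test suite) but
    without per-call validation overhead, which matters inside permutation
    loops over tiny folds.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, d = x.shape
    xc = x - x.mean(axis=0)
    s = xc.T @ xc / n
    mu = np.trace(s) / d
    delta2 = np.sum((s - mu * np.eye(d)) ** 2) / d
    if delta2 <= 0:
        return s
    x2 = xc**2
    beta2 = np.sum(x2.T @ x2 / n - s**2) / (d * n)
    beta2 = min(beta2, delta2)
    shrink = beta2 / delta2
    return shrink * mu * np.eye(d) + (1.0 - shrink) * s


def _auc_from_scores(scores: np.ndarray, y: np.ndarray) -> float:
    # midrank Mann-Whitney form; identical to the trapezoidal ROC AUC
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        return np.nan
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def _lw_cov(x: np.ndarray) -> np.ndarray:
    d = x.shape[1]
    if x.shape[0] <= 2 and d > 1:
        cov = np.diag(np.maximum(x.var(axis=0), 1e-12))
    else:
        cov = ledoit_wolf_covariance(x)
    return cov + (1e-9 * np.trace(cov) / d + 1e-12) * np.eye(d)


def pooled_loso_auc(
    x: np.ndarray,
    y: np.ndarray,
    subject_codes: np.ndarray,
    n_features: int,
    covariance_mode: str = "per_class",
) -> float:
    """Pooled LOSO AUC at a fixed feature count (lean numpy path).

    Same procedure as :func:`loso_cross_validate` - per-fold ranking,
    z-scoring and Gaussian discriminant scoring - without the bookkeeping;
    used inside permutation loops where thousands of LOSO runs are needed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    scores = np.full(y.size, np.nan)
    for code in np.unique(subject_codes):
        te = subject_codes == code
        ytr = y[~te]
        if ytr.min() == ytr.max():
            continue
        xtr = x[~te]
        z = standardized_u_matrix(xtr[ytr == 0], xtr[ytr == 1])
        cols = np.argsort(-np.abs(z), kind="stable")[:n_features]
        xt = xtr[:, cols]
        mean = xt.mean(axis=0)
        sd = xt.std(axis=0)
        sd[sd == 0] = 1.0
        xt = (xt - mean) / sd
        xe = (x[te][:, cols] - mean) / sd
        ll = np.empty((xe.shape[0], 2))
        pooled_cov = None
        if covariance_mode == "pooled":
            resid = xt.copy()
            for c in (0, 1):
                resid[ytr == c] -= xt[ytr == c].mean(axis=0)
            pooled_cov = _lw_cov(resid)
        for i, c in enumerate((0, 1)):
            xc = xt[ytr == c]
            cov = pooled_cov if pooled_cov is not None else _lw_cov(xc)
            chol = np.linalg.cholesky(cov)
            w = np.linalg.solve(chol, (xe - xc.mean(axis=0)).T)
            ll[:, i] = -0.5 * (np.sum(w**2, axis=0) + 2.0 * np.sum(np.log(np.diag(chol))))
        scores[te] = ll[:, 1] - ll[:, 0]
    ok = np.isfinite(scores)
    return _auc_from_scores(scores[ok], y[ok])


def permutation_null(
    features: pd.DataFrame,
    feature_cols: list[str],
    n_perm: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
    n_features: int | None = None,
    label_col: str = "label",
    subject_col: str = "subject",
    session_col: str = "session",
    covariance_mode: str = "per_class",
) -> tuple[float, np.ndarray]:
    """Subject-level label-permutation null of the pooled LOSO AUC.

    All sessions of a subject keep one permuted label, preserving the
    within-subject dependence; the threshold is the stated percentile of
    the null AUC distribution. ``n_features`` fixes the feature count per
    permutation (the scaled-down option); None reruns the full sequential
    selection.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = sorted(features[subject_col].unique())
    y_subj = {
        s: features.loc[features[subject_col] == s, label_col].iloc[0] for s in subjects
    }
    base_labels = np.array([int(v == "patient") if isinstance(v, str) else int(v)
                            for v in (y_subj[s] for s in subjects)])
    x = features[feature_cols].to_numpy(dtype=float)
    codes = features[subject_col].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    null_aucs = np.empty(n_perm)
    for p in range(n_perm):
        permuted = rng.permutation(base_labels)
        y = permuted[codes]
        if n_features is not None:
            null_aucs[p] = pooled_loso_auc(
                x, y, codes, n_features, covariance_mode=covariance_mode
            )
        else:
            df = features.copy()
            df[label_col] = y
            res = loso_cross_validate(
                df,
                feature_cols,
                label_col=label_col,
                subject_col=subject_col,
                session_col=session_col,
                covariance_mode=covariance_mode,
            )
            null_aucs[p] = res.auc
    return float(np.percentile(null_aucs, percentile)), null_aucs


@dataclass
class TransferResult:
    accuracy: float
    auc: float
    confusion: np.ndarray
    n_features: int
    excluded_subjects: list[str]
    curve: dict[int, float]


def transfer_evaluate(
    train: pd.DataFrame,
    test: pd.DataFrame,
    feature_cols: list[str],
    n_features: int | None = None,
    label_col: str = "label",
    subject_col: str = "subject",
    covariance_mode: str = "per_class",
    allow_overlap: bool = False,
) -> TransferResult:
    """Train on one set of sessions, evaluate on a disjoint one.

    Subjects appearing in both sets are dropped from training (unless
    ``allow_overlap``, a sanity mode for test=train checks). Normalization,
    ranking and the model come from the training set only. If
    ``n_features`` is None the count is chosen by LOSO on the training set.
    """
    excluded: list[str] = []
    if not allow_overlap:
        overlap = set(train[subject_col]) & set(test[subject_col])
        if overlap:
            excluded = sorted(overlap)
            train = train[~train[subject_col].isin(overlap)]
    y_tr = _label_vector(train, label_col)
    y_te = _label_vector(test, label_col)
    x_tr = train[feature_cols].to_numpy(dtype=float)
    x_te = test[feature_cols].to_numpy(dtype=float)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set lost a class after overlap exclusion")
    order = rank_features(x_tr, y_tr, list(feature_cols))
    name_idx = {nm: i for i, nm in enumerate(feature_cols)}
    if n_features is None:
        inner = loso_cross_validate(
            train, feature_cols, label_col=label_col, subject_col=subject_col,
            covariance_mode=covariance_mode,
        )
        n_features = inner.best_n
    curve = {}
    for n in range(1, len(feature_cols) + 1):
        cols = [name_idx[nm] for nm in order[:n]]
        scaler = _ZScaler().fit(x_tr[:, cols])
        model = GaussianDiscriminant(covariance_mode=covariance_mode).fit(
            scaler.transform(x_tr[:, cols]), y_tr
        )
        sc = model.decision_score(scaler.transform(x_te[:, cols]))
        curve[n] = float(roc_auc_score(y_te, sc)) if len(np.unique(y_te)) == 2 else np.nan
    cols = [name_idx[nm] for nm in order[:n_features]]
    scaler = _ZScaler().fit(x_tr[:, cols])
    model = GaussianDiscriminant(covariance_mode=covariance_mode).fit(
        scaler.transform(x_tr[:, cols]), y_tr
    )
    z_te = scaler.transform(x_te[:, cols])
    pred = model.predict(z_te)
    sc = model.decision_score(z_te)
    confusion = np.zeros((2, 2), dtype=int)
    for yt, p in zip(y_te, pred):
        confusion[int(yt), int(p)] += 1
    auc = float(roc_auc_score(y_te, sc)) if len(np.unique(y_te)) == 2 else np.nan
    return TransferResult(
        accuracy=float(np.mean(pred == y_te)),
        auc=auc,
        confusion=confusion,
        n_features=n_features,
        excluded_subjects=excluded,
        curve=curve,
    )
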