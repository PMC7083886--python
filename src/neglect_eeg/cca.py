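"""Canonical correlation severity analysis and staging.

A CCA between the session-level laterality indices X = (LI, F) and the
brain features Y (the 20 component x band CVs, or the 4 P3/P4 theta/alpha
CVs) yields canonical weight pairs (a, b) maximizing corr(a'X, b'Y);
significance of the first canonical correlation is assessed against a
subject-level permutation null (99th percentile). The behavioral canonical
scores U are clustered with k-means (k = 3) into no/mild/severe neglect
stages, validated against an external covariate, and a three-class
Gaussian discriminant on the brain features - the whole CCA -> k-means ->
classifier chain refit per leave-one-subject-out fold - tests whether the
EEG features can recover the stage of an unseen patient. Healthy controls
never enter these analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.cluster import KMeans

from .behavior import group_compare
from .classify import GaussianDiscriminant, _ZScaler

STAGE_NAMES = ("no", "mild", "severe")


@dataclass
class CCAModel:
    """Canonical weights, correlations and scores.

    Weights apply to column-standardized variables; U and V have unit
    variance over the fitted sessions. The first component is oriented so
    that higher U means more severe neglect (U correlates non-negatively
    with -LI, LI being the first X column by convention).
    """

    x_weights: np.ndarray  # n_x x K, on the standardized scale
    y_weights: np.ndarray  # n_y x K
    rhos: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    u: np.ndarray
    v: np.ndarray
    regularization: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.rhos < -1e-9) or np.any(self.rhos > 1 + 1e-9):
            raise ValueError("canonical correlations must lie in [0, 1]")
        if np.any(np.diff(self.rhos) > 1e-9):
            raise ValueError("canonical correlations must be non-increasing")

    def transform_x(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(x) - self.x_mean) / self.x_sd @ self.x_weights

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(y) - self.y_mean) / self.y_sd @ self.y_weights

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.round(self.x_weights, 10).tobytes())
        h.update(np.round(self.y_weights, 10).tobytes())
        h.update(np.round(self.rhos, 10).tobytes())
        return h.hexdigest()


def _standardize(m: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (m - mean) / sd, mean, sd


def fit_cca(x: np.ndarray, y: np.ndarray, regularization: float = 0.0) -> CCAModel:
    """Classical CCA via Cholesky whitening and SVD.

    If a covariance block is rank-deficient a small ridge is added and
    recorded on the model. Requires more sessions than Y columns plus two.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if n <= y.shape[1] + 2:
        raise ValueError(f"need more than {y.shape[1] + 2} sessions for {y.shape[1]} Y columns")
    xs, x_mean, x_sd = _standardize(x)
    ys, y_mean, y_sd = _standardize(y)
    cxx = xs.T @ xs / (n - 1)
    cyy = ys.T @ ys / (n - 1)
    cxy = xs.T @ ys / (n - 1)
    reg = regularization
    for attempt in range(6):
        try:
            lx = np.linalg.cholesky(cxx + reg * np.eye(cxx.shape[0]))
            ly = np.linalg.cholesky(cyy + reg * np.eye(cyy.shape[0]))
            break
        except np.linalg.LinAlgError:
            reg = max(reg * 10.0, 1e-8)
    else:
        raise np.linalg.LinAlgError("covariance blocks not positive definite")
    m = linalg.solve_triangular(lx, cxy, lower=True)
    m = linalg.solve_triangular(ly, m.T, lower=True).T
    p, d, qt = np.linalg.svd(m, full_matrices=False)
    a = linalg.solve_triangular(lx.T, p, lower=False)
    b = linalg.solve_triangular(ly.T, qt.T, lower=False)
    rhos = np.clip(d, 0.0, 1.0)
    # orientation: component 1 severity-positive (corr(U, LI) <= 0)
    u = xs @ a
    if np.corrcoef(u[:, 0], xs[:, 0])[0, 1] > 0:
        a[:, 0] *= -1.0
        b[:, 0] *= -1.0
    for j in range(1, a.shape[1]):
        if a[np.argmax(np.abs(a[:, j])), j] < 0:
            a[:, j] *= -1.0
            b[:, j] *= -1.0
    u = xs @ a
    v = ys @ b
    return CCAModel(
        x_weights=a, y_weights=b, rhos=rhos,
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd,
        u=u, v=v, regularization=reg,
    )


def permutation_significance(
    x: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    n_perm: int = 1000,
    percentile: float = 99.0,
    seed: int = 0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Subject-level permutation null of the first canonical correlation.

    Whole subjects' Y blocks are shuffled against the X rows (sessions of a
    subject move together); returns (threshold, significant-component
    flags, null rho_1 values).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    model = fit_cca(x, y)
    order = pd.unique(subjects)
    blocks = [np.flatnonzero(subjects == s) for s in order]
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(len(blocks))
        rows = np.concatenate([blocks[i] for i in perm])
        null[p] = fit_cca(x, y[rows]).rhos[0]
    threshold = float(np.percentile(null, percentile))
    return threshold, model.rhos > threshold, null


@dataclass
class SeverityClusters:
    """k = 3 staging of behavioral canonical scores.

    Cluster ids are ordered by centroid on the severity-oriented U axis and
    labeled no / mild / severe neglect.
    """

    labels: np.ndarray  # 0 = no, 1 = mild, 2 = severe
    centroids: np.ndarray  # sorted ascending on U
    counts: np.ndarray

    def __post_init__(self) -> None:
        if len(np.unique(self.labels)) != 3:
            raise ValueError("staging requires exactly 3 non-empty clusters")

    def assign(self, u: np.ndarray) -> np.ndarray:
        """Nearest-centroid stage for new canonical scores."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        return np.argmin(np.abs(u[:, None] - self.centroids[None, :]), axis=1)


def stage_severity(u: np.ndarray, seed: int = 0, n_restarts: int = 50) -> SeverityClusters:
    """k-means (k = 3, k-means++ with ``n_restarts`` restarts) on the U scores."""
    u = np.asarray(u, dtype=float).ravel()
    if u.size < 3:
        raise ValueError("need at least 3 sessions to stage severity")
    if np.ptp(u) == 0:
        raise ValueError("degenerate canonical scores (all identical); cannot cluster")
    km = KMeans(n_clusters=3, n_init=n_restarts, random_state=seed).fit(u[:, None])
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    relabel = np.empty(3, dtype=int)
    relabel[order] = np.arange(3)
    labels = relabel[km.labels_]
    counts = np.bincount(labels, minlength=3)
    if np.any(counts == 0):
        raise ValueError("k-means produced an empty cluster; more data needed")
    return SeverityClusters(labels=labels, centroids=centers[order], counts=counts)


def validate_clusters_external(
    patient_stages: pd.Series, covariate: pd.Series
) -> pd.DataFrame:
    """One-tailed Welch tests that worse stages score lower on a covariate.

    ``patient_stages`` maps patient -> stage id (0/1/2); ``covariate`` maps
    patient -> external score not used in clustering (the synthetic
    paper-test score stands in for the paper-and-pencil battery). Tests
    severe < no, severe < mild, mild < no; pairs with fewer than 2 patients
    per side are flagged missing instead of crashing.
    """
    rows = []
    for worse, better in ((2, 0), (2, 1), (1, 0)):
        a = covariate[patient_stages[patient_stages == worse].index.intersection(covariate.index)]
        b = covariate[patient_stages[patient_stages == better].index.intersection(covariate.index)]
        row = {"worse": STAGE_NAMES[worse], "better": STAGE_NAMES[better],
               "n_worse": len(a), "n_better": len(b)}
        if len(a) < 2 or len(b) < 2:
            row.update({"t": np.nan, "df": np.nan, "p": np.nan, "missing": True})
        else:
            t, df, p = group_compare(b, a, direction="greater")  # better > worse
            row.update({"t": t, "df": df, "p": p, "missing": False})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SeverityCVResult:
    confusion: np.ndarray  # 3 x 3, rows = reference stage, cols = predicted
    per_class_accuracy: np.ndarray
    mean_per_class_accuracy: float
    best_n: int
    accuracy_by_n: dict[int, float]
    chance_level: float = 1.0 / 3.0
    skipped_folds: list[str] = field(default_factory=list)
    fold_cca_checksums: dict[str, str] = field(default_factory=dict)


def loso_severity_classification(
    behavior: pd.DataFrame,
    brain: pd.DataFrame,
    behavior_cols: tuple[str, str] = ("LI", "F"),
    brain_cols: list[str] | None = None,
    subject_col: str = "subject",
    n_features_grid: list[int] | None = None,
    seed: int = 0,
    n_perm_cca: int = 0,
) -> SeverityCVResult:
    """Three-class severity staging of unseen patients.

    Per fold (one patient held out): fit CCA on the training sessions,
    stage the training U scores with k-means, rank brain features by |b| of
    the first canonical component, train a three-class Gaussian
    discriminant on them, and classify the held-out sessions. The held-out
    reference stage comes from projecting its *behavior* onto the training
    canonical axis and taking the nearest training centroid; its brain data
    never touch the fold's fitting.
    """
    if brain_cols is None:
        brain_cols = [c for c in brain.columns if c not in (subject_col, "session")]
    subjects = sorted(behavior[subject_col].unique())
    if len(subjects) < 6:
        raise ValueError("need at least 6 patients for severity LOSO")
    x_all = behavior[list(behavior_cols)].to_numpy(dtype=float)
    y_all = brain[brain_cols].to_numpy(dtype=float)
    subj = behavior[subject_col].to_numpy()

    per_n: dict[int, list] = {}
    skipped = []
    checksums = {}
    for held_out in subjects:
        te = subj == held_out
        x_tr, y_tr = x_all[~te], y_all[~te]
        x_te, y_te = x_all[te], y_all[te]
        model = fit_cca(x_tr, y_tr)
        checksums[held_out] = model.checksum()
        stages = stage_severity(model.u[:, 0], seed=seed)
        if np.any(np.bincount(stages.labels, minlength=3) < 2):
            skipped.append(held_out)
            continue
        ref = stages.assign(model.transform_x(x_te)[:, 0])
        order = np.argsort(-np.abs(model.y_weights[:, 0]), kind="stable")
        grid = n_features_grid or list(range(1, len(brain_cols) + 1))
        for n in grid:
            cols = order[:n]
            scaler = _ZScaler().fit(y_tr[:, cols])
            try:
                clf = GaussianDiscriminant().fit(scaler.transform(y_tr[:, cols]), stages.labels)
            except (ValueError, np.linalg.LinAlgError):
                continue
            pred = clf.predict(scaler.transform(y_te[:, cols]))
            per_n.setdefault(n, []).append((held_out, ref, pred))
    if not per_n:
        raise ValueError("no usable folds")

    def macro_acc(folds):
        conf = np.zeros((3, 3), dtype=int)
        for _, ref, pred in folds:
            for r, p in zip(ref, pred):
                conf[int(r), int(p)] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            rec = np.diag(conf) / conf.sum(axis=1)
        return float(np.nanmean(rec)), conf, rec

    accuracy_by_n = {n: macro_acc(folds)[0] for n, folds in per_n.items()}
    best_n = min(accuracy_by_n, key=lambda n: (-accuracy_by_n[n], n))
    mean_acc, conf, rec = macro_acc(per_n[best_n])
    return SeverityCVResult(
        confusion=conf,
        per_class_accuracy=rec,
        mean_per_class_accuracy=mean_acc,
        best_n=best_n,
        accuracy_by_n=accuracy_by_n,
        skipped_folds=skipped,
        fold_cca_checksums=checksums,
    )
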