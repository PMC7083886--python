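"""Group-level SVD topography extraction.

The channel x time matrix of preprocessed EEG, concatenated in time across
sessions and participants, is factorized as E = M S N^T. The left-singular
vectors (columns of M) are the group-level topographical maps; individual
component time courses are obtained by projecting each session onto the
retained maps. Reproducibility is assessed by split-half fits matched with
the Hungarian algorithm.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .montage import Montage
from .recording import Recording


@dataclass
class TopographyBasis:
    """Group-level topographical maps with singular values and variance shares.

    ``maps`` has orthonormal columns (channels x K). ``singular_values``,
    ``explained_pct`` and ``cumulative_pct`` always refer to the full
    decomposition (length = channel count), regardless of truncation.
    """

    maps: np.ndarray
    singular_values: np.ndarray
    explained_pct: np.ndarray
    cumulative_pct: np.ndarray
    montage: Montage
    fitted_on: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        gram = self.maps.T @ self.maps
        if not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise ValueError("topography columns must be orthonormal within 1e-8")
        if np.any(self.explained_pct < -1e-12):
            raise ValueError("explained variance must be non-negative")
        if abs(self.explained_pct.sum() - 100.0) > 1e-6:
            raise ValueError("explained variance must sum to 100")
        if np.any(np.diff(self.cumulative_pct) < -1e-9):
            raise ValueError("cumulative explained variance must be non-decreasing")

    @property
    def k(self) -> int:
        return self.maps.shape[1]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[0]

    def checksum(self) -> str:
        """Stable fingerprint of the retained maps (leakage sentinel)."""
        return hashlib.sha256(np.round(self.maps, 10).tobytes()).hexdigest()


@dataclass
class ComponentTimecourses:
    """Per-session component time courses (K x samples)."""

    subject: str
    session: str
    rate: float
    courses: np.ndarray
    segment_boundaries: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.courses = np.asarray(self.courses, dtype=float)
        if not np.all(np.isfinite(self.courses)):
            raise ValueError("time courses must be finite")

    @property
    def k(self) -> int:
        return self.courses.shape[0]


def _fix_signs(maps: np.ndarray) -> np.ndarray:
    """Orient each map so its largest-magnitude loading is positive."""
    idx = np.argmax(np.abs(maps), axis=0)
    signs = np.sign(maps[idx, np.arange(maps.shape[1])])
    signs[signs == 0] = 1.0
    return maps * signs


def explained_variance(singular_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-component and cumulative explained variance (percent).

    VAR_i = S_i^2 / sum_j S_j^2 * 100; the cumulative sequence is the running
    sum, which is the quantity the 80%-of-variance selection rule uses.
    """
    s = np.asarray(singular_values, dtype=float)
    if np.any(s < 0):
        raise ValueError("singular values must be non-negative")
    if np.any(np.diff(s) > 1e-12):
        raise ValueError("singular values must be non-increasing")
    power = s**2
    total = power.sum()
    if total <= 0:
        raise ValueError("all singular values are zero")
    per = power / total * 100.0
    return per, np.cumsum(per)


def fit_group_svd(sessions: list[Recording]) -> TopographyBasis:
    """Fit the full group-level SVD basis on time-concatenated recordings.

    Computed from the channel-space Gram matrix (channel count is small and
    the time dimension can run to millions of samples); right-singular
    vectors are not retained, individual time courses come from projection.
    """
    if not sessions:
        raise ValueError("no sessions supplied")
    montage = sessions[0].montage
    rate = sessions[0].rate
    for rec in sessions:
        if rec.montage != montage:
            raise ValueError("all sessions must share one montage")
        if rec.rate != rate:
            raise ValueError("all sessions must share one sampling rate")
    data = np.hstack([rec.data for rec in sessions])
    if data.shape[1] < data.shape[0]:
        raise ValueError("need at least as many samples as channels")
    u, s, _ = np.linalg.svd(data, full_matrices=False)
    maps = _fix_signs(u)
    per, cum = explained_variance(s)
    return TopographyBasis(
        maps=maps,
        singular_values=s,
        explained_pct=per,
        cumulative_pct=cum,
        montage=montage,
        fitted_on=[f"{r.subject}/{r.session}" for r in sessions],
    )


def select_components(
    basis: TopographyBasis,
    k: int | None = 5,
    cumulative_threshold: float | None = None,
) -> TopographyBasis:
    """Truncate a basis to K components.

    Default is a fixed K = 5; alternatively the smallest K whose cumulative
    explained variance reaches ``cumulative_threshold`` percent.
    """
    if cumulative_threshold is not None:
        if not 0 < cumulative_threshold <= 100:
            raise ValueError("cumulative threshold must be in (0, 100]")
        k = int(np.searchsorted(basis.cumulative_pct, cumulative_threshold - 1e-9) + 1)
    if k is None:
        raise ValueError("either k or cumulative_threshold is required")
    if not 1 <= k <= basis.maps.shape[1]:
        raise ValueError(f"k must be in [1, {basis.maps.shape[1]}]")
    return TopographyBasis(
        maps=basis.maps[:, :k],
        singular_values=basis.singular_values,
        explained_pct=basis.explained_pct,
        cumulative_pct=basis.cumulative_pct,
        montage=basis.montage,
        fitted_on=list(basis.fitted_on),
    )


def project_subject(rec: Recording, basis: TopographyBasis) -> ComponentTimecourses:
    """Project one session onto the group-level maps: courses = M^T E."""
    if rec.montage != basis.montage:
        raise ValueError("recording montage does not match basis montage")
    return ComponentTimecourses(
        subject=rec.subject,
        session=rec.session,
        rate=rec.rate,
        courses=basis.maps.T @ rec.data,
        segment_boundaries=rec.segment_boundaries.copy(),
    )


def match_components(
    basis_a: TopographyBasis, basis_b: TopographyBasis
) -> tuple[np.ndarray, np.ndarray]:
    """Optimally pair the maps of two bases (Hungarian algorithm).

    The assignment minimizes sum(1 - |Pearson r|) over map pairs; the sign
    ambiguity of the SVD is absorbed by matching on |r|. Returns the column
    of ``basis_b`` matched to each column of ``basis_a`` and the |r| values.
    """
    if basis_a.montage != basis_b.montage:
        raise ValueError("bases must share one montage")
    if basis_a.k != basis_b.k:
        raise ValueError("bases must have the same number of components")
    a = basis_a.maps - basis_a.maps.mean(axis=0)
    b = basis_b.maps - basis_b.maps.mean(axis=0)
    a /= np.linalg.norm(a, axis=0)
    b /= np.linalg.norm(b, axis=0)
    corr = a.T @ b
    rows, cols = linear_sum_assignment(1.0 - np.abs(corr))
    return cols, np.abs(corr[rows, cols])


def split_half_reproducibility(
    sessions: list[Recording],
    n_splits: int = 10,
    seed: int = 0,
    k: int = 5,
) -> pd.DataFrame:
    """Split-half reproducibility of the first ``k`` group-level maps.

    Subjects (with all their sessions) are randomly split into two halves;
    a basis is fitted per half, truncated to ``k``, matched, and the
    per-component |r| recorded. Returns a tidy table with one row per
    (split, component).
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    subjects = sorted({rec.subject for rec in sessions})
    if len(subjects) < 4:
        raise ValueError("need at least 4 subjects for split-half analysis")
    rng = np.random.default_rng(seed)
    rows = []
    for split in range(n_splits):
        perm = rng.permutation(subjects)
        half_a = set(perm[: len(subjects) // 2])
        basis_a = select_components(
            fit_group_svd([r for r in sessions if r.subject in half_a]), k=k
        )
        basis_b = select_components(
            fit_group_svd([r for r in sessions if r.subject not in half_a]), k=k
        )
        _, abs_r = match_components(basis_a, basis_b)
        for comp, r in enumerate(abs_r, start=1):
            rows.append({"split": split, "component": comp, "abs_corr": float(r)})
    return pd.DataFrame(rows)
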