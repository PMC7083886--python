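"""Morlet wavelet band power and coefficient-of-variation features.

Each component time course (or raw channel) is convolved with a 3-cycle
complex Morlet wavelet on a 1-64 Hz grid; power is the squared magnitude.
The feature of interest is the coefficient of variation of the band-power
time series, defined literally as variance over mean (NOT the conventional
SD/mean): it therefore carries units of power and scales as c^2 when the
signal is scaled by c.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .recording import Recording
from .svd import ComponentTimecourses


class BandDefinition(NamedTuple):
    name: str
    lower: float
    upper: float


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 3.8),
    BandDefinition("theta", 4.1, 7.6),
    BandDefinition("alpha", 8.2, 12.4),
    BandDefinition("beta", 15.3, 30.6),
)
BAND_NAMES = tuple(b.name for b in DEFAULT_BANDS)
BAND_BY_NAME = {b.name: b for b in DEFAULT_BANDS}


def default_freq_grid(fmin: float = 1.0, fmax: float = 64.0, voices_per_octave: int = 8) -> np.ndarray:
    """Geometric frequency grid, 8 voices per octave over 1-64 Hz by default."""
    n = int(round(np.log2(fmax / fmin) * voices_per_octave)) + 1
    return np.geomspace(fmin, fmax, n)


def _half_support_samples(freq: float, rate: float, n_cycles: float) -> int:
    # mne's Morlet wavelet is truncated at 5 standard deviations of its
    # Gaussian envelope; sigma_t = n_cycles / (2 pi f).
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    return int(np.ceil(5.0 * sigma_t * rate))


def morlet_power(
    course: np.ndarray,
    rate: float,
    freqs: np.ndarray | None = None,
    n_cycles: float = 3.0,
    segment_boundaries: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-frequency power of one time course (freqs x time) plus validity.

    Power is |complex Morlet transform|^2. Samples within one wavelet
    half-support of the record edges or of any concatenation boundary are
    flagged invalid (per frequency) and must be excluded from downstream
    statistics.
    """
    from mne.time_frequency import tfr_array_morlet

    course = np.asarray(course, dtype=float)
    if course.ndim != 1:
        raise ValueError("course must be one-dimensional")
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() > rate / 2.0 + 1e-9:
        raise ValueError(
            f"max frequency {freqs.max():g} Hz exceeds Nyquist {rate / 2.0:g} Hz"
        )
    n = course.size
    longest = 2 * _half_support_samples(freqs.min(), rate, n_cycles) + 1
    if n < longest:
        raise ValueError(
            f"record too short ({n} samples) for the longest wavelet ({longest} samples)"
        )
    power = tfr_array_morlet(
        course[np.newaxis, np.newaxis, :],
        sfreq=rate,
        freqs=freqs,
        n_cycles=n_cycles,
        output="power",
        verbose="error",
    )[0, 0]
    valid = np.ones((freqs.size, n), dtype=bool)
    edges = [0, n]
    if segment_boundaries is not None:
        edges += [int(b) for b in np.asarray(segment_boundaries) if 0 < b < n]
    for i, f in enumerate(freqs):
        half = _half_support_samples(f, rate, n_cycles)
        for edge in edges:
            valid[i, max(0, edge - half) : min(n, edge + half)] = False
    return power, valid


def band_cv(
    power: np.ndarray,
    freqs: np.ndarray,
    band: BandDefinition,
    valid: np.ndarray | None = None,
    min_valid: int = 100,
) -> float:
    """Coefficient of variation (variance/mean) of the band-power series.

    The band-power series p(t) is the mean of power over grid frequencies
    whose center falls inside [lower, upper] (inclusive); CV is the
    population variance of p over valid time samples divided by its mean.
    """
    freqs = np.asarray(freqs, dtype=float)
    in_band = (freqs >= band.lower) & (freqs <= band.upper)
    if not np.any(in_band):
        raise ValueError(
            f"no grid frequency inside band {band.name} [{band.lower}, {band.upper}] Hz; "
            f"grid spans {freqs.min():g}-{freqs.max():g} Hz with {freqs.size} points"
        )
    p_rows = power[in_band]
    if valid is not None:
        mask = np.all(valid[in_band], axis=0)
    else:
        mask = np.ones(power.shape[1], dtype=bool)
    if mask.sum() < min_valid:
        raise ValueError(
            f"only {int(mask.sum())} valid samples in band {band.name}; need >= {min_valid}"
        )
    p = p_rows.mean(axis=0)[mask]
    mean = p.mean()
    if mean <= 0:
        raise ValueError("zero mean band power; cannot form variance/mean ratio")
    return float(p.var() / mean)


@dataclass
class CVFeatures:
    """Per-session CV features: a (source x band) table plus metadata.

    ``source`` is 'svd_components' for projected component time courses or
    'channels' for the single-channel variant. The flat feature vector is
    ordered source-major with bands in canonical order.
    """

    subject: str
    session: str
    values: pd.DataFrame
    source: str

    def to_series(self) -> pd.Series:
        flat = {}
        for row in self.values.index:
            for band in self.values.columns:
                flat[f"{row}_{band}"] = self.values.loc[row, band]
        return pd.Series(flat, name=(self.subject, self.session))

    @property
    def feature_names(self) -> list[str]:
        return list(self.to_series().index)


def compute_cv_features(
    courses: ComponentTimecourses,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    freqs: np.ndarray | None = None,
    n_cycles: float = 3.0,
    min_valid: int = 100,
) -> CVFeatures:
    """CV features of every component time course, per frequency band.

    With the default K = 5 components and 4 bands this yields the 20-element
    feature vector used by the classifiers (names 'svd1_delta', ...,
    'svd5_beta', component-major).
    """
    if freqs is None:
        freqs = default_freq_grid()
    table = {}
    for k in range(courses.k):
        power, valid = morlet_power(
            courses.courses[k],
            courses.rate,
            freqs=freqs,
            n_cycles=n_cycles,
            segment_boundaries=courses.segment_boundaries,
        )
        table[f"svd{k + 1}"] = {
            b.name: band_cv(power, freqs, b, valid=valid, min_valid=min_valid) for b in bands
        }
    values = pd.DataFrame(table).T[[b.name for b in bands]]
    return CVFeatures(
        subject=courses.subject, session=courses.session, values=values, source="svd_components"
    )


def single_channel_cv_features(
    rec: Recording,
    channels: Sequence[str] = ("P3", "P4"),
    bands: Sequence[BandDefinition] = (BAND_BY_NAME["theta"], BAND_BY_NAME["alpha"]),
    freqs: np.ndarray | None = None,
    n_cycles: float = 3.0,
    min_valid: int = 100,
) -> CVFeatures:
    """Single-channel variant: CV of theta/alpha at P3 and P4 by default."""
    if freqs is None:
        freqs = default_freq_grid()
    table = {}
    for ch in channels:
        idx = rec.montage.index(ch)  # raises KeyError naming the channel
        power, valid = morlet_power(
            rec.data[idx],
            rec.rate,
            freqs=freqs,
            n_cycles=n_cycles,
            segment_boundaries=rec.segment_boundaries,
        )
        table[ch] = {
            b.name: band_cv(power, freqs, b, valid=valid, min_valid=min_valid) for b in bands
        }
    values = pd.DataFrame(table).T[[b.name for b in bands]]
    return CVFeatures(subject=rec.subject, session=rec.session, values=values, source="channels")
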