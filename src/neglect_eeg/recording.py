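"""The Recording container: one subject-session multichannel EEG segment."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import Montage

DIAGNOSES = ("RHD", "LHD", "control")
COHORTS = ("cohort1", "cohort2")


@dataclass
class Recording:
    """One subject-session EEG segment (channels x samples, microvolts).

    ``segment_boundaries`` marks sample indices where non-contiguous pieces
    of data were concatenated (artifact-rejection joins); spectral stages
    avoid estimating across them.
    """

    subject: str
    session: str
    day: int
    diagnosis: str
    cohort: str
    rate: float
    data: np.ndarray
    montage: Montage
    segment_boundaries: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.segment_boundaries = np.asarray(self.segment_boundaries, dtype=int)
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"diagnosis must be one of {DIAGNOSES}")
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError("channel count does not match montage")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        b = self.segment_boundaries
        if b.size and (np.any(np.diff(b) < 0) or b.min() < 0 or b.max() > self.n_samples):
            raise ValueError("segment_boundaries must be sorted within [0, n_samples]")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def is_patient(self) -> bool:
        return self.diagnosis != "control"

    def with_data(self, data: np.ndarray, note: str | None = None, **kw) -> "Recording":
        """Copy with new data, preserving metadata and appending provenance."""
        prov = list(self.provenance) + ([note] if note else [])
        return replace(self, data=np.asarray(data, dtype=float), provenance=prov, **kw)
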