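"""Electrode montages (extended 10-20 system, Biosemi cap layouts)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SUPPORTED_CHANNEL_COUNTS = (32, 64)


@dataclass
class Montage:
    """Scalp electrode set: unique labels plus unit-sphere 3-D positions.

    Parameters
    ----------
    labels : list of str
        Channel names (extended 10-20 nomenclature).
    positions : ndarray, shape (n_channels, 3)
        Electrode positions, normalized to the unit sphere.
    eog_labels : list of str
        Names of auxiliary electro-oculogram channels, if any.
    """

    labels: list[str]
    positions: np.ndarray
    eog_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("montage labels must be unique")
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("positions must lie on the unit sphere")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label} not found") from None

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Montage)
            and self.labels == other.labels
            and np.allclose(self.positions, other.positions)
        )


def make_montage(n_channels: int = 32) -> Montage:
    """Build the standard Biosemi cap montage with ``n_channels`` electrodes.

    Positions are taken from the published cap layouts (via mne's standard
    montages) and normalized to the unit sphere. Both supported layouts
    include the posterior parietal electrodes P3 and P4.
    """
    if n_channels not in SUPPORTED_CHANNEL_COUNTS:
        raise ValueError(
            f"unsupported channel count {n_channels}; "
            f"supported counts are {SUPPORTED_CHANNEL_COUNTS}"
        )
    import mne

    std = mne.channels.make_standard_montage(f"biosemi{n_channels}")
    ch_pos = std.get_positions()["ch_pos"]
    labels = list(std.ch_names)
    pos = np.array([ch_pos[c] for c in labels], dtype=float)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(labels=labels, positions=pos, eog_labels=["EOGh", "EOGv"])
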