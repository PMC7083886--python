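"""Plain-text serialization of recordings, trial tables and bases.

EEG goes to a delimited float matrix (channels x samples, microvolts) with
a JSON sidecar carrying subject, session, day, group labels, rate and
channel names; trial tables and feature tables are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage, make_montage
from .recording import Recording
from .svd import TopographyBasis


def write_recording(rec: Recording, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = directory / rec.session
    np.savetxt(stem.with_suffix(".tsv"), rec.data.T, delimiter="\t", fmt="%.6f")
    sidecar = {
        "subject": rec.subject,
        "session": rec.session,
        "day": rec.day,
        "diagnosis": rec.diagnosis,
        "cohort": rec.cohort,
        "rate_hz": rec.rate,
        "channel_names": rec.montage.labels,
        "segment_boundaries": rec.segment_boundaries.tolist(),
        "provenance": rec.provenance,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return stem.with_suffix(".tsv")


def read_recording(path: str | Path, montage: Montage | None = None) -> Recording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = np.loadtxt(path.with_suffix(".tsv"), delimiter="\t").T
    if montage is None:
        montage = make_montage(len(sidecar["channel_names"]))
    if montage.labels != sidecar["channel_names"]:
        raise ValueError("sidecar channel names do not match the montage")
    return Recording(
        subject=sidecar["subject"],
        session=sidecar["session"],
        day=int(sidecar["day"]),
        diagnosis=sidecar["diagnosis"],
        cohort=sidecar["cohort"],
        rate=float(sidecar["rate_hz"]),
        data=data,
        montage=montage,
        segment_boundaries=np.asarray(sidecar.get("segment_boundaries", []), dtype=int),
        provenance=list(sidecar.get("provenance", [])),
    )


def write_trials(trials: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)
    return path


def read_trials(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_basis(basis: TopographyBasis, directory: str | Path, name: str = "basis") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / f"{name}_maps.tsv", basis.maps, delimiter="\t", fmt="%.12g")
    meta = {
        "singular_values": basis.singular_values.tolist(),
        "explained_pct": basis.explained_pct.tolist(),
        "cumulative_pct": basis.cumulative_pct.tolist(),
        "channel_names": basis.montage.labels,
        "fitted_on": basis.fitted_on,
        "k": basis.k,
    }
    out = directory / f"{name}.json"
    out.write_text(json.dumps(meta, indent=1))
    return out


def read_basis(directory: str | Path, name: str = "basis") -> TopographyBasis:
    directory = Path(directory)
    meta = json.loads((directory / f"{name}.json").read_text())
    maps = np.loadtxt(directory / f"{name}_maps.tsv", delimiter="\t")
    if maps.ndim == 1:
        maps = maps[:, None]
    return TopographyBasis(
        maps=maps,
        singular_values=np.asarray(meta["singular_values"]),
        explained_pct=np.asarray(meta["explained_pct"]),
        cumulative_pct=np.asarray(meta["cumulative_pct"]),
        montage=make_montage(len(meta["channel_names"])),
        fitted_on=list(meta["fitted_on"]),
    )
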