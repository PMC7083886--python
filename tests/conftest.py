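import numpy as np
import pytest

from neglect_eeg.montage import make_montage
from neglect_eeg.recording import Recording
from neglect_eeg.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def montage32():
    return make_montage(32)


@pytest.fixture(scope="session")
def montage64():
    return make_montage(64)


def make_recording(data, montage, rate=128.0, subject="S01", session=None, **kw):
    defaults = dict(
        subject=subject,
        session=session or f"{subject}-d1s1",
        day=1,
        diagnosis="control",
        cohort="cohort1",
        rate=rate,
        data=np.asarray(data, dtype=float),
        montage=montage,
    )
    defaults.update(kw)
    return Recording(**defaults)


@pytest.fixture(scope="session")
def strong_cohort():
    """Small full-EEG cohort with a strong planted patient effect."""
    cfg = CohortConfig(
        seed=11,
        n_rhd_cohort1=6,
        n_lhd_cohort1=0,
        n_rhd_cohort2=0,
        n_controls=4,
        cohort1_days=1,
        cohort1_sessions_per_day=1,
        session_duration=20.0,
        severity_mode="fixed",
        fixed_severity=0.9,
    )
    return simulate_cohort(cfg)
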