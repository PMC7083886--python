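"""Shared configuration of the analysis runs.

The working cohort keeps the study's two-cohort / multi-session design at a
desk scale (fewer patients, 20 s EEG segments) so the whole sequence runs
in minutes on one CPU; docs/methods.md records the problem sizes.
"""

from pathlib import Path

from neglect_eeg.synthetic import CohortConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

SEED = 20230901

WORKING_COHORT = dict(
    seed=SEED,
    n_rhd_cohort1=8,
    n_lhd_cohort1=2,
    n_rhd_cohort2=5,
    n_controls=4,
    cohort1_days=2,
    cohort1_sessions_per_day=2,
    cohort2_days=4,
    cohort2_sessions_per_day=1,
    session_duration=20.0,
)

# statistical-mode cohort at the study's session count, for the CCA run
STUDY_SCALE_COHORT = dict(
    seed=SEED + 1,
    n_rhd_cohort1=13,
    n_lhd_cohort1=0,
    n_rhd_cohort2=12,
    n_controls=1,
    cohort1_days=3,
    cohort1_sessions_per_day=2,
    cohort2_days=6,
)


def working_config() -> CohortConfig:
    return CohortConfig(**WORKING_COHORT)


def study_scale_config() -> CohortConfig:
    return CohortConfig(**STUDY_SCALE_COHORT)


def ensure_dirs() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
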