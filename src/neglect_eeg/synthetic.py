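"""Synthetic cohort generator.

Emulates the data structure of the study: two patient cohorts (cohort #1:
right- and left-hemisphere damaged, tested 3x/day on 2 days with a 5x5
search grid; cohort #2: right-hemisphere damaged, tested once/day on 10
days with a 7x7 grid) plus healthy controls, each session consisting of a
resting-state EEG segment and a visual-search trial table.

EEG model: planted orthonormal topographies (zero channel mean, so they
survive average re-referencing) times per-component source time courses
plus spatially white sensor noise. Each source is a sum of band-limited
carriers - constant-modulus tones at a fixed random frequency inside each
canonical band - whose envelope is sinusoidally amplitude-modulated with a
subject- and band-specific depth d. The band-power coefficient of
variation of such a source is analytically monotone in d
(CV proportional to (2 d^2 + d^4/8)/(1 + d^2/2), zero at d = 0), which
gives closed-form targets for recovery tests. Patients' depths shift with
severity (delta/theta up, alpha/beta down), mirroring post-stroke spectral
abnormalities.

Behavior model: reaction times are lognormal with a location that grows
linearly with leftward target eccentricity scaled by severity, and a shape
that inflates with the same product (slower AND more variable left
responses); misses arise from the 3000 ms response deadline plus a
position-dependent lapse probability. Severity therefore drives both the
EEG features and the laterality indices, planting the brain-behavior
coupling the canonical correlation analysis looks for.

A fast "statistical" mode skips raw EEG synthesis and draws session-level
feature tables (LI, F, per-component band CVs, P3/P4 band CVs) from the
equivalent single-latent-factor Gaussian model, with noise calibrated so
the population first canonical correlation equals a configured target
(default 0.67). It exists for experiments whose sample sizes would make
time-series synthesis wasteful; the full mode remains the reference.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .montage import Montage, make_montage
from .recording import Recording
from .spectral import BAND_NAMES, DEFAULT_BANDS

_STREAM_TRUTH = 0
_STREAM_EEG = 1
_STREAM_SNT = 2
_STREAM_FEATURES = 3
_STREAM_PPT = 4


@dataclass
class CohortConfig:
    """Study-design and effect-size parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 15 RHD + 5 LHD patients in
    cohort #1 (3 sessions/day, 2 days, 5x5 grid), 13 RHD patients in
    cohort #2 (1 session/day, 10 days, 7x7 grid), 6 controls (tested like
    cohort #1), 6-minute 32-channel EEG at 128 Hz per session.
    """

    seed: int | None = None
    # cohort sizes and schedules
    n_rhd_cohort1: int = 15
    n_lhd_cohort1: int = 5
    n_rhd_cohort2: int = 13
    n_controls: int = 6
    cohort1_days: int = 2
    cohort1_sessions_per_day: int = 3
    cohort2_days: int = 10
    cohort2_sessions_per_day: int = 1
    # EEG
    n_channels: int = 32
    sampling_rate: float = 128.0
    session_duration: float = 360.0
    n_components_truth: int = 5
    source_amplitudes_uv: tuple[float, ...] = (8.0, 6.0, 5.0, 4.0, 3.0)
    sensor_noise_uv: float = 1.0
    envelope_mod_freq: float = 0.25
    # band amplitude-modulation depths: control baseline and severity slope
    control_depths: dict[str, float] = field(
        default_factory=lambda: {"delta": 0.15, "theta": 0.25, "alpha": 0.55, "beta": 0.35}
    )
    patient_depth_slopes: dict[str, float] = field(
        default_factory=lambda: {"delta": 0.55, "theta": 0.15, "alpha": -0.35, "beta": -0.15}
    )
    # which components carry each band's severity effect (length K_true each)
    component_band_pattern: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "delta": (1.0, 1.0, 1.0, 1.0, 1.0),
            "theta": (0.3, 0.3, 0.3, 1.0, 1.0),
            "alpha": (1.0, 0.6, 1.0, 0.2, 0.6),
            "beta": (0.3, 0.3, 1.0, 0.3, 0.3),
        }
    )
    # severity distribution over patients
    severity_mode: Literal["clustered", "uniform", "fixed"] = "clustered"
    severity_centers: tuple[float, ...] = (0.1, 0.5, 0.9)
    severity_sd: float = 0.05
    fixed_severity: float = 0.0
    lhd_severity_mean: float = 0.05
    session_jitter_sd: float = 0.05
    # reaction-time model
    rt_baseline_ms: float = 500.0
    rt_left_cost_ms: float = 400.0
    rt_sigma: float = 0.25
    rt_sigma_inflation: float = 0.6
    rt_deadline_ms: float = 3000.0
    onset_range_ms: tuple[float, float] = (700.0, 2100.0)
    miss_base: float = 0.02
    miss_slope: float = 0.3
    fa_rate: float = 0.01
    # statistical feature mode
    planted_cca_rho: float = 0.67
    li_effect: float = -0.07
    f_effect: float = 1.0
    li_mean: float = -0.08
    f_mean: float = 2.5
    cv_base: dict[str, float] = field(
        default_factory=lambda: {"delta": 0.10, "theta": 0.12, "alpha": 0.30, "beta": 0.20}
    )
    cv_effects: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "delta": (0.06, 0.06, 0.06, 0.06, 0.06),
            "theta": (0.0, 0.0, 0.0, 0.03, 0.03),
            "alpha": (-0.04, -0.02, -0.04, 0.0, -0.02),
            "beta": (0.0, 0.0, -0.02, 0.0, 0.0),
        }
    )
    # synthetic stand-in for the paper-and-pencil neglect score
    ppt_intercept: float = 100.0
    ppt_slope: float = -60.0
    ppt_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("CohortConfig.seed is required (reproducibility is mandatory)")
        if self.n_rhd_cohort1 + self.n_lhd_cohort1 + self.n_rhd_cohort2 < 1:
            raise ValueError("at least one patient is required")
        if self.n_controls < 1:
            raise ValueError("at least one control is required")
        for name, value in (
            ("cohort1_days", self.cohort1_days),
            ("cohort1_sessions_per_day", self.cohort1_sessions_per_day),
            ("cohort2_days", self.cohort2_days),
            ("cohort2_sessions_per_day", self.cohort2_sessions_per_day),
        ):
            if value < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sampling_rate < 128.0:
            raise ValueError("sampling_rate must be >= 128 Hz")
        if not 0.0 <= self.planted_cca_rho < 1.0:
            raise ValueError("planted_cca_rho must be in [0, 1)")
        for band in BAND_NAMES:
            for table in (self.control_depths, self.patient_depth_slopes):
                if band not in table:
                    raise ValueError(f"missing band {band} in depth tables")
            if not 0.0 <= self.control_depths[band] < 1.0:
                raise ValueError("modulation depths must be in [0, 1)")
        if len(self.source_amplitudes_uv) < self.n_components_truth:
            raise ValueError("need one source amplitude per planted component")

    # ---- roster -----------------------------------------------------------

    def roster(self) -> pd.DataFrame:
        """One row per subject: id, diagnosis, cohort, grid."""
        rows = []
        for i in range(self.n_rhd_cohort1):
            rows.append(("P%02d" % (i + 1), "RHD", "cohort1"))
        for i in range(self.n_lhd_cohort1):
            rows.append(("P%02d" % (self.n_rhd_cohort1 + i + 1), "LHD", "cohort1"))
        for i in range(self.n_rhd_cohort2):
            rows.append(("Q%02d" % (i + 1), "RHD", "cohort2"))
        for i in range(self.n_controls):
            rows.append(("C%02d" % (i + 1), "control", "cohort1"))
        df = pd.DataFrame(rows, columns=["subject", "diagnosis", "cohort"])
        df["grid_size"] = np.where(df["cohort"] == "cohort2", 7, 5)
        return df

    def sessions_of(self, cohort: str) -> list[tuple[int, int]]:
        """(day, session-of-day) pairs for a subject of the given cohort."""
        days = self.cohort1_days if cohort == "cohort1" else self.cohort2_days
        per = (
            self.cohort1_sessions_per_day
            if cohort == "cohort1"
            else self.cohort2_sessions_per_day
        )
        return [(d + 1, s + 1) for d in range(days) for s in range(per)]

    def severity_population_stats(self) -> tuple[float, float]:
        """Population mean and SD of the session-level severity latent."""
        if self.severity_mode == "fixed":
            mu, var = self.fixed_severity, 0.0
        elif self.severity_mode == "uniform":
            mu, var = 0.5, 1.0 / 12.0
        else:
            c = np.asarray(self.severity_centers)
            mu = c.mean()
            var = (c**2).mean() - mu**2 + self.severity_sd**2
        var += self.session_jitter_sd**2
        return float(mu), float(np.sqrt(max(var, 1e-12)))


def modulated_tone(
    t: np.ndarray,
    freq: float,
    depth: float,
    mod_freq: float = 0.25,
    phase: float = 0.0,
    mod_phase: float = 0.0,
) -> np.ndarray:
    """One band-limited carrier with sinusoidal envelope modulation.

    The building block of the EEG source model: a constant-modulus tone
    whose envelope 1 + depth*sin(2 pi mod_freq t) makes its band-power CV
    analytically :func:`analytic_cv`(depth) - exactly zero at depth 0.
    """
    envelope = 1.0 + depth * np.sin(2 * np.pi * mod_freq * t + mod_phase)
    return np.sin(2 * np.pi * freq * t + phase) * envelope


def analytic_cv(depth: float | np.ndarray) -> np.ndarray:
    """Relative band-power CV of a tone with envelope 1 + d sin(w t).

    Power is proportional to (1 + d sin)^2; Var/Mean of that series equals
    (2 d^2 + d^4/8) / (1 + d^2/2) times the carrier power.
    """
    d = np.asarray(depth, dtype=float)
    return (2.0 * d**2 + d**4 / 8.0) / (1.0 + d**2 / 2.0)


@dataclass
class GroundTruth:
    """Planted quantities stored alongside every simulated cohort."""

    topographies: np.ndarray  # channels x K_true, orthonormal, zero channel-mean
    montage: Montage
    subjects: pd.DataFrame  # severity, diagnosis, cohort, expected LI/F per subject
    depths: dict[str, np.ndarray]  # subject -> K_true x 4 modulation depths
    cv_targets: dict[str, np.ndarray]  # subject -> K_true x 4 analytic relative CV
    carrier_freqs: np.ndarray  # K_true x 4 Hz

    def __post_init__(self) -> None:
        gram = self.topographies.T @ self.topographies
        if not np.allclose(gram, np.eye(self.topographies.shape[1]), atol=1e-8):
            raise ValueError("planted topographies must be orthonormal within 1e-8")


def _rng(config: CohortConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(config.seed), *key)))


def _subject_index(roster: pd.DataFrame, subject: str) -> int:
    idx = roster.index[roster["subject"] == subject]
    if len(idx) == 0:
        raise KeyError(f"unknown subject {subject}")
    return int(idx[0])


def _expected_side_stats(config: CohortConfig, severity: float, grid_size: int):
    """Analytic per-hemispace RT mean/variance of the lognormal model.

    Ignores deadline truncation and lapse misses (both rare at default
    settings); pooled hemispace variance includes the between-column
    variance of the column means.
    """
    center = grid_size // 2
    out = {}
    for side in ("left", "right"):
        cols = range(0, center) if side == "left" else range(center + 1, grid_size)
        means, varis = [], []
        for col in cols:
            leftness = max(0.0, -(col - center) / center)
            med = config.rt_baseline_ms + config.rt_left_cost_ms * severity * leftness
            sig = config.rt_sigma * (1.0 + config.rt_sigma_inflation * severity * leftness)
            means.append(med * np.exp(sig**2 / 2.0))
            varis.append(med**2 * np.exp(sig**2) * (np.exp(sig**2) - 1.0))
        means = np.asarray(means)
        varis = np.asarray(varis)
        out[side] = (means.mean(), varis.mean() + means.var())
    return out


def make_ground_truth(config: CohortConfig) -> GroundTruth:
    """Deterministically derive the planted cohort structure from the seed."""
    k = config.n_components_truth
    montage = make_montage(config.n_channels)
    rng = _rng(config, _STREAM_TRUTH)

    g = rng.standard_normal((config.n_channels, k))
    g -= g.mean(axis=0, keepdims=True)  # zero channel mean: survives avg reference
    q, _ = np.linalg.qr(g)
    idx = np.argmax(np.abs(q), axis=0)
    q *= np.sign(q[idx, np.arange(k)])
    topographies = q

    carrier_freqs = np.empty((k, len(DEFAULT_BANDS)))
    for b, band in enumerate(DEFAULT_BANDS):
        lo = band.lower + 0.1 * (band.upper - band.lower)
        hi = band.upper - 0.1 * (band.upper - band.lower)
        carrier_freqs[:, b] = rng.uniform(lo, hi, size=k)

    roster = config.roster()
    severities = np.zeros(len(roster))
    for i, row in roster.iterrows():
        if row["diagnosis"] == "control":
            severities[i] = 0.0
        elif row["diagnosis"] == "LHD":
            severities[i] = np.clip(
                rng.normal(config.lhd_severity_mean, config.severity_sd / 2), 0.0, 1.0
            )
        elif config.severity_mode == "fixed":
            severities[i] = config.fixed_severity
        elif config.severity_mode == "uniform":
            severities[i] = rng.uniform(0.0, 1.0)
        else:
            center = config.severity_centers[rng.integers(len(config.severity_centers))]
            severities[i] = np.clip(rng.normal(center, config.severity_sd), 0.0, 1.0)

    subjects = roster.copy()
    subjects["severity"] = severities
    pattern = np.column_stack(
        [config.component_band_pattern[b][:k] for b in BAND_NAMES]
    )  # K x 4
    depths, cv_targets = {}, {}
    exp_li, exp_f = [], []
    for i, row in subjects.iterrows():
        s = severities[i]
        d = np.empty((k, len(BAND_NAMES)))
        for b, band in enumerate(BAND_NAMES):
            base = config.control_depths[band]
            slope = config.patient_depth_slopes[band] if row["diagnosis"] != "control" else 0.0
            d[:, b] = np.clip(base + slope * s * pattern[:, b], 0.0, 0.95)
        depths[row["subject"]] = d
        cv_targets[row["subject"]] = analytic_cv(d)
        side = _expected_side_stats(config, s, int(row["grid_size"]))
        (lm, lv), (rm, rv) = side["left"], side["right"]
        exp_li.append((rm - lm) / (rm + lm))
        exp_f.append((lv / lm) / (rv / rm))
    subjects["expected_li"] = exp_li
    subjects["expected_f"] = exp_f
    return GroundTruth(
        topographies=topographies,
        montage=montage,
        subjects=subjects,
        depths=depths,
        cv_targets=cv_targets,
        carrier_freqs=carrier_freqs,
    )


def simulate_eeg_session(
    config: CohortConfig,
    subject: str,
    day: int,
    session_of_day: int,
    truth: GroundTruth | None = None,
) -> Recording:
    """Synthesize one resting-state EEG session for ``subject``.

    data = topographies @ sources + white sensor noise, finally re-referenced
    to the common average (a no-op for the planted signal, whose maps have
    zero channel mean). Deterministic given (config.seed, subject, day,
    session): repeated calls are bit-identical.
    """
    if truth is None:
        truth = make_ground_truth(config)
    if config.session_duration < 10.0:
        raise ValueError(
            "session too short: need >= 10 s (10 cycles of the 1 Hz delta edge)"
        )
    row = truth.subjects.iloc[_subject_index(truth.subjects, subject)]
    sidx = _subject_index(truth.subjects, subject)
    rng = _rng(config, _STREAM_EEG, sidx, day, session_of_day)

    rate = config.sampling_rate
    n = int(round(config.session_duration * rate))
    t = np.arange(n) / rate
    k = config.n_components_truth
    depths = truth.depths[subject]
    sources = np.zeros((k, n))
    for ki in range(k):
        amp = config.source_amplitudes_uv[ki]
        for b in range(len(BAND_NAMES)):
            sources[ki] += amp * modulated_tone(
                t,
                truth.carrier_freqs[ki, b],
                depths[ki, b],
                mod_freq=config.envelope_mod_freq,
                phase=rng.uniform(0, 2 * np.pi),
                mod_phase=rng.uniform(0, 2 * np.pi),
            )
    data = truth.topographies @ sources
    if config.sensor_noise_uv > 0:
        data = data + config.sensor_noise_uv * rng.standard_normal(data.shape)
    data -= data.mean(axis=0, keepdims=True)  # generator's final re-referencing
    return Recording(
        subject=subject,
        session=f"{subject}-d{day}s{session_of_day}",
        day=day,
        diagnosis=row["diagnosis"],
        cohort=row["cohort"],
        rate=rate,
        data=data,
        montage=truth.montage,
        provenance=["synthetic"],
    )


def simulate_snt_session(
    config: CohortConfig,
    subject: str,
    day: int,
    session_of_day: int,
    truth: GroundTruth | None = None,
    grid: tuple[int, int] | None = None,
    repeats: int | None = None,
) -> pd.DataFrame:
    """Simulate one Starry-Night session: one trial per target presentation.

    The target visits every grid cell ``repeats`` times (4 on the 5x5 grid,
    3 on the 7x7 grid). RT is lognormal with leftward-position x severity
    location cost; draws beyond the 3000 ms deadline become misses, as do
    position-dependent attentional lapses; a small fixed fraction of trials
    are false alarms (key press before target onset).
    """
    if truth is None:
        truth = make_ground_truth(config)
    sidx = _subject_index(truth.subjects, subject)
    row = truth.subjects.iloc[sidx]
    if grid is None:
        g = int(row["grid_size"])
        grid = (g, g)
    if grid not in ((5, 5), (7, 7)):
        raise ValueError("grid must be 5x5 or 7x7")
    if repeats is None:
        repeats = 4 if grid == (5, 5) else 3
    severity = float(row["severity"])
    rng = _rng(config, _STREAM_SNT, sidx, day, session_of_day)

    n_rows, n_cols = grid
    center = n_cols // 2
    cells = [(r, c) for r in range(n_rows) for c in range(n_cols) for _ in range(repeats)]
    order = rng.permutation(len(cells))
    records = []
    for trial_index, cell_i in enumerate(order):
        r, c = cells[cell_i]
        onset = rng.uniform(*config.onset_range_ms)
        leftness = max(0.0, -(c - center) / center)
        med = config.rt_baseline_ms + config.rt_left_cost_ms * severity * leftness
        sig = config.rt_sigma * (1.0 + config.rt_sigma_inflation * severity * leftness)
        rt = med * np.exp(sig * rng.standard_normal())
        p_lapse = np.clip(config.miss_base + config.miss_slope * severity * leftness, 0, 1)
        u_fa = rng.uniform()
        u_lapse = rng.uniform()
        if u_fa < config.fa_rate:
            response, rt_ms = "fa", np.nan
        elif u_lapse < p_lapse or rt > config.rt_deadline_ms:
            response, rt_ms = "miss", np.nan
        else:
            response, rt_ms = "hit", rt
        records.append(
            {
                "subject": subject,
                "session": f"{subject}-d{day}s{session_of_day}",
                "day": day,
                "trial_index": trial_index,
                "row": r,
                "col": c,
                "onset_ms": onset,
                "response": response,
                "rt_ms": rt_ms,
            }
        )
    return pd.DataFrame(records)


@dataclass
class CohortDataset:
    """A full simulated cohort: session manifest, trials, EEG or features."""

    config: CohortConfig
    truth: GroundTruth
    sessions: pd.DataFrame
    trials: pd.DataFrame
    recordings: dict[str, Recording]  # session id -> Recording (full mode)
    features: pd.DataFrame | None  # statistical mode: LI/F + CV feature columns
    ppt: pd.Series  # per-patient synthetic paper-test score

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(self.sessions.to_csv().encode())
        h.update(self.trials.round(9).to_csv().encode())
        if self.features is not None:
            h.update(self.features.round(9).to_csv().encode())
        for sid in sorted(self.recordings):
            h.update(np.round(self.recordings[sid].data, 9).tobytes())
        h.update(np.round(self.ppt.to_numpy(dtype=float), 9).tobytes())
        return h.hexdigest()

    def patient_sessions(self) -> pd.DataFrame:
        return self.sessions[self.sessions["diagnosis"] != "control"]


def svd_feature_names(k: int = 5) -> list[str]:
    return [f"svd{i}_{b}" for i in range(1, k + 1) for b in BAND_NAMES]


P3P4_FEATURE_NAMES = [f"{ch}_{b}" for ch in ("P3", "P4") for b in ("theta", "alpha")]


def _statistical_features(config: CohortConfig, truth: GroundTruth, sessions: pd.DataFrame) -> pd.DataFrame:
    """Draw (LI, F, CV) feature rows from the calibrated latent-factor model.

    With latent t standardized over the severity population, X = mu_x +
    alpha_x t + eps_x and Y = mu_y + alpha_y t + eps_y; noise scales solve
    alpha' Sigma^-1 alpha = rho/(1-rho) on both sides so the population
    first canonical correlation equals ``planted_cca_rho``.
    """
    k = config.n_components_truth
    rho = config.planted_cca_rho
    if rho > 0:
        # The sample first canonical correlation is biased upward by the
        # maximization over directions; plant the population value whose
        # expected sample estimate at this cohort's patient-session count
        # matches the configured target (first-order Lawley correction).
        n_pat = int((sessions["diagnosis"] != "control").sum())
        dims = 2 + k * len(BAND_NAMES) - 2
        for _ in range(20):
            bias = (1.0 - rho**2) * dims / (2.0 * max(n_pat, dims + 3) * rho)
            new = max(config.planted_cca_rho - bias, 0.05)
            if abs(new - rho) < 1e-6:
                break
            rho = new
    names = svd_feature_names(k)
    alpha_y = np.array(
        [config.cv_effects[b][i] for i in range(k) for b in BAND_NAMES]
    )
    base_y = np.array([config.cv_base[b] for _ in range(k) for b in BAND_NAMES])
    alpha_x = np.array([config.li_effect, config.f_effect])
    mu_x = np.array([config.li_mean, config.f_mean])
    if rho > 0:
        a = rho / (1.0 - rho)
        sigma_x = np.abs(alpha_x) * np.sqrt(alpha_x.size / a)
        sigma_y = np.full(alpha_y.size, np.sqrt(np.sum(alpha_y**2) / a))
    else:
        # null cohort: same noise floor as the default coupling, zero effect
        a0 = 0.67 / 0.33
        sigma_x = np.abs(alpha_x) * np.sqrt(alpha_x.size / a0)
        sigma_y = np.full(alpha_y.size, np.sqrt(np.sum(alpha_y**2) / a0))
        alpha_x = np.zeros_like(alpha_x)
        alpha_y = np.zeros_like(alpha_y)
    mu_t, sd_t = config.severity_population_stats()

    p3 = truth.montage.index("P3")
    p4 = truth.montage.index("P4")
    w = truth.topographies[[p3, p4]] ** 2
    w = w / w.sum(axis=1, keepdims=True)  # power mixing weights over components
    # a channel's band-power variance mixes independent component
    # fluctuations with squared weights, so the channel CV carries the
    # component CVs diluted by w^2 (sum < 1): the spatially distributed
    # severity effect is intrinsically attenuated at single electrodes
    w_cv = w**2
    sigma_chan = float(sigma_y[0])

    sev = truth.subjects.set_index("subject")["severity"]
    rng = _rng(config, _STREAM_FEATURES)
    rows = []
    for _, srow in sessions.iterrows():
        s = sev[srow["subject"]]
        t_std = (s + rng.normal(0.0, config.session_jitter_sd) - mu_t) / sd_t
        x = mu_x + alpha_x * t_std + sigma_x * rng.standard_normal(2)
        y = base_y + alpha_y * t_std + sigma_y * rng.standard_normal(alpha_y.size)
        y_mat = y.reshape(k, len(BAND_NAMES))
        rec = {"subject": srow["subject"], "session": srow["session"], "LI": x[0], "F": x[1]}
        rec.update(dict(zip(names, y)))
        for ci, ch in enumerate(("P3", "P4")):
            for b in ("theta", "alpha"):
                bi = BAND_NAMES.index(b)
                rec[f"{ch}_{b}"] = float(
                    w_cv[ci] @ y_mat[:, bi] + sigma_chan * rng.standard_normal()
                )
        rows.append(rec)
    return pd.DataFrame(rows)


def simulate_cohort(
    config: CohortConfig, eeg_mode: Literal["full", "statistical", "none"] = "full"
) -> CohortDataset:
    """Simulate the whole cohort.

    ``eeg_mode='full'`` synthesizes raw EEG per session; ``'statistical'``
    draws session-level feature tables from the calibrated latent model
    instead; ``'none'`` produces behavior trials only. Trial tables and the
    synthetic paper-test covariate are generated in every mode.
    """
    truth = make_ground_truth(config)
    sess_rows = []
    for _, subj in truth.subjects.iterrows():
        for day, sod in config.sessions_of(subj["cohort"]):
            sess_rows.append(
                {
                    "subject": subj["subject"],
                    "session": f"{subj['subject']}-d{day}s{sod}",
                    "day": day,
                    "session_of_day": sod,
                    "diagnosis": subj["diagnosis"],
                    "cohort": subj["cohort"],
                    "label": "control" if subj["diagnosis"] == "control" else "patient",
                    "severity": subj["severity"],
                    "grid_size": subj["grid_size"],
                }
            )
    sessions = pd.DataFrame(sess_rows)

    trials = pd.concat(
        [
            simulate_snt_session(config, r["subject"], r["day"], r["session_of_day"], truth=truth)
            for _, r in sessions.iterrows()
        ],
        ignore_index=True,
    )

    recordings: dict[str, Recording] = {}
    features = None
    if eeg_mode == "full":
        for _, r in sessions.iterrows():
            rec = simulate_eeg_session(
                config, r["subject"], r["day"], r["session_of_day"], truth=truth
            )
            recordings[rec.session] = rec
    elif eeg_mode == "statistical":
        features = _statistical_features(config, truth, sessions)
    elif eeg_mode != "none":
        raise ValueError("eeg_mode must be 'full', 'statistical' or 'none'")

    rng = _rng(config, _STREAM_PPT)
    patients = truth.subjects[truth.subjects["diagnosis"] != "control"]
    ppt = pd.Series(
        config.ppt_intercept
        + config.ppt_slope * patients["severity"].to_numpy()
        + config.ppt_noise_sd * rng.standard_normal(len(patients)),
        index=patients["subject"].to_numpy(),
        name="ppt_score",
    )
    return CohortDataset(
        config=config,
        truth=truth,
        sessions=sessions,
        trials=trials,
        recordings=recordings,
        features=features,
        ppt=ppt,
    )
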