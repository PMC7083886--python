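"""End-to-end orchestration: seeded runs, provenance, and report writing.

A single global seed fans out to per-stage derived seeds (stage-name
hashing), so individual stages can be rerun independently with identical
results. Stage order is fixed: simulate -> preprocess -> svd -> features
-> behavior -> classify -> severity.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import cca as cca_mod
from . import classify as clf
from .preprocess import preprocess_recording
from .spectral import compute_cv_features, single_channel_cv_features
from .svd import fit_group_svd, project_subject, select_components, split_half_reproducibility
from .synthetic import CohortConfig, simulate_cohort, svd_feature_names

STAGES = ("simulate", "preprocess", "svd", "features", "behavior", "classify", "severity")


@dataclass
class PipelineConfig:
    """Validated, YAML-loadable configuration of a full run."""

    seed: int
    cohort: dict[str, Any] = field(default_factory=dict)
    eeg_mode: str = "full"
    band: tuple[float, float] = (1.0, 40.0)
    target_rate: float = 128.0
    artifact_threshold_uv: float = 80.0
    artifact_window_s: float = 1.0
    n_components: int = 5
    n_splits: int = 10
    n_perm: int = 100
    n_features_grid: list[int] | None = None
    classify_eeg: bool = False
    covariance_mode: str = "per_class"
    run_severity: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a global seed is mandatory")
        if self.eeg_mode not in ("full", "statistical"):
            raise ValueError("eeg_mode must be 'full' or 'statistical'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    config_hash: str
    seed: int
    stages: dict[str, Any] = field(default_factory=dict)

    def summary(self) -> dict[str, Any]:
        """Machine-readable summary of the headline numbers per stage."""
        out: dict[str, Any] = {"config_hash": self.config_hash, "seed": self.seed}
        for stage in STAGES:
            out[stage] = self.stages.get(stage, {}).get("summary", "not run")
        return out


class PipelineStageError(RuntimeError):
    """A stage failed; the partial bundle is preserved on the exception."""

    def __init__(self, stage: str, bundle: ResultBundle, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.bundle = bundle
        self.cause = cause


def run_full_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute every stage on a freshly simulated cohort."""
    bundle = ResultBundle(config_hash=config.config_hash(), seed=config.seed)

    def run(stage, fn):
        try:
            bundle.stages[stage] = fn()
        except Exception as err:  # noqa: BLE001 - stage isolation is the contract
            raise PipelineStageError(stage, bundle, err) from err

    state: dict[str, Any] = {}

    def stage_simulate():
        cohort_cfg = CohortConfig(seed=config.seed, **config.cohort)
        ds = simulate_cohort(cohort_cfg, eeg_mode=config.eeg_mode)
        state["dataset"] = ds
        return {
            "summary": {
                "n_subjects": int(ds.sessions["subject"].nunique()),
                "n_sessions": int(len(ds.sessions)),
                "n_trials": int(len(ds.trials)),
                "checksum": ds.checksum(),
            }
        }

    def stage_preprocess():
        ds = state["dataset"]
        if config.eeg_mode != "full":
            return {"summary": "skipped (no raw EEG in this mode)"}
        clean = {}
        for sid, rec in ds.recordings.items():
            clean[sid] = preprocess_recording(
                rec,
                band=config.band,
                target_rate=config.target_rate,
                artifact_threshold=config.artifact_threshold_uv,
                artifact_window=config.artifact_window_s,
            )
        state["clean"] = clean
        kept = sum(r.n_samples for r in clean.values())
        total = sum(r.n_samples for r in ds.recordings.values())
        return {"summary": {"n_recordings": len(clean), "fraction_kept": kept / total}}

    def stage_svd():
        if config.eeg_mode != "full":
            return {"summary": "skipped (statistical feature mode)"}
        recs = list(state["clean"].values())
        basis = select_components(fit_group_svd(recs), k=config.n_components)
        split = split_half_reproducibility(
            recs, n_splits=config.n_splits, seed=config.stage_seed("svd"),
            k=config.n_components,
        )
        state["basis"] = basis
        return {
            "basis": basis,
            "split_half": split,
            "summary": {
                "k": config.n_components,
                "cumulative_variance_pct": float(basis.cumulative_pct[config.n_components - 1]),
                "split_half_mean_abs_r": float(split["abs_corr"].mean()),
            },
        }

    def stage_features():
        ds = state["dataset"]
        if config.eeg_mode != "full":
            feats = ds.features.copy()
            state["cv_table"] = feats
            return {"summary": {"n_rows": len(feats), "source": "statistical"}}
        basis = state["basis"]
        rows = []
        for sid, rec in state["clean"].items():
            svd_row = compute_cv_features(project_subject(rec, basis)).to_series()
            chan_row = single_channel_cv_features(rec).to_series()
            row = pd.concat([svd_row, chan_row])
            row["subject"], row["session"] = rec.subject, sid
            rows.append(row)
        feats = pd.DataFrame(rows).reset_index(drop=True)
        state["cv_table"] = feats
        return {"features": feats, "summary": {"n_rows": len(feats), "source": "svd+channels"}}

    def stage_behavior():
        ds = state["dataset"]
        tables = []
        for g, sub in ds.sessions.groupby("grid_size"):
            tr = ds.trials[ds.trials["session"].isin(sub["session"])]
            tables.append(beh.behavior_table(tr, (int(g), int(g))))
        table = pd.concat(tables, ignore_index=True)
        table = table.merge(
            ds.sessions[["session", "day", "diagnosis", "cohort", "label"]], on="session"
        )
        state["behavior"] = table
        rhd = table[(table["diagnosis"] == "RHD") & table["complete"]]["LI"]
        ctl = table[(table["diagnosis"] == "control") & table["complete"]]["LI"]
        comp = beh.group_compare(ctl, rhd, "greater") if len(rhd) > 1 and len(ctl) > 1 else None
        return {
            "table": table,
            "summary": {
                "mean_LI_RHD": float(rhd.mean()) if len(rhd) else None,
                "mean_LI_control": float(ctl.mean()) if len(ctl) else None,
                "welch_p_control_gt_RHD": float(comp[2]) if comp else None,
            },
        }

    def stage_classify():
        if config.n_perm < 1:
            raise ValueError("n_perm must be >= 1 for the permutation null")
        table = state["behavior"]
        usable = table[table["complete"] & (table["diagnosis"] != "LHD")].copy()
        res = clf.loso_cross_validate(
            usable, beh.BEHAVIOR_FEATURES, n_features_grid=config.n_features_grid,
            covariance_mode=config.covariance_mode,
        )
        thr, _ = clf.permutation_null(
            usable, beh.BEHAVIOR_FEATURES, n_perm=config.n_perm,
            seed=config.stage_seed("classify"), n_features=res.best_n,
            covariance_mode=config.covariance_mode,
        )
        res.permutation_threshold = thr
        out = {
            "behavior": res,
            "summary": {
                "behavior_auc": res.auc,
                "behavior_threshold_95": thr,
                "behavior_mean_accuracy": res.mean_accuracy,
            },
        }
        if config.classify_eeg and config.eeg_mode == "full":
            ds = state["dataset"]
            eeg_res = clf.loso_cross_validate_eeg(
                ds, k=config.n_components, recordings=state["clean"],
                n_features_grid=config.n_features_grid,
                covariance_mode=config.covariance_mode,
            )
            out["eeg"] = eeg_res
            out["summary"]["eeg_auc"] = eeg_res.auc
        return out

    def stage_severity():
        if not config.run_severity:
            return {"summary": "skipped (disabled)"}
        ds = state["dataset"]
        cv = state["cv_table"]
        names = svd_feature_names(config.n_components)
        if config.eeg_mode == "full":
            b = state["behavior"]
            merged = cv.merge(
                b[b["complete"]][["session", "subject", "LI", "F"]],
                on=["session", "subject"],
            )
        else:
            merged = cv
        merged = merged.merge(
            ds.sessions[["session", "diagnosis"]], on="session"
        )
        pats = merged[merged["diagnosis"] != "control"].reset_index(drop=True)
        x = pats[["LI", "F"]].to_numpy(dtype=float)
        y = pats[names].to_numpy(dtype=float)
        model = cca_mod.fit_cca(x, y)
        thr, sig, _ = cca_mod.permutation_significance(
            x, y, pats["subject"].to_numpy(), n_perm=config.n_perm,
            seed=config.stage_seed("severity"),
        )
        stages_ = cca_mod.stage_severity(model.u[:, 0], seed=config.stage_seed("severity"))
        patient_stage = (
            pd.Series(stages_.labels, index=pats["subject"])
            .groupby(level=0)
            .agg(lambda s: int(np.bincount(s, minlength=3).argmax()))
        )
        validation = cca_mod.validate_clusters_external(patient_stage, ds.ppt)
        sev = cca_mod.loso_severity_classification(
            pats[["subject", "LI", "F"]], pats[["subject"] + names], brain_cols=names,
            seed=config.stage_seed("severity"),
            n_features_grid=config.n_features_grid,
        )
        return {
            "cca": model,
            "staging": stages_,
            "validation": validation,
            "loso": sev,
            "summary": {
                "rho1": float(model.rhos[0]),
                "rho1_threshold_99": thr,
                "rho1_significant": bool(sig[0]),
                "stage_counts": stages_.counts.tolist(),
                "three_class_mean_accuracy": sev.mean_per_class_accuracy,
                "confusion": sev.confusion.tolist(),
            },
        }

    run("simulate", stage_simulate)
    run("preprocess", stage_preprocess)
    run("svd", stage_svd)
    run("features", stage_features)
    run("behavior", stage_behavior)
    run("classify", stage_classify)
    run("severity", stage_severity)
    return bundle


def write_report(bundle: ResultBundle, directory: str | Path) -> Path:
    """Write a machine-readable JSON and a human-readable markdown summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    summary = bundle.summary()
    (directory / "report.json").write_text(json.dumps(summary, indent=1, default=str))
    lines = [
        "# Pipeline report",
        "",
        f"- config hash: `{bundle.config_hash}`",
        f"- seed: {bundle.seed}",
        "",
    ]
    for stage in STAGES:
        lines.append(f"## {stage}")
        info = summary.get(stage, "not run")
        if info == "not run":
            lines.append("not run")
        else:
            lines.append("```json")
            lines.append(json.dumps(info, indent=1, default=str))
            lines.append("```")
        lines.append("")
    (directory / "report.md").write_text("\n".join(lines))
    return directory / "report.json"
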