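"""Reproducible multi-stage pipeline: simulate -> preprocess -> speed ->
train -> encode -> aggregate -> stats.

Each stage reads the previous stage's artifacts from the output directory,
writes its own plus a JSON manifest (config hash, seed, input hashes, record
counts), and is deterministic for a given config and seed: one global seed
fans out to per-stage seeds by fixed offsets. Statistics CSVs are
byte-identical across reruns.

Configuration is a YAML file validated against a pydantic schema that
rejects unknown keys; see :class:`PipelineConfig`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io as gio
from .events import DetectorConfig, detect_gait_events
from .features import aggregate, attach_gait_speed, select_foot
from .preprocessing import (correct_gyro_offset, estimate_gyro_offset,
                            finalize_epochs, preprocess_recording,
                            resample_to_100hz)
from .psychometrics import (compare_groups, reliability_table, responsiveness)
from .speed import estimate_gait_speed
from .synthetic import CohortSpec, simulate_cohort
from .vae import VaeConfig, VaeModel, build_model, encode, train

log = logging.getLogger("gaitvae")

STAGES = ("simulate", "preprocess", "speed", "train", "encode", "aggregate", "stats")

# fixed per-stage seed offsets fanned out from the global seed
SEED_OFFSETS = {"simulate": 0, "train": 1000, "split": 2000}


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortConfig(_Strict):
    n_stroke: int = 10
    n_healthy: int = 10
    sessions: List[str] = ["test", "retest"]
    duration: float = 120.0
    fs: float = 104.0
    longitudinal_speed: float = 0.0
    longitudinal_asymmetry: float = 0.0
    longitudinal_fraction: float = 1.0


class PreprocessConfig(_Strict):
    zero_phase: bool = False
    filter_scope: Literal["epoch", "recording"] = "epoch"
    outlier_z: float = 5.0


class VaeSection(_Strict):
    filters: Tuple[int, int, int] = (32, 64, 128)
    latent_dim: int = 12
    batch_size: int = 64
    max_epochs: int = 200
    early_stop_patience: int = 10
    learning_rate: float = 0.001
    kl_weight: float = 1.0
    recon_reduction: Literal["sum", "mean"] = "sum"
    test_fraction: float = 0.2  # fraction of training subjects held out


class StatsConfig(_Strict):
    foot: Literal["left", "right"] = "right"
    sem_estimator: Literal["pooled_sd", "ms_error"] = "pooled_sd"
    welch: bool = False
    reliable_only: bool = True


class PipelineConfig(_Strict):
    seed: int = 0
    outdir: str = "gaitvae_out"
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    preprocessing: PreprocessConfig = Field(default_factory=PreprocessConfig)
    vae: VaeSection = Field(default_factory=VaeSection)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()).hexdigest()[:16]


def _manifest(cfg: PipelineConfig, stage: str, outdir: Path,
              inputs: List[Path], counts: Dict, t0: float) -> None:
    payload = dict(stage=stage, config_hash=cfg.config_hash(), seed=cfg.seed,
                   inputs={str(p.name): gio.file_sha256(p) for p in inputs if p.exists()},
                   counts=counts)
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    log.info("stage %s done in %.1f s: %s", stage, time.time() - t0, counts)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact for stage '{stage}': {path}")
    return path


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    t0 = time.time()
    c = cfg.cohort
    spec = CohortSpec(n_stroke=c.n_stroke, n_healthy=c.n_healthy,
                      sessions=tuple(c.sessions), duration=c.duration, fs=c.fs,
                      seed=cfg.seed + SEED_OFFSETS["simulate"],
                      longitudinal_effect={"mean_speed": c.longitudinal_speed,
                                           "asymmetry": c.longitudinal_asymmetry},
                      longitudinal_fraction=c.longitudinal_fraction)
    records, manifest = simulate_cohort(spec)
    raw = outdir / "raw"
    for r in records:
        gio.write_recording(r["left"], raw)
        gio.write_recording(r["right"], raw)
        gio.write_truth(r["truth"], r["measurement_id"], raw)
    gio.write_table(manifest, outdir / "cohort.csv")
    _manifest(cfg, "simulate", outdir, [outdir / "cohort.csv"],
              dict(measurements=len(records)), t0)


def _iter_recordings(outdir: Path, stage: str):
    cohort = pd.read_csv(_require(outdir / "cohort.csv", stage))
    for _, row in cohort.iterrows():
        for foot in ("left", "right"):
            yield row, gio.read_recording(outdir / "raw" / f"{row.measurement_id}_{foot}.csv")


def stage_preprocess(cfg: PipelineConfig, outdir: Path) -> None:
    t0 = time.time()
    all_epochs, event_rows = [], []
    for row, rec in _iter_recordings(outdir, "preprocess"):
        epochs, events, _ = preprocess_recording(
            rec, DetectorConfig(), zero_phase=cfg.preprocessing.zero_phase,
            filter_scope=cfg.preprocessing.filter_scope)
        all_epochs += epochs
        for (s, e), c in zip(events.stance_intervals, events.foot_contacts):
            event_rows.append(dict(measurement_id=row.measurement_id, foot=rec.foot,
                                   contact_index=int(c), stance_start=int(s),
                                   stance_end=int(e)))
    kept, removed, _ = finalize_epochs(all_epochs, cfg.preprocessing.outlier_z)
    gio.write_epochs(kept, outdir / "epochs.h5", outdir / "epochs_manifest.csv")
    gio.write_events_csv(event_rows, outdir / "events.csv")
    _manifest(cfg, "preprocess", outdir, [outdir / "epochs_manifest.csv"],
              dict(epochs_total=len(all_epochs), epochs_kept=len(kept),
                   epochs_removed=len(removed)), t0)


def stage_speed(cfg: PipelineConfig, outdir: Path) -> None:
    t0 = time.time()
    rows = []
    for row, rec in _iter_recordings(outdir, "speed"):
        r100 = resample_to_100hz(rec)
        r100 = correct_gyro_offset(r100, estimate_gyro_offset(r100))
        events = detect_gait_events(r100)
        res = estimate_gait_speed(r100, events)
        rows.append(dict(measurement_id=row.measurement_id, foot=rec.foot,
                         gait_speed_mps=res.gait_speed,
                         total_distance_m=res.total_distance))
    gio.write_table(pd.DataFrame(rows), outdir / "speeds.csv")
    _manifest(cfg, "speed", outdir, [outdir / "speeds.csv"], dict(rows=len(rows)), t0)


def _vae_config(cfg: PipelineConfig) -> VaeConfig:
    v = cfg.vae
    return VaeConfig(filters=tuple(v.filters), latent_dim=v.latent_dim,
                     batch_size=v.batch_size, max_epochs=v.max_epochs,
                     early_stop_patience=v.early_stop_patience,
                     learning_rate=v.learning_rate, kl_weight=v.kl_weight,
                     recon_reduction=v.recon_reduction,
                     seed=cfg.seed + SEED_OFFSETS["train"])


def stage_train(cfg: PipelineConfig, outdir: Path) -> None:
    """Train the VAE on the stroke group's epochs (participant-level split)."""
    t0 = time.time()
    data, manifest = gio.read_epochs(_require(outdir / "epochs.h5", "train"),
                                     _require(outdir / "epochs_manifest.csv", "train"))
    stroke = manifest["group"] == "stroke"
    subjects = sorted(manifest.loc[stroke, "subject_id"].unique())
    rng = np.random.default_rng(cfg.seed + SEED_OFFSETS["split"])
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    n_test = max(int(round(len(order) * cfg.vae.test_fraction)), 1)
    test_subjects = set(order[:n_test])
    is_test = manifest["subject_id"].isin(test_subjects)
    x_train = data[(stroke & ~is_test).to_numpy()]
    x_test = data[(stroke & is_test).to_numpy()]
    vcfg = _vae_config(cfg)
    model = build_model(vcfg)
    model, report = train(model, x_train, x_test, vcfg)
    model.save(outdir / "vae_model.npz")
    (outdir / "train_report.json").write_text(report.to_json())
    _manifest(cfg, "train", outdir, [outdir / "epochs_manifest.csv"],
              dict(train_epochs=int(x_train.shape[0]), test_epochs=int(x_test.shape[0]),
                   n_epochs_run=report.n_epochs, best_epoch=report.best_epoch), t0)


def stage_encode(cfg: PipelineConfig, outdir: Path) -> None:
    t0 = time.time()
    model = VaeModel.load(_require(outdir / "vae_model.npz", "encode"))
    data, manifest = gio.read_epochs(_require(outdir / "epochs.h5", "encode"),
                                     outdir / "epochs_manifest.csv")
    mu = np.concatenate([encode(model, data[i:i + 256]).mu
                         for i in range(0, len(data), 256)]) if len(data) else \
        np.empty((0, model.config.latent_dim))
    cols = [f"L{i}" for i in range(mu.shape[1])]
    out = pd.concat([manifest, pd.DataFrame(mu, columns=cols)], axis=1)
    gio.write_table(out, outdir / "scores.csv")
    _manifest(cfg, "encode", outdir, [outdir / "scores.csv"], dict(rows=len(out)), t0)


def stage_aggregate(cfg: PipelineConfig, outdir: Path) -> None:
    t0 = time.time()
    scores = pd.read_csv(_require(outdir / "scores.csv", "aggregate"))
    speeds = pd.read_csv(_require(outdir / "speeds.csv", "aggregate"))
    feats = aggregate(scores)
    feats = attach_gait_speed(feats, speeds)
    gio.write_table(feats, outdir / "features.csv")
    _manifest(cfg, "aggregate", outdir, [outdir / "features.csv"],
              dict(rows=len(feats)), t0)


def stage_stats(cfg: PipelineConfig, outdir: Path) -> None:
    t0 = time.time()
    feats = pd.read_csv(_require(outdir / "features.csv", "stats"))
    feats = select_foot(feats, cfg.stats.foot)
    latent = [c for c in feats.columns if c.startswith("L") and c[1:].isdigit()]
    analysis_features = latent + ["gait_speed_mps"]
    counts: Dict = {}

    # 1) test-retest reliability
    rel_results = []
    if {"test", "retest"} <= set(feats["session"]):
        test_df = feats[feats["session"] == "test"]
        retest_df = feats[feats["session"] == "retest"]
        rel_df, rel_results = reliability_table(
            test_df, retest_df, analysis_features, cfg.stats.sem_estimator)
        gio.write_table(rel_df, outdir / "reliability.csv")
        counts["reliability_features"] = len(rel_df)

    # 2) stroke vs healthy comparison on the base sessions
    base = feats[feats["session"].isin(["test", "retest", "T0"])]
    stroke = base[base["group"] == "stroke"]
    healthy = base[base["group"] == "healthy"]
    if len(stroke) >= 2 and len(healthy) >= 2:
        comp = [compare_groups(stroke[f], healthy[f], feature=f,
                               welch=cfg.stats.welch).__dict__
                for f in analysis_features]
        gio.write_table(pd.DataFrame(comp), outdir / "group_comparison.csv")
        counts["group_comparison_features"] = len(comp)

    # 3) responsiveness over the longitudinal sessions
    if {"T0", "Tend"} <= set(feats["session"]) and rel_results:
        t0_df = feats[feats["session"] == "T0"]
        te_df = feats[feats["session"] == "Tend"]
        res = responsiveness(t0_df, te_df, rel_results,
                             features=latent, speed_feature="gait_speed_mps",
                             reliable_only=cfg.stats.reliable_only)
        gio.write_table(res["table"], outdir / "responsiveness.csv")
        summary = dict(n_subjects=res["n_subjects"],
                       n_changed_any=res["n_changed_any"],
                       changed_any_latent=res["changed_any_latent"],
                       changed_gait_speed=res["changed_gait_speed"],
                       changed_both=res["changed_both"],
                       excluded_subjects=res["excluded_subjects"])
        (outdir / "responsiveness_summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))
        counts["responsiveness_subjects"] = res["n_subjects"]

    _manifest(cfg, "stats", outdir, [outdir / "features.csv"], counts, t0)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "speed": stage_speed,
    "train": stage_train,
    "encode": stage_encode,
    "aggregate": stage_aggregate,
    "stats": stage_stats,
}


def run_stage(stage: str, cfg: PipelineConfig, outdir: Optional[Path] = None) -> Path:
    """Run one named stage (or ``all``) and return the output directory."""
    if stage != "all" and stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage '{stage}'")
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in (STAGES if stage == "all" else (stage,)):
        _STAGE_FUNCS[s](cfg, outdir)
    return outdir
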