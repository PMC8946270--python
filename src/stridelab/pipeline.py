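"""End-to-end pipeline: simulate/load -> events -> parameters -> features ->
classification -> importance report, with a run manifest.

Each stage logs one line with its counts; a failure halts the run with a
stage-named :class:`PipelineStageError` while retaining the artifacts
written so far.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cl
from . import explain as ex
from .core import GaitError
from .events import assign_phases, detect_events
from .features import compute_features, feature_dictionary
from .io import (PipelineConfig, read_recording_csv, write_events_csv,
                 write_manifest, write_recording_csv)
from .spatiotemporal import (compute_spatiotemporal, detect_zero_velocity,
                             estimate_stride_length)
from .synthetic import GaitProfile, simulate_cohort

log = logging.getLogger(__name__)

__all__ = ["PipelineStageError", "run_pipeline", "analyze_subject"]


class PipelineStageError(GaitError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def analyze_subject(rec_right, rec_left, config: PipelineConfig | None = None):
    """Events, phases, spatial-temporal parameters and features for one
    subject.

    Returns a dict with keys ``events`` (per foot), ``phases`` (per foot),
    ``st_params`` (:class:`SpatioTemporalParams`) and ``features``
    (840-entry Series).
    """
    cfg = config or PipelineConfig()
    ev = {"right": detect_events(rec_right), "left": detect_events(rec_left)}
    ph = {"right": assign_phases(ev["right"], ev["left"]),
          "left": assign_phases(ev["left"], ev["right"])}
    lengths = {}
    for foot, rec in (("right", rec_right), ("left", rec_left)):
        mask = detect_zero_velocity(rec, cfg.zupt_gyro_thresh_dps,
                                    cfg.zupt_acc_thresh_g, cfg.zupt_window)
        try:
            est = estimate_stride_length(rec, mask, cfg.ekf_sigma_acc,
                                         cfg.ekf_sigma_gyro, cfg.ekf_sigma_vel)
            lengths[foot] = est.stride_lengths_m
        except GaitError:
            lengths[foot] = None
    st = compute_spatiotemporal(ev["right"], ev["left"],
                                lengths["right"], lengths["left"])
    feats = compute_features(rec_right, rec_left, ph["right"], ph["left"])
    return {"events": ev, "phases": ph, "st_params": st, "features": feats}


def _load_or_simulate(cfg: PipelineConfig, out: Path) -> list:
    """Return a list of (subject_id, label, rec_right, rec_left)."""
    if cfg.input_manifest:
        man = Path(cfg.input_manifest)
        if not man.exists():
            raise PipelineStageError("input", f"manifest not found: {man}")
        rows = pd.read_csv(man)
        subjects = []
        for _, r in rows.iterrows():
            for col in ("right_file", "left_file"):
                if not Path(r[col]).exists():
                    raise PipelineStageError(
                        "input", f"{r['subject_id']}: missing {col} {r[col]}")
            subjects.append((str(r["subject_id"]), int(r["label"]),
                             read_recording_csv(r["right_file"], "right", cfg.fs),
                             read_recording_csv(r["left_file"], "left", cfg.fs)))
        return subjects

    prof_a = GaitProfile(**cfg.profile_a)
    prof_b = GaitProfile(**cfg.profile_b)
    cohort = simulate_cohort(prof_a, prof_b, cfg.n_per_group, cfg.duration,
                             cfg.fs, seed=cfg.seed, jitter_sd=cfg.jitter_sd)
    rec_dir = out / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    subjects = []
    for sid, label, sim in cohort:
        rf = rec_dir / f"{sid}_right.csv"
        lf = rec_dir / f"{sid}_left.csv"
        write_recording_csv(sim.right, rf)
        write_recording_csv(sim.left, lf)
        manifest_rows.append((sid, label, str(rf), str(lf)))
        subjects.append((sid, label, sim.right, sim.left))
    pd.DataFrame(manifest_rows, columns=["subject_id", "label", "right_file",
                                         "left_file"]
                 ).to_csv(out / "cohort.csv", index=False)
    return subjects


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline and write all artifacts under ``out_dir``.

    Returns a dict with the per-model metrics, the importance report and the
    top-k sweep table.
    """
    cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    try:
        subjects = _load_or_simulate(cfg, out)
    except PipelineStageError:
        raise
    except Exception as e:  # noqa: BLE001 - stage-named rewrap
        raise PipelineStageError("input", str(e)) from e
    counts["subjects"] = len(subjects)
    log.info("input: %d subjects", len(subjects))

    st_rows, feat_rows, labels, ids = [], [], [], []
    n_strides = 0
    for sid, label, rec_r, rec_l in subjects:
        try:
            res = analyze_subject(rec_r, rec_l, cfg)
        except GaitError as e:
            raise PipelineStageError("events", f"{sid}: {e}") from e
        write_events_csv(res["events"], out / f"events_{sid}.csv")
        n_strides += res["events"]["right"].n_strides
        st_rows.append(res["st_params"].to_series().rename(sid))
        feat_rows.append(res["features"].rename(sid))
        labels.append(label)
        ids.append(sid)
    counts["strides_right_total"] = n_strides
    log.info("events: %d right-foot strides across cohort", n_strides)

    st_df = pd.DataFrame(st_rows)
    st_df.insert(0, "label", labels)
    st_df.to_csv(out / "spatiotemporal.csv", index_label="subject_id")
    feat_df = pd.DataFrame(feat_rows)
    incomplete = int(feat_df.isna().any(axis=1).sum())
    counts["features_incomplete_subjects"] = incomplete
    feat_out = feat_df.copy()
    feat_out.insert(0, "label", labels)
    feat_out.to_csv(out / "features.csv", index_label="subject_id")
    feature_dictionary().to_csv(out / "feature_dictionary.csv")
    log.info("features: %d x %d, %d incomplete", *feat_df.shape, incomplete)
    if incomplete:
        raise PipelineStageError(
            "features", f"{incomplete} subjects have incomplete vectors")

    X = feat_df.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    results = {}
    for family in cfg.models:
        spec = cl.ModelSpec(family=family, seed=cfg.seed)
        cv = cl.lopo_cv(X, y, spec, select_k=cfg.select_k)
        results[family] = {
            "accuracy": cv.accuracy, "precision": cv.precision,
            "recall": cv.recall, "f1": cv.f1, "n_folds": cv.n_folds,
            "per_fold_accuracy": [float(np.mean(p[2] == p[1]))
                                  for p in cv.fold_predictions],
        }
        log.info("classify[%s]: accuracy %.3f over %d folds", family,
                 cv.accuracy, cv.n_folds)
    (out / "metrics.json").write_text(json.dumps(results, indent=2))

    spec = cl.ModelSpec(family=cfg.importance_model, seed=cfg.seed)
    cv = cl.lopo_cv(X, y, spec, select_k=cfg.select_k)
    shap_kwargs = dict(n_permutations=cfg.shap_permutations)
    report = ex.importance_report(cv, X, y, methods=cfg.importance_methods,
                                  seed=cfg.seed, **shap_kwargs)
    report.index = report.index + 1  # 0-based columns -> canonical 1..840
    report = report.join(feature_dictionary(), how="left")
    report.index = [f"p{i:04d}" for i in report.index]
    report.to_csv(out / "importance.csv", index_label="feature")

    ranking_df = ex.fold_averaged_ranking(cv, X, y, method="shap",
                                          seed=cfg.seed, **shap_kwargs)
    ranking = ranking_df.index.to_numpy()
    ks = tuple(k for k in cfg.topk_grid if k <= ranking.size)
    sweep = ex.topk_sweep(X, y, ranking,
                          ks, tuple(cl.ModelSpec(m, seed=cfg.seed)
                                    for m in cfg.models))
    sweep.table.to_csv(out / "topk_sweep.csv")
    log.info("explain: ranked %d features; swept k in %s", ranking.size, ks)

    top_feature = int(ranking[0])
    model = cv.fold_models[0]
    feat0 = cv.fold_features[0]
    if top_feature in feat0:
        col = int(np.flatnonzero(feat0 == top_feature)[0])
        phi, _ = shap_values_for(model, X[:, feat0], cfg)
        dep = ex.dependence_table(col, X[:, feat0], phi)
        dep.to_csv(out / f"dependence_p{top_feature + 1:04d}.csv", index=False)

    write_manifest(out / "manifest.json", cfg, counts)
    return {"metrics": results, "importance": report, "sweep": sweep.table}


def shap_values_for(model, X: np.ndarray, cfg: PipelineConfig):
    """Shapley values with the pipeline's sampling settings."""
    bg = X[:min(len(X), cfg.shap_background)]
    return ex.shap_values(model, X, background=bg, seed=cfg.seed,
                          n_permutations=cfg.shap_permutations)
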