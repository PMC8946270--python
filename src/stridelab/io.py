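"""File formats, configuration, and run manifests.

All on-disk artifacts are plain CSV/JSON (there is no standard container
format for insole IMU data):

* recording CSV: ``time_s,acc_x,acc_y,acc_z,gyro_x,gyro_y,gyro_z`` (one file
  per foot; acc in g, gyro in deg/s);
* events CSV: ``foot,event,time_s`` with event in {HS, TO, HR, FA, TV};
* cohort manifest CSV: ``subject_id,label,right_file,left_file``;
* spatial-temporal CSV: one row per subject, the 24 named parameters;
* feature CSV: ``subject_id,label,p0001..p0840`` plus a companion dictionary
  CSV mapping each index to (foot, phase, signal, stat).

Every numeric default in :class:`PipelineConfig` is tagged in the emitted
run manifest with its provenance: ``paper`` for values fixed by the study
conventions this package re-implements (sampling rate, hyperparameters,
selection size, cohort sizes), ``design`` for values this package chose
(thresholds, noise scales, simulator shape constants).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import GaitError, GaitEvents, ImuRecording

__all__ = ["read_recording_csv", "write_recording_csv", "write_events_csv",
           "read_events_csv", "PipelineConfig", "config_hash",
           "write_manifest"]

_REC_COLUMNS = ["time_s", "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y",
                "gyro_z"]


def write_recording_csv(rec: ImuRecording, path: str | Path) -> None:
    df = pd.DataFrame(np.column_stack([rec.t, rec.acc, rec.gyro]),
                      columns=_REC_COLUMNS)
    df.to_csv(path, index=False)


def read_recording_csv(path: str | Path, foot: str,
                       fs: float | None = None) -> ImuRecording:
    """Read a recording CSV; ``fs`` is inferred from the time column when
    omitted."""
    path = Path(path)
    if not path.exists():
        raise GaitError(f"recording file not found: {path}")
    df = pd.read_csv(path)
    missing = set(_REC_COLUMNS) - set(df.columns)
    if missing:
        raise GaitError(f"{path}: missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if fs is None:
        if t.size < 2:
            raise GaitError(f"{path}: cannot infer sampling rate")
        fs = 1.0 / float(np.median(np.diff(t)))
    return ImuRecording(fs=round(fs, 6), t=t,
                        acc=df[_REC_COLUMNS[1:4]].to_numpy(dtype=float),
                        gyro=df[_REC_COLUMNS[4:7]].to_numpy(dtype=float),
                        foot=foot)


def write_events_csv(events_by_foot: dict, path: str | Path) -> None:
    rows = []
    for foot, ev in events_by_foot.items():
        for t in ev.hs:
            rows.append((foot, "HS", t))
        for name in ("to", "hr", "fa", "tv"):
            for t in getattr(ev, name):
                rows.append((foot, name.upper(), t))
    df = pd.DataFrame(rows, columns=["foot", "event", "time_s"])
    df.sort_values(["foot", "time_s"]).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> dict:
    """Reassemble per-foot :class:`GaitEvents` from a flat events CSV."""
    path = Path(path)
    if not path.exists():
        raise GaitError(f"events file not found: {path}")
    df = pd.read_csv(path)
    out = {}
    for foot, sub in df.groupby("foot"):
        times = {e: np.sort(sub.loc[sub["event"] == e, "time_s"].to_numpy())
                 for e in ("HS", "TO", "HR", "FA", "TV")}
        hs = times["HS"]
        n = hs.size - 1

        def per_stride(arr: np.ndarray) -> np.ndarray:
            vals = np.full(n, np.nan)
            for i in range(n):
                inside = arr[(arr > hs[i]) & (arr < hs[i + 1])]
                if inside.size:
                    vals[i] = inside[0]
            return vals

        out[foot] = GaitEvents(foot, hs, per_stride(times["TO"]),
                               per_stride(times["HR"]), per_stride(times["FA"]),
                               per_stride(times["TV"]))
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Provenance of every numeric default: study convention vs package choice.
DEFAULT_SOURCES = {
    "fs": "paper", "n_per_group": "paper", "select_k": "paper",
    "rf.n_estimators": "paper", "rf.max_depth": "paper",
    "rf.max_features": "paper",
    "xgboost.learning_rate": "paper", "xgboost.max_depth": "paper",
    "xgboost.gamma": "paper", "xgboost.subsample": "paper",
    "xgboost.colsample_bytree": "paper", "xgboost.n_estimators": "design",
    "svm.gamma": "paper", "svm.C": "paper",
    "duration": "design", "seed": "design", "jitter_sd": "design",
    "zupt_gyro_thresh_dps": "design", "zupt_acc_thresh_g": "design",
    "zupt_window": "design", "ekf_sigma_acc": "design",
    "ekf_sigma_gyro": "design", "ekf_sigma_vel": "design",
    "shap_permutations": "design", "shap_background": "design",
    "profile_a.*": "design", "profile_b.*": "design", "topk_grid": "paper",
}


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; round-trips losslessly through YAML."""

    fs: float = 100.0
    duration: float = 30.0
    n_per_group: int = 21
    seed: int = 0
    jitter_sd: float = 0.02
    profile_a: dict = field(default_factory=lambda: dict(
        cadence=114.0, stance_percent=58.8, ds1_percent=9.7,
        stride_length=0.95, asymmetry=0.031))
    profile_b: dict = field(default_factory=lambda: dict(
        cadence=114.0, stance_percent=60.4, ds1_percent=10.7,
        stride_length=0.93, asymmetry=0.032))
    input_manifest: str | None = None
    zupt_gyro_thresh_dps: float = 15.0
    zupt_acc_thresh_g: float = 0.08
    zupt_window: int = 5
    ekf_sigma_acc: float = 0.02
    ekf_sigma_gyro: float = 0.2
    ekf_sigma_vel: float = 0.01
    select_k: int = 100
    models: tuple = ("rf", "xgboost", "svm-linear", "svm-rbf")
    importance_model: str = "xgboost"
    importance_methods: tuple = ("gini", "permutation", "shap")
    topk_grid: tuple = (2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 16, 17, 18, 19, 20, 100)
    shap_permutations: int = 8
    shap_background: int = 20

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise GaitError(f"unknown config keys: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in d and isinstance(getattr(cls(), f.name), tuple):
                d[f.name] = tuple(d[f.name])
        return cls(**d)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(path: str | Path, config: PipelineConfig,
                   stage_counts: dict) -> None:
    import sklearn
    import scipy
    import xgboost
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config_hash(config),
        "default_sources": DEFAULT_SOURCES,
        "seed": config.seed,
        "stages": stage_counts,
        "versions": {
            "numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "scikit-learn": sklearn.__version__,
            "xgboost": xgboost.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
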