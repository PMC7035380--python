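"""File formats and the end-to-end pipeline driver.

Signal files are plain text (one voltage per line) with a ``<name>.meta.json``
sidecar carrying the sampling rate, duration, entity id and class label.
Trajectories and feature tables are CSV.  ``run_pipeline`` chains
simulate -> preprocess -> features -> evaluate-loo -> speed-rate and records
a manifest of everything it wrote.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, sigproc, synthgen
from .features import FEATURE_NAMES, META_COLUMNS, feature_table
from .model import desk_grid, RFGrid

log = logging.getLogger(__name__)


def _sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def write_signal(acq: synthgen.Acquisition, path, extra_meta: dict | None = None) -> Path:
    path = Path(path)
    np.savetxt(path, acq.samples, fmt="%.17g")
    meta = {
        "fs": acq.fs,
        "duration": acq.duration,
        "entity_id": acq.entity_id,
        "class_label": acq.class_label,
    }
    if extra_meta:
        meta.update(extra_meta)
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_signal(path) -> synthgen.Acquisition:
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("fs", "duration", "entity_id", "class_label"):
        if key not in meta:
            raise KeyError(f"sidecar {sidecar} missing required field {key!r}")
    samples = np.loadtxt(path, ndmin=1)
    if len(samples) != round(meta["fs"] * meta["duration"]):
        raise ValueError(
            f"{path}: {len(samples)} samples but sidecar implies "
            f"{round(meta['fs'] * meta['duration'])}"
        )
    return synthgen.Acquisition(
        samples=samples, fs=meta["fs"], duration=meta["duration"],
        entity_id=meta["entity_id"], class_label=meta["class_label"],
    )


def write_features(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_features(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    expected = [*META_COLUMNS, *FEATURE_NAMES]
    got = list(table.columns)
    if sorted(got) != sorted(expected):
        n_feat = len([c for c in got if c not in META_COLUMNS])
        raise ValueError(
            f"feature table must carry exactly the 54 canonical features "
            f"plus {META_COLUMNS}; got {n_feat} feature columns"
        )
    if got != expected:
        warnings.warn("feature columns were permuted; reordering to canonical order")
        table = table[expected]
    return table


def write_trajectory(traj, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"time_s": traj.times, "position_m": traj.positions,
         "direction": traj.direction, "repetition": traj.repetition}
    ).to_csv(path, index=False)
    return path


def read_trajectories(path):
    """Trajectories from a (time_s, position_m[, direction, repetition]) CSV,
    one per (direction, repetition) group."""
    from .force import Trajectory

    df = pd.read_csv(path)
    if "direction" not in df:
        df["direction"] = "+x"
    if "repetition" not in df:
        df["repetition"] = 0
    trajs = []
    for (direction, rep), g in df.groupby(["direction", "repetition"], sort=True):
        trajs.append(
            Trajectory(
                times=g["time_s"].to_numpy(), positions=g["position_m"].to_numpy(),
                direction=str(direction), repetition=int(rep),
            )
        )
    return trajs


DEFAULT_CONFIG = {
    "preset": "separated",  # or "identical"
    "entities_per_class": evaluation.DESK_SCALE["entities_per_class"],
    "duration": evaluation.DESK_SCALE["duration"],
    "runs": evaluation.DESK_SCALE["n_runs"],
    "k_folds": evaluation.DESK_SCALE["k_folds"],
    "grid": "desk",  # "desk", "full", or {"n_trees": [...], ...}
    "sr_repetitions": 500,
    "entity_jitter": 0.1,
}


def _resolve_grid(grid) -> RFGrid:
    if grid == "desk":
        return desk_grid()
    if grid == "full":
        return RFGrid()
    return RFGrid(
        n_trees=tuple(grid["n_trees"]),
        n_predictors=tuple(grid["n_predictors"]),
        min_leaf=tuple(grid["min_leaf"]),
    )


def _cohort_specs(config: dict):
    counts = {label: int(config["entities_per_class"]) for label in synthgen.CLASS_ORDER}
    maker = (
        synthgen.separated_class_specs
        if config["preset"] == "separated"
        else synthgen.identical_class_specs
    )
    return maker(counts, entity_jitter=float(config["entity_jitter"]))


def run_pipeline(config: dict | None, out_dir, seed: int) -> dict:
    """simulate -> preprocess -> features -> evaluate-loo -> speed-rate.

    Returns (and writes) a manifest recording every stage's inputs, outputs
    and seeds.  All randomness derives from ``seed`` via fixed per-stage
    derivations.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    if int(cfg["entities_per_class"]) < 1:
        raise ValueError("entities_per_class must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    specs = _cohort_specs(cfg)
    acqs = synthgen.generate_cohort(specs, duration=float(cfg["duration"]), seed=int(seed))
    log.info("simulate: %d acquisitions of %.1f s", len(acqs), float(cfg["duration"]))

    pcfg = sigproc.PreprocessConfig()
    epochs = []
    n_rejected = 0
    for acq in acqs:
        es = sigproc.preprocess(acq, pcfg)
        n_rejected += sum(not e.accepted for e in es)
        epochs.extend(es)
    log.info("preprocess: %d epochs, %d rejected", len(epochs), n_rejected)

    fs = specs[0].scatter.fs
    table = feature_table(epochs, fs)
    features_path = write_features(table, out / "features.csv")

    grid = _resolve_grid(cfg["grid"])
    plan, runs, summary = evaluation.evaluate_loo(
        table, grid, runs=cfg["runs"], seed=int(seed), k_folds=int(cfg["k_folds"])
    )
    sr = evaluation.speed_rate_over_runs(
        runs, repetitions=int(cfg["sr_repetitions"]), seed=int(seed) + 1
    )
    report = {
        "config": {k: v for k, v in cfg.items() if not isinstance(v, dict)},
        "seed": int(seed),
        "n_acquisitions": len(acqs),
        "n_epochs": len(epochs),
        "n_rejected_epochs": n_rejected,
        "run_accounting": evaluation.run_accounting(plan),
        "loo": {k: v for k, v in summary.items() if k != "pooled_confusion"},
        "pooled_confusion": summary["pooled_confusion"].tolist(),
        "speed_rate": {
            "mean_portions": sr.mean_portions,
            "sd_portions": sr.sd_portions,
            "mean_seconds": sr.mean_seconds,
            "sd_seconds": sr.sd_seconds,
            "fraction_single_portion": sr.fraction_single_portion,
            "n_failures": sr.n_failures,
        },
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    runs_df = pd.DataFrame(
        [
            {
                "test_entities": "|".join(r.test_entities),
                "accuracy": r.accuracy,
                "f_measure": r.f_measure,
                "entity_accuracy": r.entity_accuracy,
                "n_trees": r.params[0],
                "n_predictors": r.params[1],
                "min_leaf": r.params[2],
                "seed": r.seed,
            }
            for r in runs
        ]
    )
    runs_path = out / "runs.csv"
    runs_df.to_csv(runs_path, index=False)
    manifest = {
        "seed": int(seed),
        "files": [str(features_path), str(summary_path), str(runs_path)],
        "stages": ["simulate", "preprocess", "features", "evaluate-loo", "speed-rate"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    report["manifest"] = manifest
    return report
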