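"""Staged pipeline: simulate -> preprocess -> tune -> train -> evaluate.

Each stage writes into a fixed run-directory layout::

    <run_dir>/
      manifest.json        config, config hash, seeds, package versions
      cubes/               ENVI cubes + labels.csv          (simulate)
      patches/             patches.npz + manifest.json      (preprocess)
      tuning/              trace.csv + best.json            (tune, optional)
      models/              model.npz + model.json + history.csv  (train)
      reports/             report.csv/.json, predictions.csv     (evaluate)

Stages are skipped when their completion marker exists (resume semantics);
``force`` reruns everything.  All randomness derives from the config seed, so
re-running a desk-budget config reproduces every CSV byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io as _io
from .evaluation import evaluate_predictions, split_samples, summarize_reference
from .experiments import desk_spec, paper_spec, _per_fruit
from .hpo import ma_cnn_space, run_boa
from .models import build_model, load_model, save_model, train, count_trainable_parameters
from .preprocess import FruitPatchDataset
from .synthetic_data import LabeledCube, SyntheticSceneParams, generate_dataset, save_dataset

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "preprocess", "tune", "train", "evaluate")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "budget": "desk",  # desk | paper
    "run_dir": "runs/demo",
    "data_dir": None,  # use pre-existing ENVI dir + labels.csv instead of simulating
    "simulate": {"n_cubes": 48, "n_rows": 48, "n_cols": 48, "n_bands": 24},
    "preprocess": {"threshold": 1.6, "k_centers": 6, "crop_size": None},
    "tune": {"enabled": False, "iters": 5, "folds": 3, "epochs": 2},
    "train": {"kind": "ma-cnn", "epochs": 8},
    "evaluate": {"ratio": [5, 1]},
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML config on top of the defaults; ``overrides`` wins last."""
    import yaml

    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update({k: v for k, v in value.items() if v is not None})
        else:
            config[key] = value
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    if config["budget"] not in ("desk", "paper"):
        raise ValueError(f"budget must be desk or paper, got {config['budget']!r}")
    if config["train"]["kind"] not in ("ca-cnn", "sa-cnn", "ma-cnn"):
        raise ValueError(f"unknown model kind {config['train']['kind']!r}")
    data_dir = config.get("data_dir")
    if data_dir is not None:
        labels = Path(data_dir) / "labels.csv"
        if not labels.is_file():
            raise FileNotFoundError(f"labels file not found: {labels}")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _marker(run_dir: Path, stage: str) -> Path:
    return run_dir / f".{stage}.done"


def _write_manifest(run_dir: Path, config: dict) -> None:
    manifest = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": config["seed"],
        "versions": {"brixnet": __version__, "numpy": np.__version__},
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _scene_params(config: dict) -> SyntheticSceneParams:
    sim = dict(config["simulate"])
    n_cubes = sim.pop("n_cubes")
    return SyntheticSceneParams(seed=config["seed"], **sim), n_cubes


def _stage_simulate(run_dir: Path, config: dict) -> None:
    if config.get("data_dir") is not None:
        return  # external data: nothing to simulate
    params, n_cubes = _scene_params(config)
    cubes, labels = generate_dataset(params, n_cubes, config["seed"])
    save_dataset(cubes, labels, run_dir / "cubes")


def _load_cubes(cube_dir: Path):
    labels = _io.read_labels(cube_dir / "labels.csv")
    for _, row in labels.iterrows():
        sid = row["sample_id"]
        raw, wl = _io.read_envi(cube_dir / f"{sid}_raw")
        white, _ = _io.read_envi(cube_dir / f"{sid}_white")
        black, _ = _io.read_envi(cube_dir / f"{sid}_black")
        yield LabeledCube(
            raw=raw, white_ref=white, black_ref=black, wavelengths=wl,
            ssc=float(row["ssc_brix"]), truth_mask=np.zeros(raw.shape[:2], bool),
            sample_id=sid,
        )


def _stage_preprocess(run_dir: Path, config: dict) -> None:
    cube_dir = Path(config["data_dir"]) if config.get("data_dir") else run_dir / "cubes"
    pp = config["preprocess"]
    ds = FruitPatchDataset.from_labeled_cubes(
        _load_cubes(cube_dir),
        threshold=pp["threshold"],
        k_centers=pp["k_centers"],
        crop_size=pp["crop_size"],
    )
    xs, xp, y, pids = ds.patch_arrays(ds.sample_ids, seed=config["seed"])
    out = run_dir / "patches"
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        out / "patches.npz",
        spectral=xs.astype(np.float32),
        spatial=xp.astype(np.float32),
        labels=y,
        patch_sample_ids=np.array(pids),
        wavelengths=ds.cubes[0].wavelengths,
    )
    counts: dict[str, int] = {}
    for pid in pids:
        counts[pid] = counts.get(pid, 0) + 1
    (out / "manifest.json").write_text(
        json.dumps({"k_centers": pp["k_centers"], "threshold": pp["threshold"],
                    "n_fruits": len(ds), "patches_per_sample": counts},
                   indent=2, sort_keys=True)
    )


def _load_patches(run_dir: Path):
    data = np.load(run_dir / "patches" / "patches.npz", allow_pickle=False)
    return (data["spectral"], data["spatial"], data["labels"],
            [str(s) for s in data["patch_sample_ids"]], data["wavelengths"])


def _model_spec(config: dict, tuned: dict | None = None):
    kind = config["train"]["kind"]
    epochs = config["train"]["epochs"]
    spec = paper_spec(kind, epochs=epochs) if config["budget"] == "paper" else desk_spec(kind, epochs=epochs)
    if tuned:
        spec.learning_rate = tuned.get("learning_rate", spec.learning_rate)
        spec.batch_size = tuned.get("batch_size", spec.batch_size)
        spec.optimizer = tuned.get("optimizer", spec.optimizer)
        spec.fc_activation = tuned.get("activation", spec.fc_activation)
    return spec


def _split_patches(xs, xp, y, pids, ids):
    wanted = set(ids)
    sel = np.array([pid in wanted for pid in pids])
    return xs[sel], xp[sel], y[sel], [p for p, s in zip(pids, sel) if s]


def _stage_tune(run_dir: Path, config: dict) -> None:
    if not config["tune"].get("enabled", False):
        return
    xs, xp, y, pids, _wl = _load_patches(run_dir)
    # rebuild a fruit-level dataset view from patches for fold assignment
    order = list(dict.fromkeys(pids))
    tcfg = config["tune"]
    spec = _model_spec(config)
    spec.epochs = tcfg["epochs"]
    space = ma_cnn_space()

    def objective(hp):
        trial = _model_spec(config, tuned=hp)
        trial.epochs = tcfg["epochs"]
        trial.fc_neurons = (min(hp.get("fc1", 32), 64), min(hp.get("fc2", 16), 64))
        rng = np.random.default_rng(config["seed"])
        perm = rng.permutation(len(order))
        folds = np.array_split(perm, tcfg["folds"])
        scores = []
        for k in range(tcfg["folds"]):
            val_ids = [order[i] for i in folds[k]]
            train_ids = [order[i] for j in range(tcfg["folds"]) if j != k for i in folds[j]]
            txs, txp, ty, _ = _split_patches(xs, xp, y, pids, train_ids)
            vxs, vxp, vy, vp = _split_patches(xs, xp, y, pids, val_ids)
            model = build_model(trial, xs.shape[3], seed=config["seed"], dtype=np.float32)
            trained = train(model,
                            txs if trial.spectral_branch is not None else None,
                            txp if trial.spatial_branch is not None else None,
                            ty, trial, seed=config["seed"] + k)
            fruit_ids, preds = _per_fruit(vp, trained.predict_brix(vxs, vxp))
            truth = {p: float(vy[vp.index(p)]) for p in fruit_ids}
            t = np.array([truth[p] for p in fruit_ids])
            ss = float(np.sum((t - t.mean()) ** 2))
            scores.append(1.0 - float(np.sum((t - preds) ** 2)) / ss if ss else 0.0)
        return float(np.mean(scores)), scores

    trace, best = run_boa(space, objective, n_iter=tcfg["iters"], seed=config["seed"])
    out = run_dir / "tuning"
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {"iteration": i, "objective": r.objective, "failed": r.failed,
         "config": json.dumps(r.config, sort_keys=True),
         "fold_r2": json.dumps(r.fold_scores)}
        for i, r in enumerate(trace.iterations)
    ]
    pd.DataFrame(rows).to_csv(out / "trace.csv", index=False, float_format="%.6f")
    (out / "best.json").write_text(json.dumps(best, indent=2, sort_keys=True))


def _stage_train(run_dir: Path, config: dict) -> None:
    xs, xp, y, pids, _wl = _load_patches(run_dir)
    tuned = None
    best_path = run_dir / "tuning" / "best.json"
    if best_path.is_file():
        tuned = json.loads(best_path.read_text())
    spec = _model_spec(config, tuned=tuned)
    ids = list(dict.fromkeys(pids))
    plan = split_samples(ids, ratio=tuple(config["evaluate"]["ratio"]), seed=config["seed"])
    txs, txp, ty, _ = _split_patches(xs, xp, y, pids, plan.calibration_ids)
    model = build_model(spec, xs.shape[3], seed=config["seed"], dtype=np.float32)
    trained = train(
        model,
        txs if spec.spectral_branch is not None else None,
        txp if spec.spatial_branch is not None else None,
        ty, spec, seed=config["seed"],
    )
    out = run_dir / "models"
    out.mkdir(parents=True, exist_ok=True)
    save_model(trained, out / "model")
    pd.DataFrame(trained.training_history).to_csv(
        out / "history.csv", index=False, float_format="%.6f"
    )
    (out / "split.json").write_text(json.dumps(
        {"calibration_ids": plan.calibration_ids, "prediction_ids": plan.prediction_ids,
         "ratio": list(plan.ratio), "seed": plan.seed}, indent=2))


def _stage_evaluate(run_dir: Path, config: dict) -> None:
    xs, xp, y, pids, _wl = _load_patches(run_dir)
    trained = load_model(run_dir / "models" / "model")
    split = json.loads((run_dir / "models" / "split.json").read_text())
    vxs, vxp, vy, vp = _split_patches(xs, xp, y, pids, split["prediction_ids"])
    fruit_ids, preds = _per_fruit(vp, trained.predict_brix(vxs, vxp))
    truth_map = {p: float(vy[vp.index(p)]) for p in fruit_ids}
    truth = np.array([truth_map[p] for p in fruit_ids])
    report = evaluate_predictions(truth, preds, label_scaler=trained.label_scaler)
    out = run_dir / "reports"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([report.to_dict()]).to_csv(out / "report.csv", index=False, float_format="%.6f")
    fruit_labels = [y[pids.index(p)] for p in dict.fromkeys(pids)]
    summary = {
        "report": report.to_dict(),
        "reference_summary": summarize_reference(fruit_labels),
        "n_trainable_parameters": count_trainable_parameters(trained),
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    pd.DataFrame({"sample_id": fruit_ids, "ssc_true": truth, "ssc_pred": preds}).to_csv(
        out / "predictions.csv", index=False, float_format="%.6f"
    )


_STAGE_FN = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "tune": _stage_tune,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
}


def run_pipeline(config: dict, force: bool = False, stages: tuple[str, ...] = STAGES) -> Path:
    """Run (or resume) the pipeline; returns the run directory."""
    validate_config(config)
    run_dir = Path(config["run_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    _write_manifest(run_dir, config)
    for stage in STAGES:
        if stage not in stages:
            continue
        marker = _marker(run_dir, stage)
        if marker.exists() and not force:
            continue
        _STAGE_FN[stage](run_dir, config)
        marker.write_text("done")
    return run_dir
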