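"""End-to-end orchestration: simulate -> train -> infer -> evaluate.

Library functions assemble training data from synthetic faces, run both
training stages, apply the trained pipeline and produce the evaluation
summary; ``run_pipeline`` executes the stages against a working directory
with content-hash caching, writing its resolved configuration and a
manifest next to the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import detection as det
from . import prediction as pred
from .config import RunConfig
from .evaluation import mm_error_table, summarize, symmetry_report
from .geometry import (NormalizedCloud, VoxelGrid, crop_organ, normalize,
                       save_cloud, save_landmarks, voxelize)
from .registry import ORGAN_ORDER, Organ, organ_spec
from .synthetic import FaceParams, SyntheticFace, generate_dataset

log = logging.getLogger("facemark3d")


# ---------------------------------------------------------------------------
# Dataset assembly


def detection_dataset(faces: list[SyntheticFace], M: int
                      ) -> list[tuple[VoxelGrid, dict]]:
    """(face grid, true boxes) pairs for detector training."""
    out = []
    for face in faces:
        ncloud = NormalizedCloud(
            points=face.transform.to_normalized(face.cloud.points),
            transform=face.transform)
        out.append((voxelize(ncloud, M), face.true_boxes))
    return out


def prediction_dataset(faces: list[SyntheticFace], organ: Organ,
                       margin: float, M_organ: int
                       ) -> list[tuple[VoxelGrid, np.ndarray]]:
    """(organ grid, organ-frame landmark targets) pairs from true boxes."""
    names = organ_spec(organ).landmark_names
    out = []
    for face in faces:
        ncloud = NormalizedCloud(
            points=face.transform.to_normalized(face.cloud.points),
            transform=face.transform)
        grid, transform = crop_organ(ncloud, face.true_boxes[organ],
                                     margin=margin, M_organ=M_organ)
        targets = transform.to_normalized(
            np.stack([face.landmarks[n] for n in names]))
        out.append((grid, targets))
    return out


# ---------------------------------------------------------------------------
# Training stages


def train_full_detector(faces: list[SyntheticFace], config: RunConfig,
                        seed: int) -> tuple[det.DetectionModel, list[float]]:
    model = det.build_detection_net(
        det.DetectionNetConfig(M=config.M,
                               n_blocks=len(config.detection_channels),
                               channels=config.detection_channels,
                               fc_widths=(config.fc_width,)),
        seed=seed)
    data = detection_dataset(faces, config.M)
    opt = det.OptimizerConfig(lr=config.detection.lr,
                              batch_size=config.detection.batch_size)
    history = det.train_detector(model, data, opt, epochs=config.detection.epochs,
                                 seed=seed + 1, lambda1=config.detection.lambda1,
                                 lambda2=config.detection.lambda2,
                                 size_term=config.size_term)
    return model, history


def train_all_predictors(faces: list[SyntheticFace], config: RunConfig,
                         seed: int, organs=ORGAN_ORDER
                         ) -> tuple[dict, dict[Organ, list[float]]]:
    predictors: dict[Organ, pred.PredictionModel] = {}
    histories: dict[Organ, list[float]] = {}
    opt = det.OptimizerConfig(lr=config.prediction.lr,
                              batch_size=config.prediction.batch_size)
    for k, organ in enumerate(organs):
        model = pred.build_prediction_net(
            pred.PredictionNetConfig(organ=organ, M=config.M_organ,
                                     n_blocks=len(config.prediction_channels),
                                     channels=config.prediction_channels,
                                     fc_widths=(config.fc_width,)),
            seed=seed + 10 + k)
        data = prediction_dataset(faces, organ, config.crop_margin, config.M_organ)
        histories[organ] = pred.train_predictor(
            organ, model, data, opt, epochs=config.prediction.epochs,
            seed=seed + 100 + k, lambda1=config.prediction.lambda1,
            lambda2=config.prediction.lambda2)
        predictors[organ] = model
        log.info("trained %s: loss %.4g -> %.4g", organ.value,
                 histories[organ][0], histories[organ][-1])
    return predictors, histories


# ---------------------------------------------------------------------------
# Evaluation helpers


def evaluate_pipeline(detector, predictors, faces: list[SyntheticFace],
                      margin: float = 1.1, use_true_boxes: bool = False):
    """Run end-to-end inference on faces; returns (error table, summary)."""
    preds, truth = {}, {}
    for i, face in enumerate(faces):
        fid = f"face{i:03d}"
        boxes = face.true_boxes if use_true_boxes else None
        preds[fid] = pred.predict_landmarks_mm(detector, predictors, face.cloud,
                                               margin=margin, boxes=boxes)
        truth[fid] = face.landmarks
    table = mm_error_table(preds, truth)
    return table, summarize(table)


def box_center_baseline(faces: list[SyntheticFace]) -> float:
    """Mean mm error of predicting each organ's true-box center everywhere.

    The naive coarse-only baseline: any useful fine stage must beat it.
    """
    errs = []
    for face in faces:
        for organ in ORGAN_ORDER:
            center_mm = face.transform.to_mm(face.true_boxes[organ].center)
            for name in organ_spec(organ).landmark_names:
                errs.append(float(np.linalg.norm(face.landmarks[name] - center_mm)))
    return float(np.mean(errs))


def mean_detection_iou(detector, faces: list[SyntheticFace]) -> float:
    """Mean IoU of predicted vs true boxes over faces and organs."""
    ious = []
    for face in faces:
        ncloud = NormalizedCloud(
            points=face.transform.to_normalized(face.cloud.points),
            transform=face.transform)
        boxes = det.infer_boxes(detector, voxelize(ncloud, detector.config.M))
        for organ in ORGAN_ORDER:
            ious.append(det.box_iou(boxes[organ], face.true_boxes[organ]))
    return float(np.mean(ious))


def recovery_experiment(seed: int, n_faces: int = 80, M: int = 32,
                        detection_epochs: int = 40, prediction_epochs: int = 25,
                        n_points: int = 6000) -> dict:
    """Desk-scale end-to-end experiment: 3/4 train, 1/4 test.

    Generates the synthetic population, trains the detector and the six
    predictors, and measures detection IoU, end-to-end mm error and the
    box-center baseline on the held-out faces.  Returns a flat dict of the
    measured quantities.
    """
    from .config import RunConfig, StageTraining

    cfg = RunConfig(M=M, n_faces=n_faces, n_points=n_points, seed=seed,
                    split=(0.75, 0.25, 0.0),
                    detection=StageTraining(epochs=detection_epochs),
                    prediction=StageTraining(epochs=prediction_epochs))
    dataset = _simulate(cfg)
    detector, det_hist = train_full_detector(dataset["train"], cfg, cfg.seed)
    predictors, pred_hists = train_all_predictors(dataset["train"], cfg, cfg.seed)
    table, summary = evaluate_pipeline(detector, predictors, dataset["test"],
                                       margin=cfg.crop_margin)
    return {
        "n_train": len(dataset["train"]),
        "n_test": len(dataset["test"]),
        "mean_box_iou": mean_detection_iou(detector, dataset["test"]),
        "mean_error_mm": summary["overall_mean_mm"],
        "sd_error_mm": summary["overall_sd_mm"],
        "coverage_within_2.5mm": summary["coverage"]["within_2.5mm"],
        "coverage_within_3.0mm": summary["coverage"]["within_3.0mm"],
        "box_center_baseline_mm": box_center_baseline(dataset["test"]),
        "detection_loss_epoch1": det_hist[0],
        "detection_loss_final": det_hist[-1],
        "prediction_loss_ratio_max": max(h[-1] / h[0] for h in pred_hists.values()),
        "summary": summary,
        "error_table": table,
    }


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(path: str | Path, net, config_obj, seed: int,
                    history: list[float]) -> None:
    """Weights + architecture + seed + loss history in one .npz archive."""
    meta = {"config": dataclasses.asdict(config_obj), "seed": seed,
            "history": list(map(float, history))}
    state = net.state()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta, default=str).encode(),
                                          dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> tuple[dict, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    return state, meta


def load_detector(path: str | Path) -> det.DetectionModel:
    state, meta = load_checkpoint(path)
    cfg = meta["config"]
    cfg["channels"] = tuple(cfg["channels"])
    cfg["fc_widths"] = tuple(cfg["fc_widths"])
    model = det.build_detection_net(det.DetectionNetConfig(**{
        k: v for k, v in cfg.items() if k != "final_size"}))
    model.net.load_state(state)
    model.net.eval()
    return model


def load_predictor(path: str | Path) -> pred.PredictionModel:
    state, meta = load_checkpoint(path)
    cfg = meta["config"]
    cfg["channels"] = tuple(cfg["channels"])
    cfg["fc_widths"] = tuple(cfg["fc_widths"])
    model = pred.build_prediction_net(pred.PredictionNetConfig(**{
        k: v for k, v in cfg.items() if k not in ("final_size", "n_landmarks")}))
    model.net.load_state(state)
    model.net.eval()
    return model


# ---------------------------------------------------------------------------
# Staged pipeline with caching


def _config_hash(config: RunConfig, keys: tuple[str, ...]) -> str:
    payload = {k: getattr(config, k) for k in keys}
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


_STAGE_KEYS = {
    "simulate": ("n_faces", "noise_sd", "n_points", "split", "seed"),
    "train_detect": ("n_faces", "noise_sd", "n_points", "split", "seed", "M",
                     "detection", "detection_channels", "fc_width", "size_term"),
    "train_predict": ("n_faces", "noise_sd", "n_points", "split", "seed", "M",
                      "M_organ", "crop_margin", "prediction",
                      "prediction_channels", "fc_width"),
    "infer": ("n_faces", "noise_sd", "n_points", "split", "seed", "M", "M_organ",
              "crop_margin", "detection", "prediction", "detection_channels",
              "prediction_channels", "fc_width", "size_term"),
    "evaluate": ("n_faces", "noise_sd", "n_points", "split", "seed", "M",
                 "M_organ", "crop_margin", "detection", "prediction",
                 "detection_channels", "prediction_channels", "fc_width",
                 "size_term"),
}


def _stage_cached(workdir: Path, stage: str, digest: str,
                  outputs: list[Path]) -> bool:
    stamp = workdir / f".{stage}.stamp.json"
    if not stamp.is_file() or not all(p.exists() for p in outputs):
        return False
    return json.loads(stamp.read_text()).get("hash") == digest


def _write_stamp(workdir: Path, stage: str, digest: str) -> None:
    (workdir / f".{stage}.stamp.json").write_text(json.dumps({"hash": digest}))


def _simulate(config: RunConfig) -> dict[str, list[SyntheticFace]]:
    return generate_dataset(
        n_faces=config.n_faces, split=config.split, seed=config.seed,
        base_params=FaceParams(noise_sd=config.noise_sd,
                               n_points=config.n_points))


def run_pipeline(config: RunConfig, workdir: str | Path) -> dict:
    """Execute all stages in order, skipping cached completed stages.

    Returns a manifest of artifact paths and the stages actually executed.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(workdir / "config.yaml")
    executed: list[str] = []
    manifest: dict[str, str] = {}

    # --- simulate ---------------------------------------------------------
    data_dir = workdir / "data"
    digest = _config_hash(config, _STAGE_KEYS["simulate"])
    manifest["dataset"] = str(data_dir)
    if not _stage_cached(workdir, "simulate", digest, [data_dir / "manifest.csv"]):
        executed.append("simulate")
        data_dir.mkdir(exist_ok=True)
        dataset = _simulate(config)
        rows = []
        for split_name, faces in dataset.items():
            for j, face in enumerate(faces):
                fid = f"{split_name}{j:03d}"
                save_cloud(data_dir / f"{fid}.ply", face.cloud)
                save_landmarks(data_dir / f"{fid}.landmarks.json", face.landmarks)
                (data_dir / f"{fid}.boxes.json").write_text(json.dumps(
                    {o.value: list(map(float, b.as_vector()))
                     for o, b in face.true_boxes.items()}))
                rows.append({"face_id": fid, "split": split_name,
                             "seed": face.params.seed,
                             **dataclasses.asdict(face.params)})
        pd.DataFrame(rows).to_csv(data_dir / "manifest.csv", index=False)
        _write_stamp(workdir, "simulate", digest)
    # faces regenerate deterministically from the same seed for later stages
    dataset = _simulate(config)

    # --- train detector ---------------------------------------------------
    det_ckpt = workdir / "detector.npz"
    digest = _config_hash(config, _STAGE_KEYS["train_detect"])
    manifest["detector"] = str(det_ckpt)
    if not _stage_cached(workdir, "train_detect", digest, [det_ckpt]):
        executed.append("train_detect")
        model, history = train_full_detector(dataset["train"], config, config.seed)
        save_checkpoint(det_ckpt, model.net, model.config, config.seed, history)
        pd.DataFrame({"epoch": range(len(history)), "loss": history}).to_csv(
            workdir / "detector_log.csv", index=False)
        _write_stamp(workdir, "train_detect", digest)
    detector = load_detector(det_ckpt)

    # --- train predictors -------------------------------------------------
    digest = _config_hash(config, _STAGE_KEYS["train_predict"])
    pred_ckpts = {o: workdir / f"predictor_{o.value}.npz" for o in ORGAN_ORDER}
    manifest.update({f"predictor_{o.value}": str(p) for o, p in pred_ckpts.items()})
    if not _stage_cached(workdir, "train_predict", digest, list(pred_ckpts.values())):
        executed.append("train_predict")
        predictors, histories = train_all_predictors(dataset["train"], config,
                                                     config.seed)
        for organ, model in predictors.items():
            save_checkpoint(pred_ckpts[organ], model.net, model.config,
                            config.seed, histories[organ])
        _write_stamp(workdir, "train_predict", digest)
    predictors = {o: load_predictor(p) for o, p in pred_ckpts.items()}

    # --- infer + evaluate on the test split -------------------------------
    digest = _config_hash(config, _STAGE_KEYS["evaluate"])
    summary_path = workdir / "summary.json"
    manifest["summary"] = str(summary_path)
    manifest["errors"] = str(workdir / "errors.csv")
    if not _stage_cached(workdir, "evaluate", digest, [summary_path]):
        executed.append("evaluate")
        table, summary = evaluate_pipeline(detector, predictors, dataset["test"],
                                           margin=config.crop_margin)
        table.to_csv(workdir / "errors.csv", index=False)
        symmetry_report(table).to_csv(workdir / "symmetry.csv", index=False)
        summary["mean_box_iou"] = mean_detection_iou(detector, dataset["test"])
        summary["box_center_baseline_mm"] = box_center_baseline(dataset["test"])
        summary_path.write_text(json.dumps(summary, indent=1))
        _write_stamp(workdir, "evaluate", digest)

    manifest["executed"] = ",".join(executed)
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"executed": executed, "artifacts": manifest}
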