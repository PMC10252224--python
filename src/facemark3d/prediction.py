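"""Fine stage: per-organ landmark coordinate regression.

Each of the six organs has its own network mapping the cropped organ
occupancy grid to a 3N coordinate vector (N landmarks in the organ frame,
ordered by the registry).  The architecture mirrors the detection stage's
conv/pool/norm/sigmoid cycles, then deepens with a stage of eight
two-convolution pre-activation residual blocks (the classic 18-layer
residual layout transposed to 3D, randomly initialized) before the fully
connected head.

Training optimizes a convex combination of two losses over squared
per-landmark distances: the mean (drives the average error down) and the
max (drives the worst landmark down).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .detection import DetectionModel, OptimizerConfig, infer_boxes, stack_grids
from .geometry import (EmptyCropError, NormalizedCloud, OrganBox, PointCloud,
                       VoxelGrid, crop_organ, normalize, voxelize)
from .registry import ORGAN_ORDER, Organ, organ_spec


class PredictionError(ValueError):
    pass


class EmptyOrganCropError(PredictionError):
    """An organ box contained no points; carries the organ name."""

    def __init__(self, organ: Organ):
        self.organ = organ
        super().__init__(f"empty organ crop for organ '{organ.value}'")


@dataclass
class PredictionNetConfig:
    organ: Organ
    M: int = 32
    n_blocks: int = 3
    channels: tuple[int, ...] = (4, 8, 16)
    n_residual_blocks: int = 8
    fc_widths: tuple[int, ...] = (128,)

    def __post_init__(self) -> None:
        self.organ = Organ(self.organ)
        self.channels = tuple(self.channels)
        self.fc_widths = tuple(self.fc_widths)
        self.n_landmarks = organ_spec(self.organ).n_landmarks
        if len(self.channels) != self.n_blocks:
            raise PredictionError("channels must list one width per block")
        size = self.M
        for _ in range(self.n_blocks):
            if size % 2 or size < 2:
                raise PredictionError(
                    f"M={self.M} cannot be pooled {self.n_blocks} times")
            size //= 2
        self.final_size = size


@dataclass
class PredictionModel:
    net: nn.Sequential
    config: PredictionNetConfig


def build_prediction_net(config: PredictionNetConfig,
                         seed: int = 0) -> PredictionModel:
    """Assemble one organ's network; output is the raw 3N vector."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c_prev = 1
    for c in config.channels:
        layers += [nn.Conv3d(c_prev, c, rng), nn.MaxPool3d(),
                   nn.BatchNorm3d(c), nn.Sigmoid()]
        c_prev = c
    for _ in range(config.n_residual_blocks):
        layers.append(nn.ResidualBlock3d(c_prev, rng))
    layers.append(nn.Flatten())
    width = c_prev * config.final_size ** 3
    for w in config.fc_widths:
        layers += [nn.Linear(width, w, rng), nn.ReLU()]
        width = w
    layers.append(nn.Linear(width, 3 * config.n_landmarks, rng))
    return PredictionModel(net=nn.Sequential(layers), config=config)


# ---------------------------------------------------------------------------
# Losses (squared distances; the mm-scale metric lives in evaluation)


def _check_shapes(pred: np.ndarray, true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.shape != t.shape or p.ndim != 2 or p.shape[1] != 3:
        raise PredictionError(
            f"pred and true must both be N x 3, got {p.shape} vs {t.shape}")
    return p, t


def loss_mean(pred: np.ndarray, true: np.ndarray) -> float:
    """Mean over landmarks of the squared coordinate distance."""
    p, t = _check_shapes(pred, true)
    return float(((p - t) ** 2).sum(axis=1).mean())


def loss_max(pred: np.ndarray, true: np.ndarray) -> float:
    """Largest squared coordinate distance over the landmarks."""
    p, t = _check_shapes(pred, true)
    return float(((p - t) ** 2).sum(axis=1).max())


def loss_combined(pred: np.ndarray, true: np.ndarray, lambda1: float = 0.5,
                  lambda2: float = 0.5) -> float:
    """lambda1 * mean + lambda2 * max; lies between the two."""
    if lambda1 < 0 or lambda2 < 0 or abs(lambda1 + lambda2 - 1.0) > 1e-9:
        raise PredictionError(
            f"lambda1, lambda2 must be nonnegative and sum to 1, "
            f"got {lambda1}, {lambda2}")
    return lambda1 * loss_mean(pred, true) + lambda2 * loss_max(pred, true)


def _combined_loss_batch_grad(pred: np.ndarray, true: np.ndarray,
                              lambda1: float, lambda2: float
                              ) -> tuple[float, np.ndarray]:
    """Batch-mean combined loss on (B, N, 3) and gradient w.r.t. pred."""
    B, N, _ = pred.shape
    diff = pred - true
    sq = (diff ** 2).sum(axis=2)  # (B, N)
    worst = sq.argmax(axis=1)
    loss = float((lambda1 * sq.mean(axis=1) + lambda2 * sq[np.arange(B), worst]).mean())
    grad = 2 * lambda1 * diff / N
    grad[np.arange(B), worst] += 2 * lambda2 * diff[np.arange(B), worst]
    return loss, grad / B


# ---------------------------------------------------------------------------
# Training


def train_predictor(organ: Organ | str, model: PredictionModel, dataset,
                    optimizer_cfg: OptimizerConfig, epochs: int, seed: int,
                    lambda1: float = 0.5, lambda2: float = 0.5,
                    callback=None) -> list[float]:
    """Fit one organ's network; returns per-epoch mean training loss.

    ``dataset`` yields (VoxelGrid, N x 3 organ-frame targets) pairs.  Each
    organ has fully independent parameters.
    """
    organ = Organ(organ)
    if model.config.organ is not organ:
        raise PredictionError(
            f"model built for {model.config.organ.value}, asked to train {organ.value}")
    if len(dataset) == 0:
        raise PredictionError(f"empty training set for organ {organ.value}")
    N = model.config.n_landmarks
    X = stack_grids([g for g, _ in dataset])
    Y = np.stack([np.asarray(t, dtype=float).reshape(N, 3) for _, t in dataset])
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.net.parameters(), lr=optimizer_cfg.lr,
                  beta1=optimizer_cfg.beta1, beta2=optimizer_cfg.beta2)
    n = X.shape[0]
    bs = min(optimizer_cfg.batch_size, n)
    history: list[float] = []
    model.net.train()
    for epoch in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            raw = model.net.forward(X[idx])
            pred = raw.reshape(len(idx), N, 3).astype(np.float64)
            loss, gpred = _combined_loss_batch_grad(pred, Y[idx], lambda1, lambda2)
            if not np.isfinite(loss):
                raise PredictionError(
                    f"prediction loss diverged for {organ.value} at epoch {epoch}")
            opt.zero_grad()
            model.net.backward(gpred.reshape(len(idx), 3 * N).astype(np.float32))
            opt.step()
            total += loss * len(idx)
        history.append(total / n)
        if callback is not None:
            callback(epoch, history[-1])
    model.net.eval()
    return history


# ---------------------------------------------------------------------------
# End-to-end inference


def predict_organ(model: PredictionModel, grid: VoxelGrid) -> np.ndarray:
    """Organ-frame landmark coordinates (N x 3) for one cropped grid."""
    model.net.eval()
    x = grid.occupancy.astype(np.float32)[None, None]
    raw = model.net.forward(x)
    return raw.reshape(model.config.n_landmarks, 3).astype(np.float64)


def predict_landmarks_mm(detector: DetectionModel,
                         predictors: dict, cloud: PointCloud,
                         margin: float = 1.1,
                         boxes: dict | None = None) -> dict[str, np.ndarray]:
    """Full coarse-to-fine pipeline: mm cloud -> 32 named mm landmarks.

    normalize -> voxelize -> detect boxes -> crop each organ -> regress
    organ-frame coordinates -> invert organ then face transforms.  Passing
    ``boxes`` skips detection (e.g. to evaluate with ground-truth boxes).
    """
    missing = [o.value for o in ORGAN_ORDER if o not in predictors]
    if missing:
        raise PredictionError(f"missing predictors for organs: {missing}")
    ncloud = normalize(cloud)
    if boxes is None:
        grid = voxelize(ncloud, detector.config.M)
        boxes = infer_boxes(detector, grid)
    out: dict[str, np.ndarray] = {}
    for organ in ORGAN_ORDER:
        model = predictors[organ]
        try:
            organ_grid, transform = crop_organ(ncloud, boxes[organ],
                                               margin=margin,
                                               M_organ=model.config.M)
        except EmptyCropError:
            raise EmptyOrganCropError(organ) from None
        coords = predict_organ(model, organ_grid)
        mm = transform.to_mm(coords)
        for name, xyz in zip(organ_spec(organ).landmark_names, mm):
            out[name] = xyz
    return out
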