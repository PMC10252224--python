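"""Coarse stage: volumetric detection of the six organ bounding boxes.

A stack of conv(3^3) -> maxpool(2^3) -> batchnorm -> sigmoid cycles over the
M^3 occupancy grid, flattened into fully connected layers ending in a linear
36-unit head: six boxes, each encoded as center (x, y, z) plus per-axis
half-extents (xl, yl, zl) in the face-normalized frame, in the fixed organ
order eyes, nose, lips, chin, right face, left face.

The raw head output is decoded so that invalid boxes are unrepresentable:
centers pass through tanh onto (-1, 1), half-extents through softplus plus a
floor of 1e-3.  The training loss weighs center error against box-size error
with a convex pair (lambda1, lambda2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .geometry import OrganBox, VoxelGrid
from .registry import ORGAN_ORDER

HALF_EXTENT_FLOOR = 1e-3


class DetectionError(ValueError):
    pass


@dataclass
class DetectionNetConfig:
    M: int = 32
    n_blocks: int = 3
    channels: tuple[int, ...] = (8, 16, 32)
    fc_widths: tuple[int, ...] = (128,)

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.fc_widths = tuple(self.fc_widths)
        if self.n_blocks < 2:
            raise DetectionError(f"need n_blocks >= 2, got {self.n_blocks}")
        if len(self.channels) != self.n_blocks:
            raise DetectionError("channels must list one width per block")
        size = self.M
        for _ in range(self.n_blocks):
            if size % 2 or size < 2:
                raise DetectionError(
                    f"M={self.M} cannot be pooled {self.n_blocks} times "
                    f"(reaches size {size})")
            size //= 2
        self.final_size = size


@dataclass
class DetectionModel:
    net: nn.Sequential
    config: DetectionNetConfig


def build_detection_net(config: DetectionNetConfig,
                        seed: int = 0) -> DetectionModel:
    """Assemble the detection network; output is the raw 36-vector."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c_prev = 1
    for c in config.channels:
        layers += [nn.Conv3d(c_prev, c, rng), nn.MaxPool3d(),
                   nn.BatchNorm3d(c), nn.Sigmoid()]
        c_prev = c
    layers.append(nn.Flatten())
    width = config.channels[-1] * config.final_size ** 3
    for w in config.fc_widths:
        layers += [nn.Linear(width, w, rng), nn.ReLU()]
        width = w
    layers.append(nn.Linear(width, 36, rng))
    return DetectionModel(net=nn.Sequential(layers), config=config)


# ---------------------------------------------------------------------------
# Box encoding / decoding


def decode_boxes(raw: np.ndarray) -> np.ndarray:
    """Raw (B, 36) head output -> (B, 6, 6) valid box vectors."""
    r = raw.reshape(raw.shape[0], 6, 6).astype(np.float64)
    centers = np.tanh(r[..., :3])
    halves = np.logaddexp(0.0, r[..., 3:]) + HALF_EXTENT_FLOOR  # softplus
    return np.concatenate([centers, halves], axis=-1)


def _decode_with_grad(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decoded boxes plus d(decoded)/d(raw), elementwise."""
    r = raw.reshape(raw.shape[0], 6, 6).astype(np.float64)
    centers = np.tanh(r[..., :3])
    halves = np.logaddexp(0.0, r[..., 3:]) + HALF_EXTENT_FLOOR
    dec = np.concatenate([centers, halves], axis=-1)
    dcent = 1.0 - centers ** 2
    dhalf = 1.0 / (1.0 + np.exp(-np.clip(r[..., 3:], -30, 30)))
    return dec, np.concatenate([dcent, dhalf], axis=-1)


def boxes_to_array(boxes) -> np.ndarray:
    """6 OrganBox (dict keyed by organ, or ordered sequence) -> (6, 6)."""
    if isinstance(boxes, dict):
        boxes = [boxes[o] for o in ORGAN_ORDER]
    arr = np.stack([b.as_vector() if isinstance(b, OrganBox) else np.asarray(b, float)
                    for b in boxes])
    if arr.shape != (6, 6):
        raise DetectionError(f"expected 6 boxes of 6 values, got shape {arr.shape}")
    return arr


def array_to_boxes(arr: np.ndarray) -> dict:
    arr = np.asarray(arr, dtype=float).reshape(6, 6)
    return {o: OrganBox.from_vector(v) for o, v in zip(ORGAN_ORDER, arr)}


# ---------------------------------------------------------------------------
# Loss


def _check_lambdas(lambda1: float, lambda2: float) -> None:
    if lambda1 < 0 or lambda2 < 0 or abs(lambda1 + lambda2 - 1.0) > 1e-9:
        raise DetectionError(
            f"lambda1, lambda2 must be nonnegative and sum to 1, "
            f"got {lambda1}, {lambda2}")


def detection_loss(pred_boxes, true_boxes, lambda1: float = 0.5,
                   lambda2: float = 0.5, size_term: str = "squared_diff") -> float:
    """Mean over the six organs of weighted center + size squared errors.

    ``size_term="squared_diff"`` (default) penalizes (xl - xl_hat)^2 per
    axis; ``"diff_of_squares_abs"`` uses |xl^2 - xl_hat^2| instead.
    """
    _check_lambdas(lambda1, lambda2)
    p = boxes_to_array(pred_boxes)
    t = boxes_to_array(true_boxes)
    center = ((p[:, :3] - t[:, :3]) ** 2).sum(axis=1)
    if size_term == "squared_diff":
        size = ((p[:, 3:] - t[:, 3:]) ** 2).sum(axis=1)
    elif size_term == "diff_of_squares_abs":
        size = np.abs(p[:, 3:] ** 2 - t[:, 3:] ** 2).sum(axis=1)
    else:
        raise DetectionError(f"unknown size_term {size_term!r}")
    return float((lambda1 * center + lambda2 * size).mean())


def _detection_loss_batch_grad(dec: np.ndarray, true: np.ndarray,
                               lambda1: float, lambda2: float,
                               size_term: str) -> tuple[float, np.ndarray]:
    """Batch-mean loss on decoded (B, 6, 6) boxes and its gradient."""
    B = dec.shape[0]
    diff = dec - true
    if size_term == "squared_diff":
        per_organ = (lambda1 * (diff[..., :3] ** 2).sum(-1)
                     + lambda2 * (diff[..., 3:] ** 2).sum(-1))
        grad = np.concatenate([2 * lambda1 * diff[..., :3],
                               2 * lambda2 * diff[..., 3:]], axis=-1)
    else:
        sq = dec[..., 3:] ** 2 - true[..., 3:] ** 2
        per_organ = (lambda1 * (diff[..., :3] ** 2).sum(-1)
                     + lambda2 * np.abs(sq).sum(-1))
        grad = np.concatenate([2 * lambda1 * diff[..., :3],
                               2 * lambda2 * np.sign(sq) * dec[..., 3:]], axis=-1)
    loss = float(per_organ.sum() / (6 * B))
    return loss, grad / (6 * B)


def detection_loss_on_raw(raw: np.ndarray, true: np.ndarray,
                          lambda1: float, lambda2: float,
                          size_term: str = "squared_diff"
                          ) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. the raw (B, 36) head output."""
    _check_lambdas(lambda1, lambda2)
    dec, ddec = _decode_with_grad(raw)
    loss, gdec = _detection_loss_batch_grad(dec, true, lambda1, lambda2, size_term)
    return loss, (gdec * ddec).reshape(raw.shape[0], 36).astype(np.float32)


# ---------------------------------------------------------------------------
# Training / inference


@dataclass
class OptimizerConfig:
    lr: float = 1e-3
    batch_size: int = 12
    beta1: float = 0.9
    beta2: float = 0.999


def stack_grids(grids: list[VoxelGrid]) -> np.ndarray:
    return np.stack([g.occupancy for g in grids]).astype(np.float32)[:, None]


def train_detector(model: DetectionModel, dataset, optimizer_cfg: OptimizerConfig,
                   epochs: int, seed: int, lambda1: float = 0.5,
                   lambda2: float = 0.5, size_term: str = "squared_diff",
                   callback=None) -> list[float]:
    """Fit the detector; returns the per-epoch mean training loss.

    ``dataset`` is a sequence of (VoxelGrid, boxes) pairs where ``boxes`` is
    a dict organ -> OrganBox or an ordered 6-sequence.  Reproducible for a
    fixed seed on one device.
    """
    if len(dataset) == 0:
        raise DetectionError("empty detection training set")
    X = stack_grids([g for g, _ in dataset])
    Y = np.stack([boxes_to_array(b) for _, b in dataset])
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
            loss, graw = detection_loss_on_raw(raw, Y[idx], lambda1, lambda2,
                                               size_term)
            if not np.isfinite(loss):
                raise DetectionError(f"detection loss diverged at epoch {epoch}")
            opt.zero_grad()
            model.net.backward(graw)
            opt.step()
            total += loss * len(idx)
        history.append(total / n)
        if callback is not None:
            callback(epoch, history[-1])
    model.net.eval()
    return history


def infer_boxes(model: DetectionModel, grid: VoxelGrid) -> dict:
    """Predict the six organ boxes for one occupancy grid."""
    model.net.eval()
    x = grid.occupancy.astype(np.float32)[None, None]
    raw = model.net.forward(x)
    return array_to_boxes(decode_boxes(raw)[0])


def box_iou(a: OrganBox, b: OrganBox) -> float:
    """Volumetric intersection-over-union of two axis-aligned boxes."""
    lo = np.maximum(a.center - a.half_extents, b.center - b.half_extents)
    hi = np.minimum(a.center + a.half_extents, b.center + b.half_extents)
    inter = float(np.prod(np.clip(hi - lo, 0, None)))
    va = float(np.prod(2 * a.half_extents))
    vb = float(np.prod(2 * b.half_extents))
    union = va + vb - inter
    return inter / union if union > 0 else 0.0
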