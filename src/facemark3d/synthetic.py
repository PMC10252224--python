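"""Parametric synthetic faces with analytically known landmark ground truth.

Stands in for a clinical stereophotogrammetry dataset: each face is a smooth
height-field surface z(x, y) over an elliptical facial outline — a half-
ellipsoid "head" plus Gaussian feature bumps (nose ridge, two eye bulges, a
two-lobed mouth, a chin boss).  The 32 landmarks are images of fixed
parametric positions under the exact surface map, so ground truth is known
to machine precision before measurement noise is added.

Frame: x lateral (subject's left is +x), y superior, z anterior (mm).
The generated cloud receives an asymmetry warp, a rigid pose rotation and
iid Gaussian surface noise; landmarks follow the warp and rotation but not
the noise (they are the true positions an annotator would aim for).

Per-organ ground-truth detection boxes are the landmark bounding boxes in
the face-normalized frame, inflated by a fraction of the box diagonal plus
a minimum half-extent — the convention this package trains and evaluates
detection against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import NormTransform, OrganBox, PointCloud, normalize
from .registry import ORGAN_ORDER, Organ, organ_spec

#: Faces are sampled inside x^2/a^2 + y^2/b^2 <= _RIM; the extreme rim of the
#: ellipse is excluded (a facial scan never wraps around the head, and the
#: height-field slope diverges there).
_RIM = 0.995


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class FaceParams:
    """Generator parameters, mm unless noted."""

    head_a: float = 70.0   # lateral half-axis
    head_b: float = 90.0   # vertical half-axis
    head_c: float = 80.0   # anterior half-axis
    nose_height: float = 16.0  # ridge amplitude
    nose_width: float = 32.0   # alare-to-alare width
    eye_offset_x: float = 30.0  # eye center lateral offset
    eye_offset_y: float = 28.0  # eye center height above face center
    mouth_width: float = 50.0
    jaw_angle: float = 120.0   # degrees; wider angle -> more lateral gonion
    asymmetry: float = 0.03    # dimensionless, in [0, 0.1]
    pose_x: float = 0.0  # rotation about x, degrees
    pose_y: float = 0.0
    pose_z: float = 0.0
    noise_sd: float = 0.3  # mm, isotropic surface noise
    n_points: int = 6000   # K, sampled surface points
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("head_a", "head_b", "head_c", "nose_height", "nose_width",
                     "eye_offset_x", "eye_offset_y", "mouth_width", "jaw_angle"):
            if getattr(self, name) <= 0:
                raise SyntheticError(f"{name} must be positive")
        if not 0 <= self.asymmetry <= 0.1:
            raise SyntheticError(f"asymmetry must be in [0, 0.1], got {self.asymmetry}")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be nonnegative")
        if self.n_points < 1000:
            raise SyntheticError(f"need n_points >= 1000, got {self.n_points}")
        if self.nose_width >= self.head_a:
            raise SyntheticError("nose wider than the head")
        if self.nose_height >= self.head_c / 2:
            raise SyntheticError("nose taller than half the head depth")
        if self.mouth_width >= 1.6 * self.head_a:
            raise SyntheticError("mouth wider than the face")
        if (self.eye_offset_x / self.head_a) ** 2 + (self.eye_offset_y / self.head_b) ** 2 >= 0.8:
            raise SyntheticError("eyes fall outside the facial outline")


@dataclass
class SyntheticFace:
    params: FaceParams
    cloud: PointCloud                      # mm, noisy
    landmarks: dict[str, np.ndarray]       # mm, exact (pre-noise)
    true_boxes: dict[Organ, OrganBox]      # face-normalized frame
    transform: NormTransform               # face-normalized frame -> mm


# ---------------------------------------------------------------------------
# Analytic surface


def _surface_fn(p: FaceParams):
    """Return z(x, y) evaluating the full analytic surface (vectorized)."""
    a, b, c = p.head_a, p.head_b, p.head_c
    geo = _layout(p)

    def z(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        r2 = (x / a) ** 2 + (y / b) ** 2
        base = c * np.sqrt(np.clip(1.0 - r2, 0.0, None))
        out = base
        # nose ridge
        out = out + p.nose_height * np.exp(
            -x ** 2 / (2 * geo["nose_sx"] ** 2)
            - (y - geo["y_nose"]) ** 2 / (2 * geo["nose_sy"] ** 2))
        # eye bulges (mirrored)
        for sgn in (+1, -1):
            out = out + geo["eye_amp"] * np.exp(
                -((x - sgn * p.eye_offset_x) ** 2 + (y - geo["y_eye"]) ** 2)
                / (2 * geo["eye_s"] ** 2))
        # two-lobed mouth
        mouth = np.exp(-x ** 2 / (2 * geo["mouth_sx"] ** 2))
        for dy in (+geo["lip_sep"], -geo["lip_sep"]):
            out = out + geo["lip_amp"] * mouth * np.exp(
                -(y - geo["y_mouth"] - dy) ** 2 / (2 * geo["lip_sy"] ** 2))
        # chin boss
        out = out + geo["chin_amp"] * np.exp(
            -x ** 2 / (2 * geo["chin_sx"] ** 2)
            - (y - geo["y_chin"]) ** 2 / (2 * geo["chin_sy"] ** 2))
        return out

    return z, geo


def _layout(p: FaceParams) -> dict[str, float]:
    """Derived feature geometry from the primary parameters."""
    nose_len = 0.40 * p.head_b
    y_nose = -0.05 * p.head_b
    y_mouth = y_nose - 0.95 * nose_len
    y_chin = y_mouth - 0.28 * p.head_b
    eye_r = 0.4 * p.eye_offset_x
    return {
        "nose_len": nose_len, "y_nose": y_nose,
        "nose_sx": p.nose_width / 4.0, "nose_sy": nose_len / 2.0,
        "y_eye": p.eye_offset_y, "eye_r": eye_r, "eye_s": eye_r,
        "eye_amp": 3.0,
        "y_mouth": y_mouth, "mouth_sx": p.mouth_width / 3.0,
        "lip_sep": 0.16 * p.mouth_width, "lip_sy": 0.16 * p.mouth_width / 1.5,
        "lip_amp": 4.0,
        "y_chin": y_chin, "chin_sx": 14.0, "chin_sy": 12.0, "chin_amp": 6.0,
    }


def _landmark_xy(p: FaceParams, geo: Mapping[str, float]) -> dict[str, tuple[float, float]]:
    """Parametric (x, y) positions of all 32 landmarks (+x = subject's left)."""
    a, b = p.head_a, p.head_b
    nl, yn = geo["nose_len"], geo["y_nose"]
    ym, d = geo["y_mouth"], geo["lip_sep"]
    yc = geo["y_chin"]
    xe, ye, er = p.eye_offset_x, geo["y_eye"], geo["eye_r"]

    def x_rim(y: float) -> float:
        return a * np.sqrt(max(0.0, 1.0 - (y / b) ** 2))

    y_tra = ye - 0.10 * b
    y_zy = ye - 0.09 * a
    y_go = yc + 0.10 * b
    x_go = 0.80 * x_rim(y_go) * (p.jaw_angle / 120.0)
    y_me = yc - 0.12 * b

    lm: dict[str, tuple[float, float]] = {
        "Glabella": (0.0, yn + 1.15 * nl),
        "Nasion": (0.0, yn + 0.80 * nl),
        "Pronasale": (0.0, yn),
        "Subnasale": (0.0, yn - 0.50 * nl),
        "Subspinale": (0.0, yn - 0.70 * nl),
        "Labiale_superius": (0.0, ym + d),
        "Stomion": (0.0, ym),
        "Labiale_inferius": (0.0, ym - d),
        "Sublabiale": (0.0, (ym - d + yc) / 2.0),
        "Pogonion": (0.0, yc),
        "Gnathion": (0.0, yc - 0.06 * b),
        "Menton": (0.0, y_me),
    }
    paired = {
        "Endocanthion": (xe - er, ye),
        "Exocanthion": (xe + er, ye),
        "Palpebrale_superius": (xe, ye + 0.6 * er),
        "Palpebrale_inferius": (xe, ye - 0.6 * er),
        "Alare": (p.nose_width / 2.0, yn - 0.20 * nl),
        "Christa_philtra": (p.mouth_width / 6.0, ym + 1.1 * d),
        "Cheilion": (p.mouth_width / 2.0, ym),
        "Tragus": (0.94 * x_rim(y_tra), y_tra),
        "Zygion": (0.97 * x_rim(y_zy), y_zy),
        "Gonion": (x_go, y_go),
    }
    for base, (x, y) in paired.items():
        lm[f"{base}_left"] = (x, y)     # +x is the subject's left
        lm[f"{base}_right"] = (-x, y)
    return lm


def _asymmetry_warp(points: np.ndarray, p: FaceParams) -> np.ndarray:
    """Smooth lateral warp: x -> x * (1 + asymmetry * x / a); identity at 0."""
    out = points.copy()
    out[:, 0] = points[:, 0] * (1.0 + p.asymmetry * points[:, 0] / p.head_a)
    return out


def _pose_rotation(p: FaceParams) -> np.ndarray:
    return Rotation.from_euler(
        "xyz", [p.pose_x, p.pose_y, p.pose_z], degrees=True).as_matrix()


def _sample_surface(p: FaceParams, zfn, rng: np.random.Generator) -> np.ndarray:
    """Area-weighted uniform samples of the analytic surface (mm)."""
    a, b = p.head_a, p.head_b
    K = p.n_points
    # estimate the area-element bound on a coarse grid
    gx, gy = np.meshgrid(np.linspace(-a, a, 61), np.linspace(-b, b, 61))
    inside = (gx / a) ** 2 + (gy / b) ** 2 <= _RIM
    h = 0.5
    wgrid = np.sqrt(1.0
                    + ((zfn(gx + h, gy) - zfn(gx - h, gy)) / (2 * h)) ** 2
                    + ((zfn(gx, gy + h) - zfn(gx, gy - h)) / (2 * h)) ** 2)
    w_cap = float(wgrid[inside].max()) * 1.25
    out = np.empty((0, 3))
    while out.shape[0] < K:
        m = max(4 * K, 4096)
        x = rng.uniform(-a, a, m)
        y = rng.uniform(-b, b, m)
        keep = (x / a) ** 2 + (y / b) ** 2 <= _RIM
        x, y = x[keep], y[keep]
        w = np.sqrt(1.0
                    + ((zfn(x + h, y) - zfn(x - h, y)) / (2 * h)) ** 2
                    + ((zfn(x, y + h) - zfn(x, y - h)) / (2 * h)) ** 2)
        accept = rng.uniform(0, w_cap, x.shape[0]) < w
        pts = np.column_stack([x[accept], y[accept], zfn(x[accept], y[accept])])
        out = np.vstack([out, pts])
    return out[:K]


def derive_boxes(landmarks_norm: Mapping[str, np.ndarray],
                 inflation: float = 0.25,
                 min_half_extent: float = 0.05) -> dict[Organ, OrganBox]:
    """Organ boxes from normalized-frame landmarks.

    Each organ's box is the bounding box of its landmarks, inflated on every
    axis by ``inflation`` times the bounding-box diagonal, with half-extents
    floored at ``min_half_extent``.
    """
    boxes: dict[Organ, OrganBox] = {}
    for organ in ORGAN_ORDER:
        pts = np.stack([landmarks_norm[n] for n in organ_spec(organ).landmark_names])
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        pad = inflation * float(np.linalg.norm(hi - lo))
        half = np.maximum((hi - lo) / 2.0 + pad, min_half_extent)
        boxes[organ] = OrganBox(center=(hi + lo) / 2.0, half_extents=half)
    return boxes


def generate_face(params: FaceParams) -> SyntheticFace:
    """Generate one face: noisy cloud, exact landmarks, true organ boxes."""
    rng = np.random.default_rng(params.seed)
    zfn, geo = _surface_fn(params)
    pts = _sample_surface(params, zfn, rng)
    lm_xy = _landmark_xy(params, geo)
    lm = {name: np.array([x, y, float(zfn(x, y))]) for name, (x, y) in lm_xy.items()}

    R = _pose_rotation(params)
    pts = _asymmetry_warp(pts, params) @ R.T
    lm = {k: R @ _asymmetry_warp(v[None], params)[0] for k, v in lm.items()}
    noisy = pts + rng.normal(0.0, params.noise_sd, size=pts.shape)

    cloud = PointCloud(noisy)
    ncloud = normalize(cloud)
    lm_norm = {k: ncloud.transform.to_normalized(v) for k, v in lm.items()}
    boxes = derive_boxes(lm_norm)
    return SyntheticFace(params=params, cloud=cloud, landmarks=lm,
                         true_boxes=boxes, transform=ncloud.transform)


# ---------------------------------------------------------------------------
# Dataset generation

#: Mild population variation used when no explicit ranges are given.
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "head_a": (62.0, 78.0),
    "head_b": (82.0, 98.0),
    "head_c": (72.0, 88.0),
    "nose_height": (12.0, 20.0),
    "nose_width": (26.0, 38.0),
    "eye_offset_x": (26.0, 34.0),
    "eye_offset_y": (22.0, 32.0),
    "mouth_width": (44.0, 56.0),
    "jaw_angle": (110.0, 130.0),
    "asymmetry": (0.0, 0.06),
    "pose_x": (-5.0, 5.0),
    "pose_y": (-5.0, 5.0),
    "pose_z": (-5.0, 5.0),
}


def generate_dataset(n_faces: int = 500,
                     params_ranges: Mapping[str, tuple[float, float]] | None = None,
                     split: tuple[float, float, float] = (0.7, 0.2, 0.1),
                     seed: int = 0,
                     base_params: FaceParams = FaceParams()
                     ) -> dict[str, list[SyntheticFace]]:
    """Draw a population of faces and split it train : test : val.

    Per-face parameters are drawn uniformly from ``params_ranges`` (defaults
    to DEFAULT_PARAM_RANGES); split sizes are floor-based for test and val
    with the remainder going to train.  Fully deterministic under ``seed``.
    """
    if n_faces < 10:
        raise SyntheticError(f"need n_faces >= 10, got {n_faces}")
    if abs(sum(split) - 1.0) > 1e-9:
        raise SyntheticError(f"split fractions must sum to 1, got {split}")
    ranges = dict(params_ranges if params_ranges is not None else DEFAULT_PARAM_RANGES)
    valid_fields = {f.name for f in fields(FaceParams)}
    for key, (lo, hi) in ranges.items():
        if key not in valid_fields:
            raise SyntheticError(f"unknown parameter {key!r}")
        if hi < lo:
            raise SyntheticError(f"empty range for {key!r}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    faces: list[SyntheticFace] = []
    for i in range(n_faces):
        draw = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
        face_seed = int(rng.integers(0, 2 ** 31 - 1))
        faces.append(generate_face(replace(base_params, seed=face_seed, **draw)))
    n_test = int(np.floor(split[1] * n_faces))
    n_val = int(np.floor(split[2] * n_faces))
    n_train = n_faces - n_test - n_val
    order = rng.permutation(n_faces)
    return {
        "train": [faces[i] for i in order[:n_train]],
        "test": [faces[i] for i in order[n_train:n_train + n_test]],
        "val": [faces[i] for i in order[n_train + n_test:]],
    }
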