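"""Point-cloud geometry: I/O, normalization, voxelization, organ cropping.

Coordinate frames
-----------------
mm frame
    The raw scanner frame, coordinates in millimetres.
face frame
    The mm cloud mapped into [-1, 1]^3 by an isotropic similarity
    (single scaling multiplier S, mm per normalized unit, plus a
    translation).  S is recorded because the evaluation metric multiplies
    normalized-frame distances by S to restore millimetres.
organ frame
    A cropped organ region re-normalized to [-1, 1]^3 by its own isotropic
    transform, taken from the (margin-inflated) organ box so that the frame
    depends only on the box, not on which points fell inside it.

Voxelization maps a normalized coordinate c to the cell index
``clamp(floor((c + 1) / 2 * M), 0, M - 1)``; each cell has width 2/M in
normalized units, i.e. 2S/M mm, which bounds the per-axis quantization error.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree


class GeometryError(ValueError):
    pass


class EmptyCropError(GeometryError):
    """No point of the cloud falls inside the requested organ box."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class PointCloud:
    """K x 3 facial surface samples in mm; K >= 4, all coordinates finite."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise GeometryError(f"expected K x 3 points, got shape {pts.shape}")
        if pts.shape[0] < 4:
            raise GeometryError(f"need at least 4 points, got {pts.shape[0]}")
        if not np.isfinite(pts).all():
            bad = np.argwhere(~np.isfinite(pts))[0]
            raise GeometryError(f"non-finite coordinate at row {bad[0]}, axis {bad[1]}")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class NormTransform:
    """Isotropic similarity between a normalized frame and the mm frame.

    ``to_mm(p) = p * scale + translation``; scale is mm per normalized unit.
    """

    scale: float
    translation: np.ndarray

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise GeometryError(f"scale must be positive, got {self.scale}")
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float).reshape(3))

    def to_mm(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) * self.scale + self.translation

    def to_normalized(self, points_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(points_mm, dtype=float) - self.translation) / self.scale

    def compose(self, inner: "NormTransform") -> "NormTransform":
        """Transform mapping inner's normalized frame directly to mm.

        ``self.to_mm(inner.to_mm(p)) == self.compose(inner).to_mm(p)`` —
        used to chain the organ-frame transform through the face frame.
        """
        return NormTransform(scale=self.scale * inner.scale,
                             translation=self.to_mm(inner.translation))


@dataclass
class NormalizedCloud:
    """Cloud in [-1, 1]^3 plus the transform back to mm."""

    points: np.ndarray
    transform: NormTransform


@dataclass
class VoxelGrid:
    """M^3 binary occupancy tensor."""

    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3 or len(set(occ.shape)) != 1:
            raise GeometryError(f"occupancy must be cubic, got shape {occ.shape}")
        self.occupancy = occ.astype(np.uint8)

    @property
    def M(self) -> int:
        return self.occupancy.shape[0]


@dataclass(frozen=True)
class OrganBox:
    """Axis-aligned box: center plus per-axis half-extents, normalized units."""

    center: np.ndarray
    half_extents: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        object.__setattr__(self, "half_extents",
                           np.asarray(self.half_extents, dtype=float).reshape(3))
        if not (self.half_extents > 0).all():
            raise GeometryError(f"half extents must be positive, got {self.half_extents}")

    def as_vector(self) -> np.ndarray:
        """[x, y, z, xl, yl, zl] encoding."""
        return np.concatenate([self.center, self.half_extents])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "OrganBox":
        v = np.asarray(v, dtype=float).reshape(6)
        return cls(center=v[:3], half_extents=v[3:])

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.abs(np.atleast_2d(points) - self.center)
        return (d <= self.half_extents).all(axis=1)


# ---------------------------------------------------------------------------
# I/O

_FORMATS = ("ply", "obj", "xyz-csv")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("ply", "obj"):
        return suffix
    if suffix in ("csv", "xyz", "txt"):
        return "xyz-csv"
    raise GeometryError(f"cannot infer format of {path}; pass format explicitly")


def load_cloud(path: str | Path, format: str | None = None) -> PointCloud:
    """Load a point cloud from PLY/OBJ (vertices only) or a 3-column CSV."""
    path = Path(path)
    if not path.is_file():
        raise GeometryError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise GeometryError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    try:
        if fmt in ("ply", "obj"):
            mesh = trimesh.load(path, file_type=fmt, process=False,
                                maintain_order=True)
            verts = np.asarray(mesh.vertices, dtype=float)
        else:
            verts = _read_xyz_csv(path)
    except GeometryError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap parser failures with context
        raise GeometryError(f"failed to read {path}: {exc}") from exc
    try:
        return PointCloud(verts)
    except GeometryError as exc:
        raise GeometryError(f"{path}: {exc}") from None


def _read_xyz_csv(path: Path) -> np.ndarray:
    text = path.read_text()
    first = text.splitlines()[0] if text.strip() else ""
    has_header = any(c.isalpha() for c in first)
    df = pd.read_csv(io.StringIO(text), header=0 if has_header else None)
    if df.shape[1] < 3:
        raise GeometryError(f"{path}: expected 3 columns, got {df.shape[1]}")
    return df.iloc[:, :3].to_numpy(dtype=float)


def save_cloud(path: str | Path, cloud: PointCloud, format: str | None = None,
               encoding: str = "binary") -> None:
    """Write a cloud as PLY (ascii or binary little-endian), OBJ, or CSV."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "ply":
        pc = trimesh.PointCloud(cloud.points)
        data = pc.export(file_type="ply", encoding=encoding)
        path.write_bytes(data if isinstance(data, bytes) else data.encode())
    elif fmt == "obj":
        lines = [f"v {x:.9g} {y:.9g} {z:.9g}" for x, y, z in cloud.points]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "xyz-csv":
        df = pd.DataFrame(cloud.points, columns=["x", "y", "z"])
        df.to_csv(path, index=False)
    else:
        raise GeometryError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def load_landmarks(path: str | Path) -> dict[str, np.ndarray]:
    """Landmark file: JSON {name: [x,y,z]} or CSV (name,x,y,z), mm."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        return {k: np.asarray(v, dtype=float).reshape(3) for k, v in raw.items()}
    df = pd.read_csv(path)
    return {str(r.iloc[0]): r.iloc[1:4].to_numpy(dtype=float)
            for _, r in df.iterrows()}


def save_landmarks(path: str | Path, landmarks: dict[str, np.ndarray]) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(
            {k: [float(c) for c in np.asarray(v).reshape(3)] for k, v in landmarks.items()},
            indent=1))
    else:
        rows = [{"name": k, "x": v[0], "y": v[1], "z": v[2]}
                for k, v in landmarks.items()]
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing


def outlier_filter(cloud: PointCloud, k_neighbors: int = 8,
                   sigma_mult: float = 2.0) -> PointCloud:
    """Drop statistical outliers (e.g. stray occlusion points).

    A point is an outlier when its mean distance to its ``k_neighbors``
    nearest neighbors exceeds mean + ``sigma_mult`` * sd of that statistic
    over the cloud.  At most 20% of points are ever removed (guard against
    degenerate clouds); ``sigma_mult=inf`` is the identity.
    """
    if k_neighbors < 1:
        raise GeometryError(f"k_neighbors must be >= 1, got {k_neighbors}")
    pts = cloud.points
    n = len(pts)
    if not np.isfinite(sigma_mult) or n <= k_neighbors + 1:
        return PointCloud(pts.copy())
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=k_neighbors + 1)
    mean_d = dists[:, 1:].mean(axis=1)  # skip self-match
    thresh = mean_d.mean() + sigma_mult * mean_d.std()
    keep = mean_d <= thresh
    max_removed = int(0.2 * n)
    if (~keep).sum() > max_removed:
        order = np.argsort(mean_d)[::-1]
        keep = np.ones(n, dtype=bool)
        keep[order[:max_removed]] = False
    return PointCloud(pts[keep])


def normalize(cloud: PointCloud) -> NormalizedCloud:
    """Map a mm cloud into [-1, 1]^3, recording the scaling multiplier S.

    The transform is isotropic: t is the bounding-box midpoint and
    S is half the largest bounding-box edge, so the longest axis spans
    exactly [-1, 1] and mm distances are S times normalized distances
    along every axis.
    """
    pts = cloud.points
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    scale = float((hi - lo).max()) / 2.0
    if scale <= 0:
        raise GeometryError("cannot normalize a cloud of identical points")
    t = (hi + lo) / 2.0
    transform = NormTransform(scale=scale, translation=t)
    return NormalizedCloud(points=transform.to_normalized(pts), transform=transform)


# ---------------------------------------------------------------------------
# Voxelization


def voxel_indices(points: np.ndarray, M: int) -> np.ndarray:
    """Cell index per axis: clamp(floor((c+1)/2 * M), 0, M-1)."""
    idx = np.floor((np.asarray(points, dtype=float) + 1.0) / 2.0 * M).astype(np.int64)
    return np.clip(idx, 0, M - 1)


def voxelize(ncloud: NormalizedCloud | np.ndarray, M: int) -> VoxelGrid:
    """Binary occupancy grid of a normalized cloud on an M^3 uniform grid."""
    if M < 2:
        raise GeometryError(f"M must be >= 2, got {M}")
    pts = ncloud.points if isinstance(ncloud, NormalizedCloud) else np.asarray(ncloud)
    occ = np.zeros((M, M, M), dtype=np.uint8)
    idx = voxel_indices(pts, M)
    occ[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    return VoxelGrid(occ)


def voxel_center(i: int, j: int, k: int, M: int) -> np.ndarray:
    """Normalized-frame center of cell (i, j, k): ((idx+0.5) * 2/M - 1)."""
    idx = np.array([i, j, k], dtype=float)
    if ((idx < 0) | (idx >= M)).any():
        raise GeometryError(f"cell ({i},{j},{k}) out of range for M={M}")
    return (idx + 0.5) * 2.0 / M - 1.0


def occupied_centers(grid: VoxelGrid) -> np.ndarray:
    """Normalized-frame centers of all occupied cells."""
    idx = np.argwhere(grid.occupancy > 0).astype(float)
    return (idx + 0.5) * 2.0 / grid.M - 1.0


# ---------------------------------------------------------------------------
# Organ cropping


def crop_organ(ncloud: NormalizedCloud, box: OrganBox, margin: float = 1.1,
               M_organ: int = 32) -> tuple[VoxelGrid, NormTransform]:
    """Extract the points inside a (margin-inflated) organ box and re-voxelize.

    Points p with ``|p - center| <= margin * half_extents`` on every axis are
    selected and mapped into the organ frame by an isotropic transform taken
    from the inflated box itself (origin at the box center, scale = largest
    inflated half-extent).  The returned transform is composed with the
    face-level transform, so it maps organ-frame coordinates directly to mm.
    """
    if margin < 1.0:
        raise GeometryError(f"margin must be >= 1.0, got {margin}")
    if M_organ < 2:
        raise GeometryError(f"M_organ must be >= 2, got {M_organ}")
    half = margin * box.half_extents
    mask = (np.abs(ncloud.points - box.center) <= half).all(axis=1)
    if not mask.any():
        raise EmptyCropError("empty organ crop")
    local = NormTransform(scale=float(half.max()), translation=box.center)
    organ_pts = local.to_normalized(ncloud.points[mask])
    grid = voxelize(organ_pts, M_organ)
    return grid, ncloud.transform.compose(local)
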