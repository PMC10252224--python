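"""Geometry: I/O round-trips, normalization, voxelization, organ cropping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from facemark3d import geometry as geo


def cube_corners(scale=10.0):
    corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                       dtype=float)
    return geo.PointCloud(corners * scale)


# ---------------------------------------------------------------------------
# I/O


def test_cloud_rejects_too_few_points(tmp_path):
    path = tmp_path / "tiny.csv"
    path.write_text("x,y,z\n0,0,0\n1,0,0\n0,1,0\n")
    with pytest.raises(geo.GeometryError, match="4"):
        geo.load_cloud(path)


def test_cloud_rejects_nonfinite():
    pts = np.zeros((5, 3))
    pts[2, 1] = np.nan
    with pytest.raises(geo.GeometryError, match="non-finite"):
        geo.PointCloud(pts)


@pytest.mark.parametrize("fmt,encoding", [
    ("ply", "ascii"), ("ply", "binary"), ("obj", None), ("xyz-csv", None)])
def test_save_load_round_trip(tmp_path, fmt, encoding, rng):
    pts = rng.normal(scale=40.0, size=(50, 3))
    cloud = geo.PointCloud(pts)
    suffix = {"ply": "ply", "obj": "obj", "xyz-csv": "csv"}[fmt]
    path = tmp_path / f"cloud.{suffix}"
    kwargs = {"encoding": encoding} if encoding else {}
    geo.save_cloud(path, cloud, format=fmt, **kwargs)
    loaded = geo.load_cloud(path, format=fmt)
    np.testing.assert_allclose(loaded.points, pts, rtol=1e-6, atol=1e-5)


def test_obj_with_faces_matches_vertex_only_parse(tmp_path):
    text = ("v 0 0 0\nv 10 0 0\nv 0 10 0\nv 0 0 10\nv 5 5 5\n"
            "f 1 2 3\nf 2 3 4\n")
    path = tmp_path / "mesh.obj"
    path.write_text(text)
    loaded = geo.load_cloud(path)
    # independent parse of the "v" records
    expected = np.array([list(map(float, line.split()[1:]))
                         for line in text.splitlines() if line.startswith("v ")])
    np.testing.assert_allclose(np.sort(loaded.points, axis=0),
                               np.sort(expected, axis=0))


def test_landmark_file_round_trip(tmp_path, rng):
    lm = {f"pt{i}": rng.normal(size=3) for i in range(5)}
    for suffix in ("json", "csv"):
        path = tmp_path / f"lm.{suffix}"
        geo.save_landmarks(path, lm)
        loaded = geo.load_landmarks(path)
        assert set(loaded) == set(lm)
        for k in lm:
            np.testing.assert_allclose(loaded[k], lm[k], atol=1e-12)


# ---------------------------------------------------------------------------
# Outlier filter


def test_outlier_filter_removes_far_point(rng):
    u = rng.normal(size=(400, 3))
    sphere = u / np.linalg.norm(u, axis=1, keepdims=True) * 50.0
    outlier = np.array([[500.0, 0.0, 0.0]])
    cloud = geo.PointCloud(np.vstack([sphere, outlier]))
    filtered = geo.outlier_filter(cloud, k_neighbors=5, sigma_mult=2.0)
    # brute-force kNN check that the far point is the anomaly
    assert len(filtered) < len(cloud)
    assert not (np.abs(filtered.points[:, 0] - 500.0) < 1e-9).any()


def test_outlier_filter_infinite_sigma_is_identity(small_face):
    out = geo.outlier_filter(small_face.cloud, sigma_mult=np.inf)
    np.testing.assert_array_equal(out.points, small_face.cloud.points)


def test_outlier_filter_output_is_subset(small_face):
    out = geo.outlier_filter(small_face.cloud, k_neighbors=4, sigma_mult=1.0)
    rows = {tuple(p) for p in np.round(small_face.cloud.points, 9)}
    assert all(tuple(p) in rows for p in np.round(out.points, 9))
    # guard: never removes more than 20%
    assert len(out) >= 0.8 * len(small_face.cloud)


# ---------------------------------------------------------------------------
# Normalization


def test_normalize_two_point_example():
    cloud = geo.PointCloud(np.array([[0, 0, 0], [10, 0, 0],
                                     [0, 0, 0], [10, 0, 0]], dtype=float))
    ncloud = geo.normalize(cloud)
    assert ncloud.transform.scale == pytest.approx(5.0)
    np.testing.assert_allclose(ncloud.transform.translation, [5, 0, 0])
    assert set(map(tuple, ncloud.points)) == {(-1, 0, 0), (1, 0, 0)}


def test_normalize_round_trip(small_face):
    ncloud = geo.normalize(small_face.cloud)
    back = ncloud.transform.to_mm(ncloud.points)
    np.testing.assert_allclose(back, small_face.cloud.points, rtol=1e-9)
    assert np.abs(ncloud.points).max() <= 1.0 + 1e-12
    # tight scaling: some coordinate attains magnitude 1
    assert np.isclose(np.abs(ncloud.points).max(), 1.0)


def test_normalize_scale_shift_equivariance(small_face):
    base = geo.normalize(small_face.cloud)
    moved = geo.PointCloud(small_face.cloud.points * 3.0 + np.array([7.0, 7.0, 7.0]))
    other = geo.normalize(moved)
    np.testing.assert_allclose(other.points, base.points, atol=1e-9)
    assert other.transform.scale == pytest.approx(3.0 * base.transform.scale)


def test_normalize_rejects_degenerate():
    with pytest.raises(geo.GeometryError):
        geo.normalize(geo.PointCloud(np.ones((5, 3))))


# ---------------------------------------------------------------------------
# Voxelization


def test_voxelize_corner_cells():
    grid = geo.voxelize(np.array([[-1.0, -1.0, -1.0]]), M=2)
    assert grid.occupancy[0, 0, 0] == 1
    assert grid.occupancy.sum() == 1
    # +1 boundary clamps into the last cell
    grid = geo.voxelize(np.array([[1.0, 1.0, 1.0]]), M=2)
    assert grid.occupancy[1, 1, 1] == 1


def test_voxel_center_examples_and_round_trip():
    np.testing.assert_allclose(geo.voxel_center(0, 0, 0, 2), [-0.5, -0.5, -0.5])
    for M in (4,):
        for i in range(M):
            for j in range(M):
                for k in range(M):
                    c = geo.voxel_center(i, j, k, M)
                    idx = geo.voxel_indices(c[None], M)[0]
                    assert tuple(idx) == (i, j, k)
    # symmetry under index reflection
    np.testing.assert_allclose(geo.voxel_center(0, 1, 2, 4),
                               -geo.voxel_center(3, 2, 1, 4))
    with pytest.raises(geo.GeometryError):
        geo.voxel_center(4, 0, 0, 4)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    pts=arrays(np.float64, (30, 3), elements=st.floats(-1, 1, width=64)),
    M=st.sampled_from([2, 8, 32, 200]),
)
def test_voxel_quantization_accuracy_bound(pts, M):
    """Per-axis displacement between a point and its voxel center <= 2S/M.

    With S = 1 normalized unit the grid precision is the cell width 2/M;
    the mm bound follows by scaling.
    """
    idx = geo.voxel_indices(pts, M)
    centers = (idx + 0.5) * 2.0 / M - 1.0
    assert (np.abs(centers - pts) <= 2.0 / M + 1e-12).all()


def test_occupied_count_invariant_under_point_order(small_face, rng):
    ncloud = geo.normalize(small_face.cloud)
    grid1 = geo.voxelize(ncloud, 32)
    perm = rng.permutation(len(ncloud.points))
    grid2 = geo.voxelize(ncloud.points[perm], 32)
    np.testing.assert_array_equal(grid1.occupancy, grid2.occupancy)
    assert grid1.occupancy.sum() <= len(small_face.cloud)


# ---------------------------------------------------------------------------
# Organ cropping


def test_crop_whole_domain_is_identity(small_face):
    ncloud = geo.normalize(small_face.cloud)
    box = geo.OrganBox(center=np.zeros(3), half_extents=np.ones(3))
    grid, transform = geo.crop_organ(ncloud, box, margin=1.0, M_organ=16)
    np.testing.assert_array_equal(grid.occupancy, geo.voxelize(ncloud, 16).occupancy)
    # organ frame == face frame here, so composed transform == face transform
    assert transform.scale == pytest.approx(ncloud.transform.scale)


def test_crop_selects_exact_membership():
    cloud = cube_corners(scale=10.0)  # corners of [0,10]^3
    ncloud = geo.normalize(cloud)
    # box over the low-x half: normalized x in [-1, 0]
    box = geo.OrganBox(center=[-0.5, 0.0, 0.0], half_extents=[0.5, 1.0, 1.0])
    # brute-force membership oracle
    inside = [p for p in ncloud.points
              if (np.abs(p - box.center) <= box.half_extents).all()]
    assert len(inside) == 4
    grid, _ = geo.crop_organ(ncloud, box, margin=1.0, M_organ=4)
    assert grid.occupancy.sum() == 4


def test_crop_transform_maps_origin_to_box_center_mm(small_face):
    ncloud = geo.normalize(small_face.cloud)
    box = list(small_face.true_boxes.values())[0]
    _, transform = geo.crop_organ(ncloud, box, margin=1.1, M_organ=8)
    origin_mm = transform.to_mm(np.zeros(3))
    expected = ncloud.transform.to_mm(box.center)
    np.testing.assert_allclose(origin_mm, expected, atol=1e-9)


def test_crop_margin_monotonicity(small_face):
    ncloud = geo.normalize(small_face.cloud)
    for box in small_face.true_boxes.values():
        half1 = 1.0 * box.half_extents
        half2 = 1.2 * box.half_extents
        m1 = (np.abs(ncloud.points - box.center) <= half1).all(axis=1)
        m2 = (np.abs(ncloud.points - box.center) <= half2).all(axis=1)
        assert (m2 | ~m1).all()  # margin 1.2 selects a superset


def test_crop_empty_box_rejected(small_face):
    ncloud = geo.normalize(small_face.cloud)
    box = geo.OrganBox(center=[0.0, 0.0, -0.999], half_extents=[1e-4] * 3)
    with pytest.raises(geo.EmptyCropError):
        geo.crop_organ(ncloud, box, margin=1.0, M_organ=4)
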