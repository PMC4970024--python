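"""Isolated-point filtering, frame detection, cropping, quadrat split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from weedvol.mesh_core import PointCloud, TriMesh, triangle_areas, triangle_centroids
from weedvol.preprocess import (
    EmptyCropError,
    FrameDetectionError,
    crop_to_frame,
    detect_frame,
    filter_isolated_points,
    filter_isolated_vertices,
    split_quadrats,
)
from weedvol.synthetic_field import generate_scene, noiseless


# ---------------------------------------------------------------------------
# isolated-point filtering


def test_grid_survives_and_outlier_is_dropped():
    xs = np.arange(10) * 0.005
    gx, gy = np.meshgrid(xs, xs)
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(100)])
    cloud = PointCloud(np.vstack([pts, [[0.5, 0.5, 0.05]]]))
    out = filter_isolated_points(cloud, radius=0.01)
    assert len(out) == 100
    assert not np.any(np.all(out.points == [0.5, 0.5, 0.05], axis=1))


def test_empty_cloud_passes_through():
    out = filter_isolated_points(PointCloud(np.zeros((0, 3))))
    assert len(out) == 0


def test_filter_matches_brute_force_neighbor_count():
    rng = np.random.default_rng(0)
    pts = rng.uniform(size=(1000, 3)) * 0.2
    radius, k = 0.015, 2
    out = filter_isolated_points(PointCloud(pts), radius=radius, min_neighbors=k)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    counts = (d <= radius).sum(axis=1) - 1
    expected = pts[counts >= k]
    assert np.array_equal(out.points, expected)


def test_filter_is_order_independent():
    rng = np.random.default_rng(1)
    pts = rng.uniform(size=(400, 3)) * 0.1
    perm = rng.permutation(len(pts))
    a = filter_isolated_points(PointCloud(pts), 0.012).points
    b = filter_isolated_points(PointCloud(pts[perm]), 0.012).points
    assert {tuple(p) for p in a} == {tuple(p) for p in b}


def test_filter_second_pass_is_noop_on_scan_density():
    xs = np.arange(30) * 0.005
    gx, gy = np.meshgrid(xs, xs)
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    once = filter_isolated_points(PointCloud(pts), 0.01)
    twice = filter_isolated_points(once, 0.01)
    assert np.array_equal(once.points, twice.points)


@given(
    pts=hnp.arrays(
        np.float64,
        st.tuples(st.integers(3, 60), st.just(3)),
        elements=st.floats(0, 0.125, allow_nan=False, width=32),
    )
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_filter_retains_a_subset_with_enough_neighbors(pts):
    """Property: output is a subset of the input and every retained point
    really has the required number of neighbors within the radius."""
    radius, k = 0.02, 1
    out = filter_isolated_points(PointCloud(pts), radius=radius, min_neighbors=k)
    in_set = {tuple(p) for p in pts}
    assert all(tuple(p) in in_set for p in out.points)
    for p in out.points:
        d = np.linalg.norm(pts - p, axis=1)
        assert np.count_nonzero(d <= radius) - 1 >= k


def test_mesh_filter_drops_faces_touching_removed_vertices():
    verts = np.array(
        [[0, 0, 0], [0.005, 0, 0], [0, 0.005, 0], [0.5, 0.5, 0.5]], dtype=float
    )
    mesh = TriMesh(verts, np.array([[0, 1, 2], [0, 1, 3]]))
    out = filter_isolated_vertices(mesh, radius=0.01)
    assert out.n_faces == 1 and out.n_vertices == 3


# ---------------------------------------------------------------------------
# frame detection


def test_frame_recovered_within_a_centimeter(pristine_scene):
    mesh, frame_true, _ = pristine_scene
    fr = detect_frame(mesh)
    err = np.linalg.norm(fr.corners - frame_true.corners, axis=1)
    assert np.all(err < 0.01)
    assert abs(fr.side_length - 1.0) < 0.01
    assert fr.rms_residual <= 0.01
    assert abs(fr.ground_plane.normal[2] - 1.0) < 1e-3


def test_rotated_frame_orientation_recovered_within_one_degree():
    mesh, frame_true, _ = generate_scene(noiseless(seed=9, frame_rotation_deg=30.0))
    fr = detect_frame(mesh)
    def edge_angle(c):
        e = c[1] - c[0]
        return np.degrees(np.arctan2(e[1], e[0])) % 90.0
    da = abs(edge_angle(fr.corners) - edge_angle(frame_true.corners))
    assert min(da, 90 - da) < 1.0
    err = np.linalg.norm(fr.corners - frame_true.corners, axis=1)
    assert np.all(err < 0.01)


def test_no_white_vertices_raises_no_frame_found():
    rng = np.random.default_rng(2)
    verts = rng.uniform(size=(300, 3))
    faces = np.arange(300).reshape(-1, 3)
    colors = np.full((300, 3), [120, 90, 60], dtype=np.uint8)
    with pytest.raises(FrameDetectionError, match="no frame found"):
        detect_frame(TriMesh(verts, faces, colors))


# ---------------------------------------------------------------------------
# cropping


def test_face_outside_frame_is_cropped(pristine_scene):
    mesh, _, _ = pristine_scene
    fr = detect_frame(mesh)
    extra_v = np.array([[1.1, 0.5, 0.0], [1.12, 0.5, 0.0], [1.1, 0.52, 0.0]])
    aug = TriMesh(
        np.vstack([mesh.vertices, extra_v]),
        np.vstack([mesh.faces, [[mesh.n_vertices, mesh.n_vertices + 1, mesh.n_vertices + 2]]]),
        np.vstack([mesh.vertex_colors, np.full((3, 3), 100, dtype=np.uint8)]),
    )
    out = crop_to_frame(aug, fr)
    assert aug.n_faces - 1 not in out.face_ids  # the appended face is gone


def test_crop_keeps_exactly_centroid_inside_nonwhite_faces(pristine_scene):
    """Retained face set equals a point-in-polygon oracle on centroids."""
    from shapely import contains_xy
    from shapely.geometry import Polygon

    mesh, _, _ = pristine_scene
    fr = detect_frame(mesh)
    out, idx = crop_to_frame(mesh, fr, return_indices=True)
    cent = triangle_centroids(mesh)
    poly = Polygon(fr.corners[:, :2])
    inside = contains_xy(poly.buffer(1e-9), cent[:, 0], cent[:, 1])
    c = mesh.vertex_colors.astype(int)
    white = (c.min(axis=1) >= 200) & (np.ptp(c, axis=1) <= 30)
    expected = np.flatnonzero(inside & ~white[mesh.faces].any(axis=1))
    assert np.array_equal(np.sort(idx), expected)


def test_crop_to_empty_raises(pristine_scene):
    mesh, _, _ = pristine_scene
    fr = detect_frame(mesh)
    # a mesh entirely outside the frame polygon
    far = TriMesh(
        np.array([[5, 5, 0], [6, 5, 0], [5, 6, 0]], float),
        np.array([[0, 1, 2]]),
        np.full((3, 3), 90, dtype=np.uint8),
    )
    with pytest.raises(EmptyCropError):
        crop_to_frame(far, fr)


# ---------------------------------------------------------------------------
# quadrat split


def test_split_conserves_faces_and_area(pristine_scene):
    mesh, _, _ = pristine_scene
    fr = detect_frame(mesh)
    cropped = crop_to_frame(mesh, fr)
    samples = split_quadrats(cropped, fr)
    assert sum(s.mesh.n_faces for s in samples) == cropped.n_faces
    total = sum(triangle_areas(s.mesh).sum() for s in samples)
    assert np.isclose(total, triangle_areas(cropped).sum(), rtol=1e-12)
    all_ids = np.concatenate([s.mesh.face_ids for s in samples])
    assert len(np.unique(all_ids)) == len(all_ids)  # disjoint
    for s in samples:
        s.validate()


def test_split_assignment_matches_coordinate_oracle(pristine_scene):
    mesh, _, _ = pristine_scene
    fr = detect_frame(mesh)
    cropped = crop_to_frame(mesh, fr)
    samples = split_quadrats(cropped, fr)
    uv = fr.to_frame_coords(triangle_centroids(cropped))
    mu, mv = fr.side_lengths()[0] / 2, fr.side_lengths()[3] / 2
    oracle = (uv[:, 0] >= mu).astype(int) + 2 * (uv[:, 1] >= mv).astype(int)
    for s in samples:
        assert np.all(oracle[s.face_indices] == s.quadrat_index)


def test_midline_centroid_goes_to_exactly_one_quadrat():
    from weedvol.preprocess import FramePose
    from weedvol.mesh_core import Plane

    fr = FramePose(
        np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float),
        Plane(np.array([0.0, 0.0, 1.0]), 0.0),
        1.0,
    )
    # triangle whose centroid is exactly the frame center
    mesh = TriMesh(
        np.array([[0.5, 0.4, 0], [0.6, 0.55, 0], [0.4, 0.55, 0]], float),
        np.array([[0, 1, 2]]),
    )
    samples = split_quadrats(mesh, fr)
    counts = [s.mesh.n_faces for s in samples]
    assert sum(counts) == 1
    assert counts[3] == 1  # [mid, max] half-open rule sends it to the upper quadrat
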