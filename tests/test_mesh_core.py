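"""Mesh container, PLY/OBJ round trips, components, and cleaning."""

import hashlib

import numpy as np
import pytest

from weedvol.mesh_core import (
    MeshFormatError,
    MeshIOError,
    TriMesh,
    clean_mesh,
    connected_components,
    read_mesh,
    triangle_areas,
    write_mesh,
)

from conftest import make_cube


def _random_colored_mesh(rng, n_tris=8):
    verts = rng.uniform(-1, 1, size=(3 * n_tris, 3))
    faces = np.arange(3 * n_tris).reshape(-1, 3)
    colors = rng.integers(0, 256, size=(3 * n_tris, 3), dtype=np.uint8)
    return TriMesh(verts, faces, colors)


# ---------------------------------------------------------------------------
# I/O


@pytest.mark.parametrize("binary", [False, True], ids=["ascii", "binary_le"])
def test_ply_round_trip_preserves_geometry_and_colors(tmp_path, binary):
    rng = np.random.default_rng(0)
    mesh = _random_colored_mesh(rng)
    path = tmp_path / "m.ply"
    write_mesh(mesh, path, binary=binary)
    back = read_mesh(path)
    assert np.allclose(back.vertices, mesh.vertices, atol=1e-6)
    assert np.array_equal(back.faces, mesh.faces)
    assert np.array_equal(back.vertex_colors, mesh.vertex_colors)


def test_ascii_and_binary_dialects_read_identically(tmp_path):
    """Both dialects of the same mesh parse to the same TriMesh, and they
    agree with a file produced by an independent hand-rolled ASCII writer."""
    rng = np.random.default_rng(1)
    mesh = _random_colored_mesh(rng, n_tris=4)
    pa, pb, pi = tmp_path / "a.ply", tmp_path / "b.ply", tmp_path / "ind.ply"
    write_mesh(mesh, pa, binary=False)
    write_mesh(mesh, pb, binary=True)

    # independent minimal ASCII PLY writer
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property float x", "property float y", "property float z",
        "property uchar red", "property uchar green", "property uchar blue",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices", "end_header",
    ]
    for v, c in zip(mesh.vertices, mesh.vertex_colors):
        lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g} {c[0]} {c[1]} {c[2]}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    pi.write_text("\n".join(lines) + "\n")

    a, b, ind = read_mesh(pa), read_mesh(pb), read_mesh(pi)
    for other in (b, ind):
        assert np.allclose(a.vertices, other.vertices, atol=1e-6)
        assert np.array_equal(a.faces, other.faces)
        assert np.array_equal(a.vertex_colors, other.vertex_colors)


def test_mesh_without_colors_writes_colorless_ply(tmp_path):
    mesh = make_cube()
    path = tmp_path / "c.ply"
    write_mesh(mesh, path)
    header = path.read_bytes().split(b"end_header")[0]
    assert b"red" not in header
    assert read_mesh(path).vertex_colors is None


def test_out_of_range_face_index_is_a_format_error(tmp_path):
    bad = (
        "ply\nformat ascii 1.0\nelement vertex 4\n"
        "property float x\nproperty float y\nproperty float z\n"
        "element face 1\nproperty list uchar int vertex_indices\nend_header\n"
        "0 0 0\n1 0 0\n0 1 0\n0 0 1\n3 0 1 99\n"
    )
    p = tmp_path / "bad.ply"
    p.write_text(bad)
    with pytest.raises(MeshFormatError, match="99"):
        read_mesh(p)


def test_missing_file_is_an_io_error(tmp_path):
    with pytest.raises(MeshIOError):
        read_mesh(tmp_path / "nope.ply")


def test_obj_round_trip_geometry_only(tmp_path):
    mesh = make_cube()
    p = tmp_path / "c.obj"
    write_mesh(mesh, p)
    back = read_mesh(p)
    assert np.allclose(back.vertices, mesh.vertices, atol=1e-6)
    assert np.array_equal(back.faces, mesh.faces)


def test_writes_are_byte_stable(tmp_path):
    rng = np.random.default_rng(2)
    for k in range(5):
        mesh = _random_colored_mesh(rng)
        hashes = set()
        for rep in range(2):
            p = tmp_path / f"m{k}_{rep}.ply"
            write_mesh(mesh, p, binary=True)
            hashes.add(hashlib.sha256(p.read_bytes()).hexdigest())
        assert len(hashes) == 1


# ---------------------------------------------------------------------------
# connected components


def _union_find_components(mesh):
    """Brute-force oracle: union faces sharing an undirected edge."""
    parent = list(range(mesh.n_faces))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges = {}
    for fi, f in enumerate(mesh.faces):
        for e in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(e), max(e))
            if key in edges:
                ra, rb = find(edges[key]), find(fi)
                parent[ra] = rb
            else:
                edges[key] = fi
    return np.array([find(i) for i in range(mesh.n_faces)])


def test_disjoint_triangles_are_separate_components():
    mesh = TriMesh(
        np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 5, 5], [6, 5, 5], [5, 6, 5]], float),
        np.array([[0, 1, 2], [3, 4, 5]]),
    )
    lab = connected_components(mesh)
    assert lab.n_components == 2
    assert lab.face_labels[0] != lab.face_labels[1]


def test_cube_is_one_component():
    assert connected_components(make_cube()).n_components == 1


def test_vertex_contact_does_not_connect_faces():
    """Two triangles sharing only a single vertex remain separate."""
    mesh = TriMesh(
        np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]], float),
        np.array([[0, 1, 2], [0, 3, 4]]),
    )
    assert connected_components(mesh).n_components == 2


def test_empty_mesh_yields_empty_labeling():
    mesh = TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
    lab = connected_components(mesh)
    assert lab.n_components == 0 and len(lab.face_labels) == 0


def test_components_match_union_find_oracle_on_random_clusters():
    rng = np.random.default_rng(3)
    verts, faces = [], []
    off = 0
    for k in range(50):
        c = rng.uniform(-10, 10, size=3)
        n_tri = int(rng.integers(1, 8))
        # chain of triangles sharing edges within the cluster
        pts = c + rng.normal(scale=0.1, size=(n_tri + 2, 3))
        verts.append(pts)
        for t in range(n_tri):
            faces.append([off + t, off + t + 1, off + t + 2])
        off += n_tri + 2
    mesh = TriMesh(np.vstack(verts), np.array(faces))
    lab = connected_components(mesh)
    oracle = _union_find_components(mesh)
    # same partition: label pairs must be consistent both ways
    assert lab.n_components == len(np.unique(oracle))
    joint = {(a, b) for a, b in zip(lab.face_labels, oracle)}
    assert len(joint) == lab.n_components


def test_component_ids_ordered_by_descending_size():
    # cluster A: 3 faces, cluster B: 1 face -> A gets label 0
    verts = np.vstack(
        [np.random.default_rng(4).normal(size=(5, 3)), [[9, 9, 9], [10, 9, 9], [9, 10, 9]]]
    )
    faces = np.array([[5, 6, 7], [0, 1, 2], [1, 2, 3], [2, 3, 4]])
    lab = connected_components(TriMesh(verts, faces))
    assert lab.face_labels[0] == 1  # the singleton placed first still labels second
    assert np.all(lab.face_labels[1:] == 0)


# ---------------------------------------------------------------------------
# cleaning


def test_collinear_face_is_removed():
    mesh = TriMesh(
        np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]], float),
        np.array([[0, 1, 2], [0, 1, 3]]),
    )
    out = clean_mesh(mesh)
    assert out.n_faces == 1
    assert np.allclose(out.vertices[out.faces[0]][:, :2], [[0, 0], [1, 0], [0, 1]])


def test_clean_mesh_identity_and_idempotence():
    cube = make_cube()
    once = clean_mesh(cube)
    assert np.array_equal(once.faces, cube.faces)
    assert np.allclose(once.vertices, cube.vertices)
    twice = clean_mesh(once)
    assert np.array_equal(twice.faces, once.faces)


def test_degenerate_removal_matches_area_oracle():
    rng = np.random.default_rng(5)
    verts = rng.uniform(size=(60, 3))
    faces = rng.integers(0, 60, size=(40, 3))
    # inject topologically degenerate faces
    faces[::7, 1] = faces[::7, 0]
    mesh = TriMesh(verts, faces)
    out = clean_mesh(mesh)
    areas = triangle_areas(mesh)
    topo = (
        (faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2]) | (faces[:, 2] == faces[:, 0])
    )
    expected = int(np.sum(~topo & (areas >= 1e-12)))
    assert out.n_faces == expected
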