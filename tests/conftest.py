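"""Shared fixtures: small canonical meshes and one session-scoped scene."""

import numpy as np
import pytest

from weedvol.mesh_core import Plane, TriMesh
from weedvol.synthetic_field import SceneConfig, generate_scene, noiseless


def make_cube(side: float = 1.0, origin=(0.0, 0.0, 0.0)) -> TriMesh:
    """Axis-aligned cube as 12 outward-wound triangles."""
    o = np.asarray(origin, dtype=float)
    v = o + side * np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        dtype=float,
    )
    f = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom (z=0, outward down)
            [4, 5, 6], [4, 6, 7],  # top
            [0, 1, 5], [0, 5, 4],  # y=0
            [2, 3, 7], [2, 7, 6],  # y=1
            [1, 2, 6], [1, 6, 5],  # x=1
            [3, 0, 4], [3, 4, 7],  # x=0
        ]
    )
    return TriMesh(v, f)


def make_tetrahedron() -> TriMesh:
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriMesh(v, f)


def make_sphere(radius: float, n_theta: int = 48, n_phi: int = 96) -> TriMesh:
    """UV sphere centered at origin (closed, outward)."""
    th = np.linspace(0, np.pi, n_theta)[1:-1]
    ph = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    tt, pp = np.meshgrid(th, ph, indexing="ij")
    ring = np.column_stack(
        [
            (radius * np.sin(tt) * np.cos(pp)).ravel(),
            (radius * np.sin(tt) * np.sin(pp)).ravel(),
            (radius * np.cos(tt)).ravel(),
        ]
    )
    verts = np.vstack([[0, 0, radius], ring, [0, 0, -radius]])
    K, J = len(th), n_phi
    idx = lambda k, j: 1 + k * J + (j % J)
    faces = []
    for j in range(J):
        faces.append([0, idx(0, j), idx(0, j + 1)])
        faces.append([len(verts) - 1, idx(K - 1, j + 1), idx(K - 1, j)])
    for k in range(K - 1):
        for j in range(J):
            faces.append([idx(k, j), idx(k + 1, j), idx(k + 1, j + 1)])
            faces.append([idx(k, j), idx(k + 1, j + 1), idx(k, j + 1)])
    return TriMesh(verts, np.array(faces))


def random_convex_mesh(rng: np.random.Generator, n_points: int = 50) -> TriMesh:
    """Convex hull of random points, outward-wound."""
    from scipy.spatial import ConvexHull

    pts = rng.normal(size=(n_points, 3)) * rng.uniform(0.05, 0.5)
    hull = ConvexHull(pts)
    verts = pts[hull.vertices]
    remap = {old: new for new, old in enumerate(hull.vertices)}
    faces = np.array([[remap[i] for i in s] for s in hull.simplices])
    m = TriMesh(verts, faces)
    # ConvexHull simplices are not consistently wound; orient outward
    from weedvol.volumetry import repair_orientation

    return repair_orientation(m)


GROUND = Plane(np.array([0.0, 0.0, 1.0]), 0.0)


@pytest.fixture(scope="session")
def pristine_scene():
    """One noiseless synthetic frame scene shared across tests."""
    return generate_scene(noiseless(seed=7))


@pytest.fixture(scope="session")
def noisy_scene():
    """One scene with the default sensor noise model."""
    return generate_scene(SceneConfig(seed=21))
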