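"""Triangular-mesh data model, PLY/OBJ I/O, and topology utilities.

The whole pipeline trades in one currency: a colored triangular mesh in
meters, as produced by fusing depth-camera frames of a field quadrat.
This module defines that container (:class:`TriMesh`), reads and writes it
in Meshlab-interoperable formats (ASCII and binary-little-endian PLY, OBJ
as a geometry-only secondary import), and provides the two topology
primitives everything downstream relies on: edge-connected face components
(the "connected faces" used to grow a crop plant from its tall seed faces)
and degenerate-face cleaning.

Conventions: right-handed coordinates with the z axis up, units meters,
ground near z = 0 once the sampling frame has been leveled.  Colors are
stored per vertex as 8-bit RGB; per-face color input is averaged onto the
incident vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cs_connected_components

__all__ = [
    "TriMesh",
    "PointCloud",
    "Plane",
    "ComponentLabeling",
    "MeshIOError",
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "connected_components",
    "face_adjacency_pairs",
    "clean_mesh",
    "triangle_areas",
    "triangle_centroids",
    "DEGENERATE_AREA",
]

#: Faces with area below this (m^2) are numerically zero at scene scale.
DEGENERATE_AREA = 1e-12


class MeshIOError(IOError):
    """A mesh file could not be read or written."""


class MeshFormatError(ValueError):
    """A mesh file parsed but violates structural invariants."""


@dataclass
class PointCloud:
    """Unstructured 3D points in meters with optional per-point RGB."""

    points: np.ndarray
    colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
            if len(self.colors) != len(self.points):
                raise ValueError("colors must have exactly one entry per point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class TriMesh:
    """Triangular surface mesh: vertices (m), faces, optional vertex RGB.

    ``face_ids`` is bookkeeping: when a mesh is derived from another by
    face subsetting (cropping, splitting, segmentation) it records, for
    every face, the id the face carried in the source mesh.  Freshly
    constructed meshes default to ``arange(n_faces)``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_colors: np.ndarray | None = None
    face_ids: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.vertex_colors is not None:
            self.vertex_colors = np.asarray(self.vertex_colors, dtype=np.uint8).reshape(-1, 3)
        if self.face_ids is None:
            self.face_ids = np.arange(len(self.faces), dtype=np.int64)
        else:
            self.face_ids = np.asarray(self.face_ids, dtype=np.int64).reshape(-1)

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if not np.all(np.isfinite(self.vertices)):
            raise MeshFormatError("non-finite vertex coordinates")
        if len(self.faces):
            bad = np.flatnonzero((self.faces < 0) | (self.faces >= len(self.vertices)))
            if bad.size:
                f = bad[0] // 3
                raise MeshFormatError(
                    f"face {f} references vertex index {self.faces.flat[bad[0]]} "
                    f"of {len(self.vertices)} vertices"
                )
        if self.vertex_colors is not None and len(self.vertex_colors) != len(self.vertices):
            raise MeshFormatError("vertex_colors length must equal vertex count")
        if len(self.face_ids) != len(self.faces):
            raise MeshFormatError("face_ids length must equal face count")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_empty(self) -> bool:
        return self.n_faces == 0

    # -- derivation ----------------------------------------------------
    def submesh(self, face_mask: np.ndarray) -> "TriMesh":
        """Mesh restricted to the selected faces; unreferenced vertices dropped.

        ``face_mask`` may be boolean or an index array.  ``face_ids`` of the
        result point back to this mesh's ``face_ids``.
        """
        face_mask = np.asarray(face_mask)
        faces = self.faces[face_mask]
        ids = self.face_ids[face_mask]
        used = np.unique(faces)
        remap = np.full(self.n_vertices, -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        colors = self.vertex_colors[used] if self.vertex_colors is not None else None
        return TriMesh(self.vertices[used], remap[faces], colors, ids)

    @staticmethod
    def concatenate(meshes: "list[TriMesh]") -> "TriMesh":
        """Stack meshes into one; face_ids are concatenated as given."""
        meshes = [m for m in meshes if m.n_vertices]
        if not meshes:
            return TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
        offs = np.cumsum([0] + [m.n_vertices for m in meshes[:-1]])
        verts = np.vstack([m.vertices for m in meshes])
        faces = np.vstack([m.faces + o for m, o in zip(meshes, offs)])
        if all(m.vertex_colors is not None for m in meshes):
            colors = np.vstack([m.vertex_colors for m in meshes])
        else:
            colors = None
        ids = np.concatenate([m.face_ids for m in meshes])
        return TriMesh(verts, faces, colors, ids)

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.vertex_colors is None else self.vertex_colors.copy(),
            self.face_ids.copy(),
        )


@dataclass
class Plane:
    """Oriented plane ``normal . x = offset`` (normal unit length, z-up)."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be nonzero")
        n = n / norm
        if n[2] < 0:  # keep "up" consistent with the z-up convention
            n = -n
            self.offset = -float(self.offset)
        self.normal = n
        self.offset = float(self.offset)

    def height_of(self, points: np.ndarray) -> np.ndarray:
        """Signed perpendicular height of points above the plane (m)."""
        return np.asarray(points, dtype=np.float64).reshape(-1, 3) @ self.normal - self.offset

    def project(self, points: np.ndarray) -> np.ndarray:
        """Orthogonal projection of points onto the plane."""
        p = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        return p - np.outer(self.height_of(p), self.normal)

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal in-plane axes (deterministic)."""
        n = self.normal
        ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(n, ref)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v


@dataclass
class ComponentLabeling:
    """Partition of the face set into edge-connected components.

    Component ids are ordered by descending face count; ties broken by the
    lower minimum face index.
    """

    face_labels: np.ndarray
    n_components: int

    def faces_of(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.face_labels == label)


# ---------------------------------------------------------------------------
# geometry helpers


def triangle_areas(mesh: TriMesh) -> np.ndarray:
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def triangle_centroids(mesh: TriMesh) -> np.ndarray:
    v = mesh.vertices
    return v[mesh.faces].mean(axis=1)


# ---------------------------------------------------------------------------
# I/O


def _as_trimesh(mesh: TriMesh) -> trimesh.Trimesh:
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    if mesh.vertex_colors is not None:
        rgba = np.column_stack(
            [mesh.vertex_colors, np.full(mesh.n_vertices, 255, dtype=np.uint8)]
        )
        tm.visual.vertex_colors = rgba
    return tm


def _from_trimesh(tm: trimesh.Trimesh) -> TriMesh:
    colors = None
    kind = tm.visual.kind if tm.visual is not None else None
    if kind == "vertex":
        colors = np.asarray(tm.visual.vertex_colors, dtype=np.uint8)[:, :3]
    elif kind == "face":
        # average per-face color onto incident vertices (depth-camera exports
        # are per-vertex; per-face input is accepted and converted)
        fc = np.asarray(tm.visual.face_colors, dtype=np.float64)[:, :3]
        acc = np.zeros((len(tm.vertices), 3))
        cnt = np.zeros(len(tm.vertices))
        for k in range(3):
            np.add.at(acc, tm.faces[:, k], fc)
            np.add.at(cnt, tm.faces[:, k], 1.0)
        cnt[cnt == 0] = 1.0
        colors = np.clip(acc / cnt[:, None], 0, 255).astype(np.uint8)
    return TriMesh(np.asarray(tm.vertices, dtype=np.float64), np.asarray(tm.faces), colors)


def read_mesh(path: str | Path, format: str | None = None) -> TriMesh:
    """Read a triangular mesh from PLY (ASCII or binary LE) or OBJ.

    Vertex colors are read when present.  Raises :class:`MeshIOError` for
    unreadable files and :class:`MeshFormatError` for structurally invalid
    content (e.g., a face index out of range, reported by face number).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("ply", "obj"):
        raise MeshIOError(f"unsupported mesh format: {fmt!r}")
    if not path.exists():
        raise MeshIOError(f"no such file: {path}")
    try:
        tm = trimesh.load(str(path), file_type=fmt, process=False, maintain_order=True)
    except MemoryError:
        raise
    except Exception as exc:  # parser errors vary by backend
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise MeshFormatError(f"{path}: file contains no mesh geometry")
        tm = trimesh.util.concatenate(geoms)
    mesh = _from_trimesh(tm)
    mesh.validate()
    return mesh


def write_mesh(
    mesh: TriMesh, path: str | Path, format: str | None = None, *, binary: bool = False
) -> None:
    """Write a mesh to PLY (colors preserved) or OBJ (geometry only).

    PLY is written ASCII by default; ``binary=True`` selects the
    binary-little-endian dialect.  Output is byte-stable for fixed input.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("ply", "obj"):
        raise MeshIOError(f"unsupported mesh format: {fmt!r}")
    mesh.validate()
    tm = _as_trimesh(mesh)
    if fmt == "ply":
        encoding = "binary_little_endian" if binary else "ascii"
        data = tm.export(file_type="ply", encoding=encoding)
    else:
        data = tm.export(file_type="obj")
    if isinstance(data, str):
        data = data.encode()
    try:
        path.write_bytes(data)
    except OSError as exc:
        raise MeshIOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# topology


def _edge_keys(faces: np.ndarray, n_vertices: int) -> np.ndarray:
    """Undirected edge keys, 3 per face, as scalar codes."""
    e = np.stack(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=1
    ).reshape(-1, 2)
    lo = e.min(axis=1).astype(np.int64)
    hi = e.max(axis=1).astype(np.int64)
    return lo * np.int64(n_vertices) + hi


def face_adjacency_pairs(mesh: TriMesh) -> np.ndarray:
    """Pairs of face indices sharing an undirected edge, shape (k, 2).

    Shared-vertex contact does not count: adjacency through a single pinch
    vertex would leak selections between plants that merely touch.
    """
    if mesh.is_empty():
        return np.zeros((0, 2), dtype=np.int64)
    keys = _edge_keys(mesh.faces, mesh.n_vertices)
    face_of = np.repeat(np.arange(mesh.n_faces, dtype=np.int64), 3)
    order = np.argsort(keys, kind="stable")
    keys, face_of = keys[order], face_of[order]
    # group boundaries
    starts = np.flatnonzero(np.concatenate(([True], keys[1:] != keys[:-1])))
    counts = np.diff(np.append(starts, len(keys)))
    pairs = []
    # edges shared by exactly 2 faces dominate; handle >2 (non-manifold) too
    two = counts == 2
    s2 = starts[two]
    if s2.size:
        pairs.append(np.column_stack([face_of[s2], face_of[s2 + 1]]))
    for s, c in zip(starts[counts > 2], counts[counts > 2]):
        fs = face_of[s : s + c]
        i, j = np.triu_indices(c, k=1)
        pairs.append(np.column_stack([fs[i], fs[j]]))
    if not pairs:
        return np.zeros((0, 2), dtype=np.int64)
    return np.vstack(pairs)


def connected_components(mesh: TriMesh, adjacency: str = "edge_shared") -> ComponentLabeling:
    """Label faces by edge-connected component.

    Ids are ordered by descending component face count; ties go to the
    component containing the lower minimum face index.  An empty mesh
    yields an empty labeling.
    """
    if adjacency != "edge_shared":
        raise ValueError(f"unknown adjacency rule: {adjacency!r}")
    if mesh.is_empty():
        return ComponentLabeling(np.zeros(0, dtype=np.int64), 0)
    pairs = face_adjacency_pairs(mesh)
    n = mesh.n_faces
    if pairs.size:
        g = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        n_comp, raw = _cs_connected_components(g, directed=False)
    else:
        n_comp, raw = n, np.arange(n)
    # canonical ordering
    sizes = np.bincount(raw, minlength=n_comp)
    first = np.full(n_comp, n, dtype=np.int64)
    np.minimum.at(first, raw, np.arange(n))
    order = np.lexsort((first, -sizes))
    relabel = np.empty(n_comp, dtype=np.int64)
    relabel[order] = np.arange(n_comp)
    return ComponentLabeling(relabel[raw], n_comp)


def clean_mesh(mesh: TriMesh, area_threshold: float = DEGENERATE_AREA) -> TriMesh:
    """Drop degenerate faces and unreferenced vertices.

    A face is degenerate if it repeats a vertex index or its area is below
    ``area_threshold`` (default numerically zero at scene scale).  The
    operation is idempotent; an empty mesh passes through unchanged.
    """
    if mesh.is_empty():
        return mesh.submesh(np.zeros(0, dtype=bool)) if mesh.n_vertices else mesh.copy()
    f = mesh.faces
    topological = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 2] == f[:, 0])
    keep = ~topological & (triangle_areas(mesh) >= area_threshold)
    return mesh.submesh(keep)
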