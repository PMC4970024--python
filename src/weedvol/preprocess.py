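"""Scan preprocessing: noise filtering, frame detection, cropping, splitting.

A fused field scan contains flying-pixel outliers, the white 1 m x 1 m
sampling frame, and soil well beyond the plot of interest.  This module
(1) removes points with no neighbor within 1 cm (the "no connection"
rule), (2) locates the white frame from vertex colors — PCA plane fit of
the low-chroma bright vertices followed by a minimum-area rotated
rectangle of their in-plane projection — (3) crops the mesh to the frame
interior, and (4) splits it into the four 0.5 m x 0.5 m quadrats used for
sampling, with user-supplied row / inter-row position labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh_core import Plane, PointCloud, TriMesh, triangle_centroids

__all__ = [
    "FramePose",
    "QuadratSample",
    "FrameDetectionError",
    "EmptyCropError",
    "white_vertex_mask",
    "filter_isolated_points",
    "filter_isolated_vertices",
    "detect_frame",
    "crop_to_frame",
    "split_quadrats",
    "DEFAULT_POSITION_LABELS",
]

DEFAULT_POSITION_LABELS = ("row", "row", "inter_row", "inter_row")


class FrameDetectionError(ValueError):
    """The white sampling frame could not be located."""


class EmptyCropError(ValueError):
    """Cropping to the frame produced an empty mesh."""


@dataclass
class FramePose:
    """Recovered pose of the square sampling frame.

    ``corners`` are four coplanar 3D points, counterclockwise seen from
    above, starting at the lexicographically smallest (x, y); the frame
    polygon is their convex hull.  ``ground_plane`` is the least-squares
    plane through the white frame vertices, used as the height datum for
    every downstream stage.
    """

    corners: np.ndarray
    ground_plane: Plane
    side_length: float
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        self.corners = np.asarray(self.corners, dtype=np.float64).reshape(4, 3)

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit in-plane axes along the first two frame edges."""
        u = self.corners[1] - self.corners[0]
        v = self.corners[3] - self.corners[0]
        return u / np.linalg.norm(u), v / np.linalg.norm(v)

    def side_lengths(self) -> np.ndarray:
        d = np.diff(np.vstack([self.corners, self.corners[:1]]), axis=0)
        return np.linalg.norm(d, axis=1)

    def to_frame_coords(self, points: np.ndarray) -> np.ndarray:
        """(u, v) coordinates relative to corner 0 along the frame edges."""
        p = np.asarray(points, dtype=np.float64).reshape(-1, 3) - self.corners[0]
        eu, ev = self.axes()
        return np.column_stack([p @ eu, p @ ev])


@dataclass
class QuadratSample:
    """One cropped 0.5 m x 0.5 m sub-mesh with its position label."""

    mesh: TriMesh
    quadrat_index: int
    position_label: str
    frame: FramePose
    face_indices: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def validate(self, tolerance: float | None = None) -> None:
        """Check all vertices lie inside this quadrat's rectangle.

        Faces are assigned by centroid, so a face straddling the midline
        legitimately keeps vertices slightly outside; the default
        tolerance is therefore the longest face edge of the sample.
        """
        if self.mesh.is_empty():
            return
        if tolerance is None:
            v = self.mesh.vertices
            f = self.mesh.faces
            e = np.concatenate(
                [
                    np.linalg.norm(v[f[:, 0]] - v[f[:, 1]], axis=1),
                    np.linalg.norm(v[f[:, 1]] - v[f[:, 2]], axis=1),
                    np.linalg.norm(v[f[:, 2]] - v[f[:, 0]], axis=1),
                ]
            )
            tolerance = float(e.max()) if e.size else 1e-3
        uv = self.frame.to_frame_coords(self.mesh.vertices)
        su, sv = self.frame.side_lengths()[0], self.frame.side_lengths()[3]
        lo_u = 0.0 if self.quadrat_index % 2 == 0 else su / 2
        hi_u = su / 2 if self.quadrat_index % 2 == 0 else su
        lo_v = 0.0 if self.quadrat_index < 2 else sv / 2
        hi_v = sv / 2 if self.quadrat_index < 2 else sv
        ok = (
            (uv[:, 0] >= lo_u - tolerance)
            & (uv[:, 0] <= hi_u + tolerance)
            & (uv[:, 1] >= lo_v - tolerance)
            & (uv[:, 1] <= hi_v + tolerance)
        )
        if not ok.all():
            raise ValueError(
                f"{np.count_nonzero(~ok)} vertices outside quadrat "
                f"{self.quadrat_index} beyond tolerance {tolerance:.4f} m"
            )


# ---------------------------------------------------------------------------
# (a) isolated-point filtering


def filter_isolated_points(
    cloud: PointCloud, radius: float = 0.01, min_neighbors: int = 1
) -> PointCloud:
    """Drop points with fewer than ``min_neighbors`` others within ``radius``.

    This is the "1 cm out of the grid" rule: a genuine surface sample from
    a dense scan always has close neighbors; flying pixels do not.
    Idempotent? No — removal can strand previously supported points — but
    on scan-like densities a second pass is a no-op; order-independent by
    construction.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(cloud) == 0:
        return PointCloud(cloud.points.copy(), None)
    keep = _supported_mask(cloud.points, radius, min_neighbors)
    colors = cloud.colors[keep] if cloud.colors is not None else None
    return PointCloud(cloud.points[keep], colors)


def _supported_mask(points: np.ndarray, radius: float, min_neighbors: int) -> np.ndarray:
    tree = cKDTree(points)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    counts = np.zeros(len(points), dtype=np.int64)
    if len(pairs):
        np.add.at(counts, pairs[:, 0], 1)
        np.add.at(counts, pairs[:, 1], 1)
    return counts >= min_neighbors


def filter_isolated_vertices(
    mesh: TriMesh, radius: float = 0.01, min_neighbors: int = 1
) -> TriMesh:
    """Mesh entry point of the isolated-point rule.

    The neighbor test runs on vertex positions (topology ignored, so
    injected outlier vertices with no faces are caught too); faces that
    lose a vertex are dropped and the rest reindexed.
    """
    if mesh.n_vertices == 0:
        return mesh.copy()
    keep = _supported_mask(mesh.vertices, radius, min_neighbors)
    if len(mesh.faces):
        face_ok = keep[mesh.faces].all(axis=1)
    else:
        face_ok = np.zeros(0, dtype=bool)
    out = mesh.submesh(face_ok)
    return out


# ---------------------------------------------------------------------------
# (b) frame detection, cropping, quadrat split


def white_vertex_mask(
    mesh: TriMesh, white_threshold: int = 200, saturation_max: int = 30
) -> np.ndarray:
    """Low-chroma bright vertices: all channels >= threshold, max-min small.

    The chroma bound keeps shaded white paint in and bright sunlit
    vegetation out.
    """
    if mesh.vertex_colors is None:
        raise FrameDetectionError("mesh has no vertex colors")
    c = mesh.vertex_colors.astype(np.int64)
    return (c.min(axis=1) >= white_threshold) & (c.max(axis=1) - c.min(axis=1) <= saturation_max)


def detect_frame(
    mesh: TriMesh,
    white_threshold: int = 200,
    saturation_max: int = 30,
    min_white_vertices: int = 200,
) -> FramePose:
    """Locate the white sampling frame by color segmentation.

    PCA plane fit of the white vertices gives the ground plane; the
    minimum-area rotated rectangle of their in-plane projection gives the
    four corners (the frame band's outer edge).
    """
    from shapely import MultiPoint

    white = white_vertex_mask(mesh, white_threshold, saturation_max)
    n_white = int(np.count_nonzero(white))
    if n_white < min_white_vertices:
        raise FrameDetectionError(
            f"no frame found: only {n_white} white vertices "
            f"(minimum {min_white_vertices})"
        )
    pts = mesh.vertices[white]
    centroid = pts.mean(axis=0)
    _, svals, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    normal = vt[2]
    plane = Plane(normal, float(centroid @ normal))
    rms = float(np.sqrt(np.mean(plane.height_of(pts) ** 2)))
    u, w = plane.basis()
    p2 = np.column_stack([pts @ u, pts @ w])
    rect = MultiPoint(p2).minimum_rotated_rectangle
    xy = np.asarray(rect.exterior.coords)[:4]
    corners3 = plane.project(xy[:, 0:1] * u + xy[:, 1:2] * w)
    corners3 = _canonical_corners(corners3)
    sides = np.linalg.norm(np.diff(np.vstack([corners3, corners3[:1]]), axis=0), axis=1)
    return FramePose(corners3, plane, float(sides.mean()), rms)


def _canonical_corners(corners: np.ndarray) -> np.ndarray:
    """Order corners CCW seen from above, starting at the min-(x+y) corner.

    The x+y criterion is stable under small detection noise (corners of a
    square differ by a full side in it), unlike a lexicographic rule.
    """
    c = corners - corners.mean(axis=0)
    ang = np.arctan2(c[:, 1], c[:, 0])
    order = np.argsort(ang)  # CCW in the xy projection
    corners = corners[order]
    start = int(np.argmin(corners[:, 0] + corners[:, 1]))
    return np.roll(corners, -start, axis=0)


def crop_to_frame(
    mesh: TriMesh,
    frame: FramePose,
    white_threshold: int = 200,
    saturation_max: int = 30,
    return_indices: bool = False,
):
    """Keep faces whose centroid falls inside the frame polygon.

    Faces touching a white (frame) vertex are excluded so the frame itself
    never contaminates plant or soil statistics.  Raises
    :class:`EmptyCropError` when nothing remains.
    """
    uv = frame.to_frame_coords(triangle_centroids(mesh))
    su = frame.side_lengths()[0]
    sv = frame.side_lengths()[3]
    inside = (uv[:, 0] >= 0) & (uv[:, 0] <= su) & (uv[:, 1] >= 0) & (uv[:, 1] <= sv)
    if mesh.vertex_colors is not None:
        white = white_vertex_mask(mesh, white_threshold, saturation_max)
        inside &= ~white[mesh.faces].any(axis=1)
    if not inside.any():
        raise EmptyCropError("empty quadrat: no faces inside the frame")
    out = mesh.submesh(inside)
    if return_indices:
        return out, np.flatnonzero(inside)
    return out


def split_quadrats(
    mesh: TriMesh,
    frame: FramePose,
    labels: tuple[str, str, str, str] = DEFAULT_POSITION_LABELS,
) -> list[QuadratSample]:
    """Split a cropped mesh into the four 0.5 m x 0.5 m quadrats.

    Assignment is by face centroid in frame coordinates with half-open
    midline intervals: a centroid exactly on a midline goes to the
    higher-index quadrat ([mid, max] side).  Quadrat k has bit 0 = u side,
    bit 1 = v side.  The four face sets are disjoint and cover the input.
    """
    if len(labels) != 4:
        raise ValueError("exactly four position labels required")
    uv = frame.to_frame_coords(triangle_centroids(mesh))
    su = frame.side_lengths()[0]
    sv = frame.side_lengths()[3]
    qi = (uv[:, 0] >= su / 2).astype(np.int64) + 2 * (uv[:, 1] >= sv / 2).astype(np.int64)
    samples = []
    for k in range(4):
        mask = qi == k
        samples.append(
            QuadratSample(
                mesh=mesh.submesh(mask),
                quadrat_index=k,
                position_label=labels[k],
                frame=frame,
                face_indices=np.flatnonzero(mask),
            )
        )
    return samples
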