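"""Dual crop/weed/soil segmentation: height selection plus RGB filtering.

Maize towers over the weed flora (crop plants 40-55 cm against grasses of
at most 20 cm and broad-leaved weeds under 10 cm), so the crop is isolated
first: every face with a vertex above the height threshold seeds a region
that grows across edge-connected, vegetation-colored faces — the whole
plant follows its tall seed.  Weeds, however, sit inside the soil
microrelief (~2 cm), where height alone is useless; the remaining faces
are therefore classified by the excess-green index ExG = 2G - R - B, the
standard agronomic greenness measure.  The result is a disjoint partition
of every input face into maize / weed / soil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cs_components

from .mesh_core import Plane, TriMesh, face_adjacency_pairs
from .preprocess import QuadratSample

__all__ = [
    "SegmentationParams",
    "VegetationMask",
    "SegmentationResult",
    "HeightFeatures",
    "MAIZE",
    "WEED",
    "SOIL",
    "CLASS_NAMES",
    "excess_green",
    "vegetation_mask",
    "otsu_exg_threshold",
    "select_maize",
    "select_weeds",
    "segment_sample",
    "weed_height_features",
]

MAIZE, WEED, SOIL = 0, 1, 2
CLASS_NAMES = ("maize", "weed", "soil")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable thresholds of the dual methodology.

    height_threshold: m above ground separating crop seeds from weeds;
        default 0.30, the midpoint between the tallest expected weed
        (0.20 m) and the shortest expected maize (0.40 m).
    exg_threshold: excess-green index above which a vertex counts as
        green vegetation; default 20 on the 8-bit ExG scale.
    ground_clearance: m; faces lying entirely below this height are
        absorbed into an adjacent region but never propagate growth,
        preventing flood-fill leakage along the soil where a stalk meets
        the ground.
    """

    height_threshold: float = 0.30
    exg_threshold: float = 20.0
    ground_clearance: float = 0.02


@dataclass
class VegetationMask:
    """Per-vertex greenness: ExG values and the thresholded flags."""

    vertex_flags: np.ndarray
    index_values: np.ndarray


@dataclass
class HeightFeatures:
    """Summary of weed canopy heights above the ground plane (m)."""

    max_height: float
    p90_height: float
    mean_height: float


@dataclass
class SegmentationResult:
    """Disjoint maize / weed / soil partition of a quadrat mesh.

    ``face_assignment`` holds one of MAIZE, WEED, SOIL per input face, in
    input face order; the three sub-meshes are its materialization.
    """

    maize_mesh: TriMesh
    weed_mesh: TriMesh
    soil_mesh: TriMesh
    face_assignment: np.ndarray


def excess_green(color) -> np.ndarray | float:
    """Excess-green index ExG = 2G - R - B of an RGB triple or array.

    Ranges from -510 (pure magenta) to +510 (pure green); achromatic
    colors score 0.
    """
    c = np.asarray(color, dtype=np.int64)
    scalar = c.ndim == 1
    c = c.reshape(-1, 3)
    exg = 2 * c[:, 1] - c[:, 0] - c[:, 2]
    return float(exg[0]) if scalar else exg


def vegetation_mask(mesh: TriMesh, exg_threshold: float = 20.0) -> VegetationMask:
    """Flag green vertices of a colored mesh by thresholding ExG."""
    if mesh.vertex_colors is None:
        raise ValueError("mesh has no vertex colors")
    exg = excess_green(mesh.vertex_colors)
    return VegetationMask(exg > exg_threshold, exg)


def otsu_exg_threshold(mesh: TriMesh) -> float:
    """Automatic ExG threshold by Otsu's criterion on the vertex histogram.

    Optional alternative to the fixed default when illumination shifts
    the greenness distribution.
    """
    if mesh.vertex_colors is None:
        raise ValueError("mesh has no vertex colors")
    exg = np.asarray(excess_green(mesh.vertex_colors), dtype=np.float64)
    lo, hi = exg.min(), exg.max()
    if hi <= lo:
        return float(lo)
    hist, edges = np.histogram(exg, bins=256, range=(lo, hi))
    mids = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(np.float64)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * mids)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return float(mids[int(np.argmax(sigma_b))])


def _vegetation_faces(mesh: TriMesh, exg_threshold: float) -> np.ndarray:
    """Face-level vote: a face is vegetation iff >= 2 of 3 vertices are green."""
    flags = vegetation_mask(mesh, exg_threshold).vertex_flags
    return flags[mesh.faces].sum(axis=1) >= 2


def _maize_face_mask(
    mesh: TriMesh, ground_plane: Plane, params: SegmentationParams
) -> np.ndarray:
    """Faces belonging to height-seeded, vegetation-restricted regions.

    Region graph: nodes are vegetation faces; edges join faces sharing a
    mesh edge, except between two faces both entirely below the ground
    clearance (those may be absorbed but cannot relay growth).  A region
    is maize iff it contains a seed face (some vertex above the height
    threshold).
    """
    if mesh.is_empty():
        return np.zeros(0, dtype=bool)
    veg = _vegetation_faces(mesh, params.exg_threshold)
    heights = ground_plane.height_of(mesh.vertices)
    face_h = heights[mesh.faces]
    seed = veg & (face_h.max(axis=1) > params.height_threshold)
    if not seed.any():
        return np.zeros(mesh.n_faces, dtype=bool)
    low = face_h.max(axis=1) < params.ground_clearance
    pairs = face_adjacency_pairs(mesh)
    if len(pairs):
        ok = (
            veg[pairs[:, 0]]
            & veg[pairs[:, 1]]
            & ~(low[pairs[:, 0]] & low[pairs[:, 1]])
        )
        pairs = pairs[ok]
    n = mesh.n_faces
    if len(pairs):
        g = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        _, labels = _cs_components(g, directed=False)
    else:
        labels = np.arange(n)
    seed_labels = np.unique(labels[seed])
    return veg & np.isin(labels, seed_labels)


def select_maize(
    sample: QuadratSample,
    height_threshold: float = 0.30,
    exg_threshold: float = 20.0,
    ground_clearance: float = 0.02,
) -> tuple[TriMesh, TriMesh]:
    """Isolate the crop: (maize_mesh, remainder).

    Heights are measured perpendicular to the frame's ground plane.  With
    no face above the threshold the maize mesh is empty and the remainder
    is the whole input.
    """
    params = SegmentationParams(height_threshold, exg_threshold, ground_clearance)
    mask = _maize_face_mask(sample.mesh, sample.frame.ground_plane, params)
    return sample.mesh.submesh(mask), sample.mesh.submesh(~mask)


def select_weeds(remainder: TriMesh, exg_threshold: float = 20.0) -> tuple[TriMesh, TriMesh]:
    """Split the crop-free remainder into (weed_mesh, soil_mesh) by color.

    A face is weed iff at least two of its three vertices exceed the
    excess-green threshold; raising the threshold can only shrink the
    weed set.
    """
    if remainder.is_empty():
        return remainder.submesh(np.zeros(0, dtype=bool)), remainder.copy()
    weed = _vegetation_faces(remainder, exg_threshold)
    return remainder.submesh(weed), remainder.submesh(~weed)


def segment_sample(
    sample: QuadratSample, params: SegmentationParams = SegmentationParams()
) -> SegmentationResult:
    """Full dual segmentation of one quadrat into maize / weed / soil.

    Composition of height-seeded crop selection followed by excess-green
    weed selection on the remainder; deterministic and invariant to face
    order.
    """
    mesh = sample.mesh
    assignment = np.full(mesh.n_faces, SOIL, dtype=np.int64)
    maize_mask = _maize_face_mask(mesh, sample.frame.ground_plane, params)
    assignment[maize_mask] = MAIZE
    rest = ~maize_mask
    if rest.any() and not mesh.is_empty():
        veg = _vegetation_faces(mesh, params.exg_threshold)
        assignment[rest & veg] = WEED
    return SegmentationResult(
        maize_mesh=mesh.submesh(assignment == MAIZE),
        weed_mesh=mesh.submesh(assignment == WEED),
        soil_mesh=mesh.submesh(assignment == SOIL),
        face_assignment=assignment,
    )


def weed_height_features(weed_mesh: TriMesh, ground_plane: Plane) -> HeightFeatures:
    """Max, 90th-percentile, and mean weed vertex height above ground (m).

    The per-quadrat maximum is dominated by grasses when present, which is
    what makes these features discriminative between weed classes.
    """
    if weed_mesh.n_vertices == 0:
        raise ValueError("no weed vertices")
    h = ground_plane.height_of(weed_mesh.vertices)
    return HeightFeatures(
        max_height=float(h.max()),
        p90_height=float(np.percentile(h, 90)),
        mean_height=float(h.mean()),
    )
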