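"""Synthetic field-quadrat scenes with exact ground truth.

No depth-camera accession accompanies the study design this package
implements, so a procedural generator stands in for the fused field scans:
a tilled-soil height field with ~2 cm microrelief, a white square sampling
frame of side 1 m, maize plants of 0.40-0.55 m built as lofted
star-section solids (stalk plus leaf lobes), grass tufts of thin erect
blades up to 0.20 m, and low broad-leaved rosettes under 0.10 m.  Every
plant is generated as a closed mesh whose enclosed volume is recorded at
construction, so every downstream stage can be checked against exact
truth: per-face class labels, per-plant heights, per-quadrat volumes, and
dry biomass simulated as ``biomass = density_factor * volume * (1 + eps)``
with ``eps ~ N(0, sigma)``, sigma chosen to realize a requested population
correlation between volume and biomass.

Geometry is parametric-procedural, not botanically realistic: the pipeline
consumes only heights, colors, connectivity, and volumes, and those are
reproduced faithfully.  A single integer seed reproduces a whole study
byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .mesh_core import Plane, TriMesh
from .preprocess import FramePose, _canonical_corners

__all__ = [
    "SceneConfig",
    "StudyConfig",
    "GroundTruth",
    "QuadratTruth",
    "Study",
    "PackingError",
    "FACE_SOIL",
    "FACE_FRAME",
    "FACE_MAIZE",
    "FACE_WEED",
    "TRUTH_FACE_NAMES",
    "generate_scene",
    "generate_study",
    "add_sensor_noise",
    "noiseless",
]

FACE_SOIL, FACE_FRAME, FACE_MAIZE, FACE_WEED = 0, 1, 2, 3
TRUTH_FACE_NAMES = ("soil", "frame", "maize", "weed")

_ROW_V = 0.25  # crop row position in frame coordinates (m)


class PackingError(ValueError):
    """Requested plant count cannot be placed without overlap."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic 1 m x 1 m frame scene.

    Height ranges mirror the crop/weed stand the pipeline is designed
    for: maize 0.40-0.55 m, grasses at most 0.20 m, broad-leaved weeds
    under 0.10 m, soil microrelief of about 2 cm so that color rather
    than height must separate weeds from soil.  Sensor defaults emulate a
    fused depth scan: 3 mm depth jitter along the vertical view axis, 1 %
    isolated outlier points, ~5 mm surface sampling.
    """

    n_maize: int = 6
    maize_height_range: tuple[float, float] = (0.40, 0.55)
    grass_height_range: tuple[float, float] = (0.10, 0.20)
    broadleaf_height_range: tuple[float, float] = (0.02, 0.10)
    weed_density_range: tuple[int, int] = (2, 12)
    quadrat_weed_classes: tuple[str, str, str, str] = (
        "mixture",
        "monocots",
        "dicots",
        "none",
    )
    soil_relief_amplitude: float = 0.02
    color_noise_sd: float = 3.0
    depth_noise_sd: float = 0.003
    outlier_fraction: float = 0.01
    dropout_fraction: float = 0.0
    point_spacing: float = 0.005
    frame_side: float = 1.0
    frame_band_width: float = 0.04
    scene_margin: float = 0.06
    frame_rotation_deg: float = 0.0
    frame_origin: tuple[float, float] = (0.0, 0.0)
    maize_density_factor: float = 14000.0  # g dry biomass per m^3 canopy
    weed_density_factor: float = 10000.0
    biomass_noise_sd_maize: float = 0.0
    biomass_noise_sd_weed: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("maize_height_range", "grass_height_range", "broadleaf_height_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if not 0 <= self.dropout_fraction < 1:
            raise ValueError("dropout_fraction must be in [0, 1)")
        if self.point_spacing <= 0 or self.frame_side <= 0:
            raise ValueError("point_spacing and frame_side must be positive")
        for c in self.quadrat_weed_classes:
            if c not in ("none", "monocots", "dicots", "mixture"):
                raise ValueError(f"unknown quadrat weed class {c!r}")


def noiseless(config: SceneConfig | None = None, **overrides) -> SceneConfig:
    """Copy of a scene config with every sensor noise source switched off."""
    base = config or SceneConfig()
    return replace(
        base,
        color_noise_sd=0.0,
        depth_noise_sd=0.0,
        outlier_fraction=0.0,
        dropout_fraction=0.0,
        **overrides,
    )


@dataclass
class QuadratTruth:
    """Exact per-quadrat ground truth."""

    quadrat_index: int
    position_label: str
    weed_class: str  # none / monocots / dicots / mixture
    maize_count: int
    weed_density: int
    true_maize_volume: float
    true_weed_volume: float
    maize_biomass: float
    weed_biomass: float
    biomass_eps_maize: float
    biomass_eps_weed: float
    plant_heights: list
    weed_max_height: float | None
    weed_p90_height: float | None


@dataclass
class GroundTruth:
    """Scene-level truth: face labels, quadrat records, true frame pose."""

    face_labels: np.ndarray
    quadrats: list
    frame: FramePose
    config: SceneConfig
    seed: int


@dataclass
class Study:
    """A multi-frame quadrat campaign with its ground-truth table."""

    records: list  # (frame_index, QuadratTruth)
    config: "StudyConfig"
    scenes: list | None = None  # (TriMesh, FramePose, GroundTruth) per frame

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for frame_idx, q in self.records:
            rows.append(
                {
                    "sample_id": f"f{frame_idx}_q{q.quadrat_index}",
                    "frame_index": frame_idx,
                    "quadrat_index": q.quadrat_index,
                    "position_label": q.position_label,
                    "weed_class": q.weed_class,
                    "maize_count": q.maize_count,
                    "weed_density": q.weed_density,
                    "maize_volume_m3": q.true_maize_volume,
                    "weed_volume_m3": q.true_weed_volume,
                    "total_volume_m3": q.true_maize_volume + q.true_weed_volume,
                    "maize_biomass_g": q.maize_biomass,
                    "weed_biomass_g": q.weed_biomass,
                    "weed_max_height_m": q.weed_max_height,
                    "weed_p90_height_m": q.weed_p90_height,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lofted plant solids


def _det_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    v = verts - verts.mean(axis=0)
    dets = np.einsum("ij,ij->i", v[faces[:, 0]], np.cross(v[faces[:, 1]], v[faces[:, 2]]))
    return float(dets.sum() / 6.0)


def _loft(centers: np.ndarray, zs: np.ndarray, radii: np.ndarray, phase: float = 0.0):
    """Closed solid of revolution-like loft: star-section rings plus caps.

    centers (K, 2) ring axis positions, zs (K,) ring heights, radii (K, J)
    per-ring per-angle radius.  Returns (vertices, faces) wound outward.
    """
    K, J = radii.shape
    theta = phase + 2 * np.pi * np.arange(J) / J
    ct, st = np.cos(theta), np.sin(theta)
    x = centers[:, 0:1] + radii * ct[None, :]
    y = centers[:, 1:2] + radii * st[None, :]
    z = np.broadcast_to(zs[:, None], (K, J))
    verts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    bc = np.array([[centers[0, 0], centers[0, 1], zs[0]]])
    tc = np.array([[centers[-1, 0], centers[-1, 1], zs[-1]]])
    verts = np.vstack([verts, bc, tc])
    bci, tci = K * J, K * J + 1

    j = np.arange(J)
    jn = (j + 1) % J
    k = np.arange(K - 1)[:, None]
    a = k * J + j[None, :]
    b = k * J + jn[None, :]
    c = (k + 1) * J + jn[None, :]
    d = (k + 1) * J + j[None, :]
    walls = np.concatenate(
        [
            np.stack([a, b, c], axis=-1).reshape(-1, 3),
            np.stack([a, c, d], axis=-1).reshape(-1, 3),
        ]
    )
    bottom = np.column_stack([np.full(J, bci), jn, j])
    top = np.column_stack([np.full(J, tci), (K - 1) * J + j, (K - 1) * J + jn])
    faces = np.vstack([walls, bottom, top]).astype(np.int64)
    return verts, faces


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def _build_maize(rng: np.random.Generator, height: float, base_uv: tuple[float, float]):
    """Maize plant: tapered stalk with 4-6 leaf lobes, single closed solid.

    The lowest wall ring spans 0-2.6 cm: the stalk base is featureless, so
    a single coarse ring suffices there, and every face incident to the
    base cap then reaches above the segmentation ground clearance.
    """
    J = 64
    z1 = 0.026
    K_up = max(3, int(round((height - z1) / 0.005)) + 1)
    zs = np.concatenate([[0.0], np.linspace(z1, height, K_up)])
    K = len(zs)
    stalk = 0.016 * (1.0 - 0.7 * zs / height)
    theta = 2 * np.pi * np.arange(J) / J
    r = np.broadcast_to(stalk[:, None], (K, J)).copy()
    n_leaves = int(rng.integers(4, 7))
    for _ in range(n_leaves):
        th0 = rng.uniform(0, 2 * np.pi)
        z0 = rng.uniform(0.35, 0.95) * height
        amp = rng.uniform(0.035, 0.060)
        aw = rng.uniform(0.18, 0.28)  # angular width (rad)
        vw = rng.uniform(0.10, 0.22) * height
        ang = np.exp(-0.5 * (_wrap_angle(theta - th0) / aw) ** 2)
        vert = np.exp(-0.5 * ((zs - z0) / vw) ** 2)
        r += amp * vert[:, None] * ang[None, :]
    centers = np.tile(np.asarray(base_uv, dtype=np.float64), (K, 1))
    phase = rng.uniform(0, 2 * np.pi)
    return _loft(centers, zs, r, phase)


def _build_grass(rng: np.random.Generator, height: float, base_uv: tuple[float, float]):
    """Grass tuft: 5-9 thin leaning blades; the tallest reaches ``height``."""
    n_blades = int(rng.integers(5, 10))
    parts_v, parts_f = [], []
    offset = 0
    for b in range(n_blades):
        h = height if b == 0 else height * rng.uniform(0.55, 0.95)
        K = max(4, int(round(h / 0.004)) + 1)
        J = 6
        zs = np.linspace(0.0, h, K)
        r = (0.0022 * (1.0 - 0.75 * zs / h) + 0.0005)[:, None] * np.ones((1, J))
        root = np.asarray(base_uv) + rng.uniform(-0.012, 0.012, size=2)
        lean_dir = rng.uniform(0, 2 * np.pi)
        lean = rng.uniform(0.10, 0.30) * h
        frac = (zs / h) ** 1.5
        centers = root[None, :] + lean * frac[:, None] * np.array(
            [math.cos(lean_dir), math.sin(lean_dir)]
        )
        v, f = _loft(centers, zs, r, rng.uniform(0, 2 * np.pi))
        parts_v.append(v)
        parts_f.append(f + offset)
        offset += len(v)
    return np.vstack(parts_v), np.vstack(parts_f)


def _build_broadleaf(rng: np.random.Generator, height: float, base_uv: tuple[float, float]):
    """Broad-leaved weed: low dome-shaped rosette with a wavy margin."""
    K = max(5, int(round(height / 0.004)) + 1)
    J = 64
    zs = np.linspace(0.0, height, K)
    R = rng.uniform(0.030, 0.055)
    m = int(rng.integers(4, 7))
    phi = rng.uniform(0, 2 * np.pi)
    theta = 2 * np.pi * np.arange(J) / J
    prof = R * np.sqrt(np.clip(1.0 - (zs / height) ** 2, 0.004, None))
    wave = 1.0 + 0.22 * np.cos(m * theta + phi)
    r = prof[:, None] * wave[None, :]
    centers = np.tile(np.asarray(base_uv, dtype=np.float64), (K, 1))
    return _loft(centers, zs, r, rng.uniform(0, 2 * np.pi))


_BUILDERS = {"maize": _build_maize, "grass": _build_grass, "broadleaf": _build_broadleaf}
_BASE_COLORS = {
    "maize": np.array([72, 158, 62], dtype=np.float64),
    "grass": np.array([82, 166, 70], dtype=np.float64),
    "broadleaf": np.array([62, 150, 58], dtype=np.float64),
}


def _plant_colors(rng: np.random.Generator, n: int, kind: str) -> np.ndarray:
    # lightness-only variation keeps the excess-green index of the class stable
    f = np.clip(rng.normal(1.0, 0.08, size=n), 0.7, 1.3)
    return np.clip(_BASE_COLORS[kind][None, :] * f[:, None], 0, 255).astype(np.uint8)


@dataclass
class _Plant:
    kind: str
    height: float
    volume: float
    verts: np.ndarray
    faces: np.ndarray
    colors: np.ndarray


def _make_plant(
    rng: np.random.Generator,
    kind: str,
    height: float,
    base_uv,
    with_colors=True,
    color_rng: np.random.Generator | None = None,
):
    # colors come from a separate stream so that truth-only generation
    # (which skips them) consumes exactly the same geometry draws
    v, f = _BUILDERS[kind](rng, height, base_uv)
    vol = abs(_det_volume(v, f))
    colors = _plant_colors(color_rng or rng, len(v), kind) if with_colors else None
    return _Plant(kind, height, vol, v, f, colors)


# ---------------------------------------------------------------------------
# placement and per-quadrat sampling

_PLANT_MARGIN = {"maize": 0.09, "grass": 0.05, "broadleaf": 0.08}


def _quadrat_bounds(q: int, side: float) -> tuple[float, float, float, float]:
    half = side / 2
    u0 = 0.0 if q % 2 == 0 else half
    v0 = 0.0 if q < 2 else half
    return u0, u0 + half, v0, v0 + half


def _place_weeds(
    rng: np.random.Generator,
    q: int,
    side: float,
    kinds: list[str],
    maize_centers: np.ndarray,
) -> list[tuple[float, float]]:
    u0, u1, v0, v1 = _quadrat_bounds(q, side)
    placed: list[tuple[float, float]] = []
    for kind in kinds:
        margin = _PLANT_MARGIN[kind]
        ok = False
        for _ in range(200):
            u = rng.uniform(u0 + margin, u1 - margin)
            v = rng.uniform(v0 + margin, v1 - margin)
            if len(maize_centers) and np.min(
                np.hypot(maize_centers[:, 0] - u, maize_centers[:, 1] - v)
            ) < 0.11:
                continue
            if placed and min(math.hypot(pu - u, pv - v) for pu, pv in placed) < 0.05:
                continue
            placed.append((u, v))
            ok = True
            break
        if not ok:
            raise PackingError(
                f"could not place {len(kinds)} weeds in quadrat {q}: too dense"
            )
    return placed


def _weed_kinds(rng: np.random.Generator, weed_class: str, n: int) -> list[str]:
    if weed_class == "monocots":
        return ["grass"] * n
    if weed_class == "dicots":
        return ["broadleaf"] * n
    # mixture: at least one of each
    kinds = ["grass", "broadleaf"] + [
        "grass" if rng.random() < 0.5 else "broadleaf" for _ in range(max(0, n - 2))
    ]
    return kinds[:n]


def _sample_scene_truth(rng: np.random.Generator, config: SceneConfig, with_colors=True):
    """All stochastic plant content of one scene, plus its exact truth.

    Returns (plants_per_quadrat, quadrat_truths).  Used identically by the
    full mesh generator and the truth-only study mode so both agree draw
    for draw.
    """
    color_rng = np.random.default_rng(int(rng.integers(2**31 - 1)))
    side = config.frame_side
    row_quadrats = (0, 1)  # the crop row crosses the lower half (v = 0.25 m)
    per_row = [config.n_maize // 2, config.n_maize - config.n_maize // 2]
    plants: dict[int, list[_Plant]] = {q: [] for q in range(4)}
    truths: list[QuadratTruth] = []
    maize_centers_all: dict[int, np.ndarray] = {}

    # maize first: evenly spaced along the row with small jitter
    for qi, q in enumerate(row_quadrats):
        n = per_row[qi]
        u0, u1, _, _ = _quadrat_bounds(q, side)
        lo, hi = u0 + 0.10, u1 - 0.10
        centers = []
        if n > 0:
            if (hi - lo) < (n - 1) * 0.12:
                raise PackingError(f"{n} maize plants do not fit in quadrat {q}")
            us = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2])
            for u in us:
                centers.append(
                    (
                        float(u + rng.uniform(-0.008, 0.008)),
                        float(_ROW_V * side / 1.0 + rng.uniform(-0.01, 0.01)),
                    )
                )
        maize_centers_all[q] = np.asarray(centers).reshape(-1, 2)
        for u, v in centers:
            h = rng.uniform(*config.maize_height_range)
            plants[q].append(_make_plant(rng, "maize", h, (u, v), with_colors, color_rng))

    for q in range(4):
        weed_class = config.quadrat_weed_classes[q]
        if weed_class == "none":
            n_weeds, kinds, positions = 0, [], []
        else:
            lo, hi = config.weed_density_range
            n_weeds = int(rng.integers(lo, hi + 1))
            n_weeds = max(n_weeds, 2 if weed_class == "mixture" else 1)
            kinds = _weed_kinds(rng, weed_class, n_weeds)
            positions = _place_weeds(
                rng, q, side, kinds, maize_centers_all.get(q, np.zeros((0, 2)))
            )
        for kind, pos in zip(kinds, positions):
            rng_range = (
                config.grass_height_range if kind == "grass" else config.broadleaf_height_range
            )
            h = rng.uniform(*rng_range)
            plants[q].append(_make_plant(rng, kind, h, pos, with_colors, color_rng))

        qp = plants[q]
        maize_v = sum(p.volume for p in qp if p.kind == "maize")
        weed_v = sum(p.volume for p in qp if p.kind != "maize")
        n_maize_q = sum(1 for p in qp if p.kind == "maize")
        eps_m = float(rng.normal(0.0, config.biomass_noise_sd_maize)) if maize_v > 0 else 0.0
        eps_w = float(rng.normal(0.0, config.biomass_noise_sd_weed)) if weed_v > 0 else 0.0
        eps_m, eps_w = max(eps_m, -1.0), max(eps_w, -1.0)
        weed_z = (
            np.concatenate([p.verts[:, 2] for p in qp if p.kind != "maize"])
            if weed_v > 0
            else None
        )
        truths.append(
            QuadratTruth(
                quadrat_index=q,
                position_label="row" if q in row_quadrats else "inter_row",
                weed_class=weed_class,
                maize_count=n_maize_q,
                weed_density=n_weeds,
                true_maize_volume=maize_v,
                true_weed_volume=weed_v,
                maize_biomass=config.maize_density_factor * maize_v * (1 + eps_m),
                weed_biomass=config.weed_density_factor * weed_v * (1 + eps_w),
                biomass_eps_maize=eps_m,
                biomass_eps_weed=eps_w,
                plant_heights=[(p.kind, p.height) for p in qp],
                weed_max_height=float(weed_z.max()) if weed_z is not None else None,
                weed_p90_height=float(np.percentile(weed_z, 90)) if weed_z is not None else None,
            )
        )
    return plants, truths


# ---------------------------------------------------------------------------
# soil, frame, and scene assembly


def _soil_grid(rng: np.random.Generator, config: SceneConfig):
    side = config.frame_side
    lo, hi = -config.scene_margin, side + config.scene_margin
    n = int(round((hi - lo) / config.point_spacing)) + 1
    xs = np.linspace(lo, hi, n)
    ys = np.linspace(lo, hi, n)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")

    # fractal-ish microrelief: cubic upsampling of coarse noise + fine grain
    nc = 24
    coarse = rng.normal(size=(nc, nc))
    ci = np.linspace(lo, hi, nc)
    interp = RegularGridInterpolator((ci, ci), coarse, method="cubic")
    z = interp(np.column_stack([gx.ravel(), gy.ravel()])).reshape(n, n)
    peak = np.abs(z).max()
    if peak > 0:
        z *= config.soil_relief_amplitude / peak
    z += rng.normal(0.0, 0.0008, size=z.shape)

    # white frame band: flush with the leveled ground, inside the outer edge
    inside = (gx >= 0) & (gx <= side) & (gy >= 0) & (gy <= side)
    edge_dist = np.minimum(np.minimum(gx, side - gx), np.minimum(gy, side - gy))
    band = inside & (edge_dist <= config.frame_band_width)
    z[band] = 0.0

    verts = np.column_stack([gx.ravel(), gy.ravel(), z.ravel()])
    # soil color: correlated (lightness-only) texture keeps ExG near zero
    f = np.clip(rng.normal(1.0, 0.10, size=len(verts)), 0.6, 1.4)
    colors = np.clip(np.array([128.0, 98.0, 66.0])[None, :] * f[:, None], 0, 255)
    fw = np.clip(rng.normal(1.0, 0.02, size=len(verts)), 0.9, 1.05)
    white = np.clip(np.array([246.0, 246.0, 246.0])[None, :] * fw[:, None], 0, 255)
    bflat = band.ravel()
    colors[bflat] = white[bflat]
    colors = colors.astype(np.uint8)

    ii, jj = np.meshgrid(np.arange(n - 1), np.arange(n - 1), indexing="ij")
    v00 = (ii * n + jj).ravel()
    v10 = ((ii + 1) * n + jj).ravel()
    v01 = (ii * n + jj + 1).ravel()
    v11 = ((ii + 1) * n + jj + 1).ravel()
    faces = np.vstack(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])]
    )
    frame_vertex = bflat
    face_is_frame = frame_vertex[faces].any(axis=1)
    labels = np.where(face_is_frame, FACE_FRAME, FACE_SOIL)
    return verts, faces, colors, labels


def _true_frame_pose(config: SceneConfig) -> FramePose:
    s = config.frame_side
    corners = np.array([[0, 0, 0], [s, 0, 0], [s, s, 0], [0, s, 0]], dtype=np.float64)
    corners = _apply_world_transform(corners, config)
    corners = _canonical_corners(corners)
    return FramePose(corners, Plane(np.array([0.0, 0.0, 1.0]), 0.0), s, 0.0)


def _apply_world_transform(points: np.ndarray, config: SceneConfig) -> np.ndarray:
    a = math.radians(config.frame_rotation_deg)
    if a == 0.0 and config.frame_origin == (0.0, 0.0):
        return points
    c, s = math.cos(a), math.sin(a)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    out = points @ rot.T
    out[:, 0] += config.frame_origin[0]
    out[:, 1] += config.frame_origin[1]
    return out


def generate_scene(config: SceneConfig) -> tuple[TriMesh, FramePose, GroundTruth]:
    """One complete synthetic frame scene with exact ground truth.

    Deterministic per seed: the same config yields byte-identical output.
    Sensor noise (vertical depth jitter, isolated outliers, face dropout)
    is applied according to the config; set the noise fields to zero (see
    :func:`noiseless`) for pristine scenes.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_plants, rng_soil, rng_sensor = (np.random.default_rng(s) for s in ss.spawn(3))

    plants, truths = _sample_scene_truth(rng_plants, config, with_colors=True)
    sv, sf, sc, slabels = _soil_grid(rng_soil, config)

    verts = [sv]
    faces = [sf]
    colors = [sc]
    labels = [slabels]
    offset = len(sv)
    for q in range(4):
        for p in plants[q]:
            verts.append(p.verts)
            faces.append(p.faces + offset)
            colors.append(p.colors)
            labels.append(
                np.full(len(p.faces), FACE_MAIZE if p.kind == "maize" else FACE_WEED)
            )
            offset += len(p.verts)
    vertices = np.vstack(verts)
    all_faces = np.vstack(faces)
    all_colors = np.vstack(colors).astype(np.float64)
    face_labels = np.concatenate(labels).astype(np.int64)

    if config.color_noise_sd > 0:
        all_colors = all_colors + rng_sensor.normal(0, config.color_noise_sd, all_colors.shape)
    all_colors = np.clip(all_colors, 0, 255).astype(np.uint8)

    vertices = _apply_world_transform(vertices, config)
    mesh = TriMesh(vertices, all_faces, all_colors)
    if config.depth_noise_sd > 0 or config.outlier_fraction > 0 or config.dropout_fraction > 0:
        noise_seed = int(rng_sensor.integers(0, 2**31 - 1))
        mesh, kept = add_sensor_noise(
            mesh,
            config.depth_noise_sd,
            config.outlier_fraction,
            config.dropout_fraction,
            noise_seed,
            return_kept_faces=True,
        )
        face_labels = face_labels[kept]
    frame = _true_frame_pose(config)
    truth = GroundTruth(face_labels, truths, frame, config, config.seed)
    return mesh, frame, truth


def add_sensor_noise(
    mesh: TriMesh,
    depth_noise_sd: float = 0.003,
    outlier_fraction: float = 0.01,
    dropout_fraction: float = 0.0,
    seed: int = 0,
    return_kept_faces: bool = False,
):
    """Depth-camera degradation: vertical jitter, flying pixels, dropout.

    Vertex positions are jittered along the (vertical) view axis; isolated
    outlier vertices are injected at least 2 cm from every surface vertex
    and from each other, appended *after* all surface vertices; a random
    face fraction is dropped.  Deterministic per seed; zero settings
    return an identical copy.
    """
    if not 0 <= outlier_fraction < 1 or not 0 <= dropout_fraction < 1:
        raise ValueError("fractions must be in [0, 1)")
    rng = np.random.default_rng(seed)
    verts = mesh.vertices.copy()
    if depth_noise_sd > 0:
        verts[:, 2] += rng.normal(0, depth_noise_sd, len(verts))
    faces = mesh.faces
    kept = np.arange(len(faces))
    if dropout_fraction > 0 and len(faces):
        keep = rng.random(len(faces)) >= dropout_fraction
        kept = np.flatnonzero(keep)
        faces = faces[keep]
    colors = mesh.vertex_colors.copy() if mesh.vertex_colors is not None else None

    n_out = int(round(outlier_fraction * len(verts)))
    if n_out > 0:
        tree = cKDTree(verts)
        lo = verts.min(axis=0) - 0.05
        hi = verts.max(axis=0) + np.array([0.05, 0.05, 0.30])
        accepted: list[np.ndarray] = []
        for _ in range(40):
            if len(accepted) >= n_out:
                break
            cand = rng.uniform(lo, hi, size=(4 * n_out, 3))
            d, _ = tree.query(cand, k=1)
            cand = cand[d >= 0.02]
            for p in cand:
                if len(accepted) >= n_out:
                    break
                if accepted and np.min(
                    np.linalg.norm(np.asarray(accepted) - p, axis=1)
                ) < 0.02:
                    continue
                accepted.append(p)
        out_pts = np.asarray(accepted).reshape(-1, 3)
        verts = np.vstack([verts, out_pts])
        if colors is not None:
            grey = np.clip(
                rng.normal(180, 20, size=(len(out_pts), 3)), 0, 255
            ).astype(np.uint8)
            colors = np.vstack([colors, grey])
    out = TriMesh(verts, faces, colors, mesh.face_ids[kept])
    if return_kept_faces:
        return out, kept
    return out


# ---------------------------------------------------------------------------
# whole-study generation


@dataclass(frozen=True)
class StudyConfig:
    """Layout of a full sampling campaign: frames, composition, correlations.

    Forty quadrats (ten 1 m frames), half on the crop row and half
    inter-row; the composition mix makes weed-free, grass-only,
    broadleaf-only and mixed quadrats explicit.  ``target_r_*`` are the
    population Pearson correlations between true volume and simulated dry
    biomass; the generator back-solves the multiplicative noise sigma
    from the volume distribution's moments.
    """

    n_frames: int = 10
    n_weed_free: int = 8
    n_grass_only: int = 11
    n_broadleaf_only: int = 11
    n_mixed: int = 10
    target_r_weed: float = 0.83
    target_r_maize: float = 0.77
    scene: SceneConfig = field(default_factory=SceneConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.n_weed_free + self.n_grass_only + self.n_broadleaf_only + self.n_mixed
        if total != 4 * self.n_frames:
            raise ValueError("quadrat composition counts must sum to 4 * n_frames")
        for r in (self.target_r_weed, self.target_r_maize):
            if not 0 < r <= 1:
                raise ValueError("target correlations must be in (0, 1]")


def _moments_key(config: StudyConfig) -> tuple:
    s = config.scene
    return (
        config.n_frames,
        config.n_weed_free,
        config.n_grass_only,
        config.n_broadleaf_only,
        config.n_mixed,
        s.n_maize,
        s.maize_height_range,
        s.grass_height_range,
        s.broadleaf_height_range,
        s.weed_density_range,
    )


@lru_cache(maxsize=8)
def _volume_moments(key: tuple) -> dict:
    """Monte-Carlo moments of per-quadrat true volumes under a composition mix.

    Uses a fixed internal seed: the moments characterize the population,
    not any particular study realization.
    """
    (
        n_frames,
        n_free,
        n_grass,
        n_broad,
        n_mixed,
        n_maize,
        maize_hr,
        grass_hr,
        broad_hr,
        dens_rng,
    ) = key
    total = 4 * n_frames
    probs = np.array([n_free, n_grass, n_broad, n_mixed], dtype=np.float64) / total
    classes = np.array(["none", "monocots", "dicots", "mixture"])
    rng = np.random.default_rng(123456789)
    nsim = 1500
    weed_v = np.zeros(nsim)
    maize_v = np.zeros(nsim)
    per_row = n_maize - n_maize // 2
    for i in range(nsim):
        wc = classes[rng.choice(4, p=probs)]
        if wc != "none":
            lo, hi = dens_rng
            nw = int(rng.integers(lo, hi + 1))
            nw = max(nw, 2 if wc == "mixture" else 1)
            kinds = _weed_kinds(rng, str(wc), nw)
            v = 0.0
            for kind in kinds:
                hr = grass_hr if kind == "grass" else broad_hr
                h = rng.uniform(*hr)
                v += _make_plant(rng, kind, h, (0.25, 0.25), with_colors=False).volume
            weed_v[i] = v
        if rng.random() < 0.5:  # row quadrat
            v = 0.0
            for _ in range(per_row):
                h = rng.uniform(*maize_hr)
                v += _make_plant(rng, "maize", h, (0.25, 0.25), with_colors=False).volume
            maize_v[i] = v
    return {
        "weed_var": float(weed_v.var()),
        "weed_m2": float((weed_v**2).mean()),
        "weed_mean": float(weed_v.mean()),
        "maize_var": float(maize_v.var()),
        "maize_m2": float((maize_v**2).mean()),
        "maize_mean": float(maize_v.mean()),
    }


def _clipped_eps_moments(sigma: float) -> tuple[float, float]:
    """First two moments of max(N(0, sigma), -1) (biomass cannot go negative)."""
    from scipy.stats import norm

    if sigma == 0:
        return 0.0, 0.0
    c = 1.0 / sigma
    phi, Phi_mc = norm.pdf(c), norm.cdf(-c)
    m1 = sigma * phi - Phi_mc
    m2 = sigma**2 * (norm.cdf(c) - c * phi) + Phi_mc
    return float(m1), float(m2)


def _population_r(sigma: float, var: float, m2: float, mean: float) -> float:
    """corr(V, a V (1 + eps_clipped)) with eps ~ N(0, sigma) clipped at -1."""
    e1, e2 = _clipped_eps_moments(sigma)
    cov = var * (1.0 + e1)
    var_b = m2 * (1.0 + 2 * e1 + e2) - mean**2 * (1.0 + e1) ** 2
    return cov / math.sqrt(var * var_b)


def _sigma_for_target_r(target_r: float, var: float, m2: float, mean: float) -> float:
    """Back-solve the multiplicative-noise sigma for a population correlation.

    With B = a V (1 + eps), eps ~ N(0, sigma) truncated below at -1, the
    correlation is a monotone decreasing function of sigma; invert it
    numerically.
    """
    if target_r >= 1.0 or m2 <= 0 or var <= 0:
        return 0.0
    from scipy.optimize import brentq

    lo, hi = 1e-9, 1.0
    while _population_r(hi, var, m2, mean) > target_r and hi < 64:
        hi *= 2
    return float(brentq(lambda s: _population_r(s, var, m2, mean) - target_r, lo, hi))


def biomass_noise_sigmas(config: StudyConfig) -> tuple[float, float]:
    """(sigma_maize, sigma_weed) realizing the config's target correlations."""
    if config.target_r_maize >= 1.0 and config.target_r_weed >= 1.0:
        return 0.0, 0.0  # exact proportionality needs no moment calibration
    mom = _volume_moments(_moments_key(config))
    sm = _sigma_for_target_r(
        config.target_r_maize, mom["maize_var"], mom["maize_m2"], mom["maize_mean"]
    )
    sw = _sigma_for_target_r(
        config.target_r_weed, mom["weed_var"], mom["weed_m2"], mom["weed_mean"]
    )
    return sm, sw


def generate_study(config: StudyConfig = StudyConfig(), meshes: bool = False) -> Study:
    """Simulate a whole sampling campaign.

    With ``meshes=False`` (default) only the exact ground-truth records
    are produced — cheap enough for replicated statistical experiments.
    With ``meshes=True`` every frame scene is generated in full for
    end-to-end pipeline runs; the truth records are identical in both
    modes for the same seed.
    """
    sigma_m, sigma_w = biomass_noise_sigmas(config)
    ss = np.random.SeedSequence(config.seed)
    shuffle_rng = np.random.default_rng(ss.spawn(1)[0])
    classes = (
        ["none"] * config.n_weed_free
        + ["monocots"] * config.n_grass_only
        + ["dicots"] * config.n_broadleaf_only
        + ["mixture"] * config.n_mixed
    )
    order = shuffle_rng.permutation(len(classes))
    classes = [classes[i] for i in order]

    records = []
    scenes = [] if meshes else None
    frame_seeds = shuffle_rng.integers(0, 2**31 - 1, size=config.n_frames)
    for fi in range(config.n_frames):
        quad_classes = tuple(classes[4 * fi : 4 * fi + 4])
        cfg = replace(
            config.scene,
            quadrat_weed_classes=quad_classes,
            biomass_noise_sd_maize=sigma_m,
            biomass_noise_sd_weed=sigma_w,
            seed=int(frame_seeds[fi]),
        )
        if meshes:
            scene = generate_scene(cfg)
            truths = scene[2].quadrats
            scenes.append(scene)
        else:
            ss_f = np.random.SeedSequence(cfg.seed)
            rng_plants = np.random.default_rng(ss_f.spawn(1)[0])
            _, truths = _sample_scene_truth(rng_plants, cfg, with_colors=False)
        for q in truths:
            records.append((fi, q))
    return Study(records=records, config=config, scenes=scenes)
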