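"""Synthetic fixtures: analytic-volume primitives, a piglet-like composite
shape, noise/occlusion corruption, and volume-weight tables.

Every generator is a pure function of its spec and seed. Each sampled
shape carries its ground-truth volume: analytic for the primitives, the
signed tetrahedral volume of the constructive mesh for the composite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from skimage.measure import marching_cubes

from cloudvol.geometry import PointCloud, TriangleMesh
from cloudvol.volume import mesh_volume, orient_faces

__all__ = ["ShapeSpec", "NoiseSpec", "sample_shape", "corrupt", "make_volume_weight_table", "piglet_mesh"]

_KINDS = ("cube", "cylinder", "sphere", "l_prism", "thin_plate", "piglet")


@dataclass(frozen=True)
class ShapeSpec:
    """Parametric synthetic shape with retrievable ground-truth volume.

    density is points per unit area of surface; normals attached to the
    samples point *inward* (the pipeline's global convention).
    """

    kind: str = "cube"
    side: float = 1.0  # cube and l_prism outer side
    radius: float = 1.0  # cylinder / sphere
    height: float = 1.0  # cylinder / l_prism extrusion
    notch: float = 0.5  # l_prism removed corner side
    separation: float = 0.05  # thin_plate sheet gap
    spacing: float = 0.02  # thin_plate in-sheet grid spacing
    density: float = 1.0e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r} (expected one of {_KINDS})")
        for name in ("side", "radius", "height", "notch", "separation", "spacing", "density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kind == "l_prism" and self.notch >= self.side:
            raise ValueError("l_prism notch must be smaller than the side")


@dataclass(frozen=True)
class NoiseSpec:
    """Corruption model: normal-direction jitter, burr outliers, occlusion."""

    sigma: float = 0.0
    outlier_fraction: float = 0.0
    outlier_scale: float = 0.1
    occlusion: Callable[[np.ndarray], np.ndarray] | None = None  # mask of points to drop

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction must lie in [0, 1)")


def sample_shape(spec: ShapeSpec) -> tuple[PointCloud, float]:
    """Seeded stratified surface sampling; returns (cloud, true volume)."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "cube":
        return _sample_cube(spec, rng)
    if spec.kind == "cylinder":
        return _sample_cylinder(spec, rng)
    if spec.kind == "sphere":
        return _sample_sphere(spec, rng)
    if spec.kind == "l_prism":
        return _sample_l_prism(spec, rng)
    if spec.kind == "thin_plate":
        return _sample_thin_plate(spec)
    return _sample_piglet(spec, rng)


# ---------------------------------------------------------------------------
# primitives (inward normals throughout)


def _jittered_grid(n_u: int, n_v: int, rng: np.random.Generator) -> np.ndarray:
    """One uniform point per cell of an n_u x n_v unit-square grid."""
    iu, iv = np.meshgrid(np.arange(n_u), np.arange(n_v), indexing="ij")
    u = (iu.ravel() + rng.random(n_u * n_v)) / n_u
    v = (iv.ravel() + rng.random(n_u * n_v)) / n_v
    return np.column_stack([u, v])


def _sample_cube(spec: ShapeSpec, rng) -> tuple[PointCloud, float]:
    s = spec.side
    n = max(1, round(s * np.sqrt(spec.density)))
    pts, nrm = [], []
    for axis in range(3):
        for side_val, sign in ((0.0, 1.0), (s, -1.0)):  # inward normal
            uv = _jittered_grid(n, n, rng) * s
            p = np.zeros((len(uv), 3))
            other = [i for i in range(3) if i != axis]
            p[:, other[0]] = uv[:, 0]
            p[:, other[1]] = uv[:, 1]
            p[:, axis] = side_val
            normal = np.zeros(3)
            normal[axis] = sign
            pts.append(p)
            nrm.append(np.tile(normal, (len(p), 1)))
    cloud = PointCloud(np.vstack(pts), np.vstack(nrm))
    return cloud, s**3


def _sample_cylinder(spec: ShapeSpec, rng) -> tuple[PointCloud, float]:
    r, h = spec.radius, spec.height
    # lateral wall
    circ = 2 * np.pi * r
    n_t = max(3, round(circ * np.sqrt(spec.density)))
    n_z = max(1, round(h * np.sqrt(spec.density)))
    uv = _jittered_grid(n_t, n_z, rng)
    theta = uv[:, 0] * 2 * np.pi
    z = uv[:, 1] * h
    wall = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    wall_n = np.column_stack([-np.cos(theta), -np.sin(theta), np.zeros_like(theta)])
    pts, nrm = [wall], [wall_n]
    # caps: stratified in (r^2, theta) for area uniformity
    n_cap = max(4, round(np.pi * r * r * spec.density))
    n_ring = max(2, round(np.sqrt(n_cap / np.pi)))
    n_ang = max(3, n_cap // n_ring)
    for z_val, sign in ((0.0, 1.0), (h, -1.0)):
        uv = _jittered_grid(n_ring, n_ang, rng)
        rad = r * np.sqrt(uv[:, 0])
        ang = uv[:, 1] * 2 * np.pi
        cap = np.column_stack([rad * np.cos(ang), rad * np.sin(ang), np.full(len(uv), z_val)])
        pts.append(cap)
        nrm.append(np.tile([0.0, 0.0, sign], (len(cap), 1)))
    cloud = PointCloud(np.vstack(pts), np.vstack(nrm))
    return cloud, np.pi * r * r * h


def _sample_sphere(spec: ShapeSpec, rng) -> tuple[PointCloud, float]:
    r = spec.radius
    n_total = max(8, round(4 * np.pi * r * r * spec.density))
    n_z = max(2, round(np.sqrt(n_total / 2)))
    n_t = max(3, n_total // n_z)
    uv = _jittered_grid(n_z, n_t, rng)
    z = 2.0 * uv[:, 0] - 1.0  # area-uniform in z
    theta = uv[:, 1] * 2 * np.pi
    rho = np.sqrt(np.clip(1 - z * z, 0.0, None))
    unit = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    cloud = PointCloud(r * unit, -unit)
    return cloud, 4.0 / 3.0 * np.pi * r**3


def _rect_patch(origin, e_u, e_v, len_u, len_v, normal, density, rng):
    n_u = max(1, round(len_u * np.sqrt(density)))
    n_v = max(1, round(len_v * np.sqrt(density)))
    uv = _jittered_grid(n_u, n_v, rng)
    p = (
        np.asarray(origin)
        + uv[:, :1] * len_u * np.asarray(e_u)
        + uv[:, 1:] * len_v * np.asarray(e_v)
    )
    return p, np.tile(np.asarray(normal, dtype=np.float64), (len(p), 1))


def _sample_l_prism(spec: ShapeSpec, rng) -> tuple[PointCloud, float]:
    """L cross-section: [0,A]x[0,A] minus the [A-B,A]x[A-B,A] corner,
    extruded to height H along z."""
    A, B, H = spec.side, spec.notch, spec.height
    d = spec.density
    ex, ey, ez = np.eye(3)
    patches = [
        # outer walls (inward normals)
        _rect_patch((0, 0, 0), ey, ez, A, H, (1, 0, 0), d, rng),  # x=0
        _rect_patch((0, 0, 0), ex, ez, A, H, (0, 1, 0), d, rng),  # y=0
        _rect_patch((A, 0, 0), ey, ez, A - B, H, (-1, 0, 0), d, rng),  # x=A, y<A-B
        _rect_patch((0, A, 0), ex, ez, A - B, H, (0, -1, 0), d, rng),  # y=A, x<A-B
        # notch walls
        _rect_patch((A - B, A - B, 0), ey, ez, B, H, (-1, 0, 0), d, rng),  # x=A-B
        _rect_patch((A - B, A - B, 0), ex, ez, B, H, (0, -1, 0), d, rng),  # y=A-B
    ]
    # top and bottom L faces: two rectangles each
    for z_val, sign in ((0.0, 1.0), (H, -1.0)):
        patches.append(_rect_patch((0, 0, z_val), ex, ey, A, A - B, (0, 0, sign), d, rng))
        patches.append(_rect_patch((0, A - B, z_val), ex, ey, A - B, B, (0, 0, sign), d, rng))
    pts = np.vstack([p for p, _ in patches])
    nrm = np.vstack([n for _, n in patches])
    return PointCloud(pts, nrm), (A * A - B * B) * H


def _sample_thin_plate(spec: ShapeSpec) -> tuple[PointCloud, float]:
    """Two parallel square sheets (regular grids) a small gap apart.

    An orientation stress fixture; the nominal volume is the enclosed
    slab: side^2 * separation.
    """
    s, gap, dx = spec.side, spec.separation, spec.spacing
    n = max(2, int(round(s / dx)) + 1)
    ax = np.linspace(0.0, s, n)
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    sheet = np.column_stack([gx.ravel(), gy.ravel()])
    top = np.column_stack([sheet, np.full(len(sheet), gap)])
    bottom = np.column_stack([sheet, np.zeros(len(sheet))])
    pts = np.vstack([top, bottom])
    nrm = np.vstack(
        [
            np.tile([0.0, 0.0, -1.0], (len(top), 1)),  # inward: toward the slab
            np.tile([0.0, 0.0, 1.0], (len(bottom), 1)),
        ]
    )
    return PointCloud(pts, nrm), s * s * gap


# ---------------------------------------------------------------------------
# piglet composite


def _piglet_implicit(p: np.ndarray) -> np.ndarray:
    """Inside-negative implicit function of the composite body.

    Union (pointwise min) of: ellipsoid torso, ellipsoid head, four
    capsule legs with hemispherical feet. Dimensions in metres; the
    resulting body is roughly 0.7 m long.
    """

    def ellipsoid(center, axes):
        q = (p - center) / axes
        return np.einsum("ij,ij->i", q, q) - 1.0

    def leg(cx, cy, r=0.035, z0=0.035, z1=0.30):
        dz = np.clip(p[:, 2], z0, z1)
        d = p - np.column_stack([np.full(len(p), cx), np.full(len(p), cy), dz])
        return np.linalg.norm(d, axis=1) - r

    parts = [
        ellipsoid(np.array([0.0, 0.0, 0.30]), np.array([0.30, 0.12, 0.13])),
        ellipsoid(np.array([0.34, 0.0, 0.34]), np.array([0.11, 0.08, 0.09])),
        leg(-0.18, -0.07),
        leg(-0.18, 0.07),
        leg(0.18, -0.07),
        leg(0.18, 0.07),
    ]
    return np.min(parts, axis=0)


_PIGLET_CACHE: dict[int, TriangleMesh] = {}


def piglet_mesh(resolution: int = 160) -> TriangleMesh:
    """Constructive mesh of the composite piglet (marching cubes of the
    implicit union); this mesh is the shape's ground truth."""
    if resolution in _PIGLET_CACHE:
        return _PIGLET_CACHE[resolution].copy()
    lo = np.array([-0.34, -0.17, -0.01])
    hi = np.array([0.50, 0.17, 0.48])
    axes = [np.linspace(lo[i], hi[i], resolution) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    vals = _piglet_implicit(grid).reshape(resolution, resolution, resolution)
    spacing = (hi - lo) / (resolution - 1)
    verts, faces, _n, _v = marching_cubes(vals, level=0.0, spacing=tuple(spacing))
    mesh = orient_faces(TriangleMesh(verts + lo, faces.astype(np.int64)))
    _PIGLET_CACHE[resolution] = mesh
    return mesh.copy()


def _sample_piglet(spec: ShapeSpec, rng) -> tuple[PointCloud, float]:
    mesh = piglet_mesh()
    truth = mesh_volume(mesh).volume
    v0 = mesh.vertices[mesh.faces[:, 0]]
    v1 = mesh.vertices[mesh.faces[:, 1]]
    v2 = mesh.vertices[mesh.faces[:, 2]]
    cross = np.cross(v1 - v0, v2 - v0)
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    total_area = areas.sum()
    n_pts = max(16, round(total_area * spec.density))
    # stratified by face: systematic sampling over the cumulative area
    cum = np.cumsum(areas) / total_area
    u = (np.arange(n_pts) + rng.random(n_pts)) / n_pts
    face_idx = np.searchsorted(cum, u)
    r1 = np.sqrt(rng.random(n_pts))
    r2 = rng.random(n_pts)
    a = 1.0 - r1
    b = r1 * (1.0 - r2)
    c = r1 * r2
    pts = (
        a[:, None] * v0[face_idx] + b[:, None] * v1[face_idx] + c[:, None] * v2[face_idx]
    )
    fn = cross[face_idx]
    fn /= np.linalg.norm(fn, axis=1)[:, None]
    # mesh faces are outward (positive signed volume); flip to inward
    return PointCloud(pts, -fn), truth


# ---------------------------------------------------------------------------
# corruption and regression tables


def corrupt(cloud: PointCloud, noise: NoiseSpec, seed: int = 0) -> PointCloud:
    """Apply seeded jitter / burr outliers / occlusion to a cloud.

    Gaussian displacement acts along the per-point normals; a
    round(fraction * n) subset is pushed out by ``outlier_scale`` to form
    burrs; the occlusion predicate deletes the points it selects.
    """
    rng = np.random.default_rng(seed)
    pts = cloud.points.copy()
    normals = cloud.normals
    if (noise.sigma > 0 or noise.outlier_fraction > 0) and normals is None:
        from cloudvol.normals import estimate_normals_pca

        normals = estimate_normals_pca(cloud, k=min(20, len(cloud) - 1)).normals
    if noise.sigma > 0:
        pts += normals * rng.normal(0.0, noise.sigma, len(pts))[:, None]
    if noise.outlier_fraction > 0:
        n_out = int(round(noise.outlier_fraction * len(pts)))
        idx = rng.choice(len(pts), size=n_out, replace=False)
        pts[idx] += normals[idx] * noise.outlier_scale * rng.choice([-1.0, 1.0], n_out)[:, None]
    keep = np.ones(len(pts), dtype=bool)
    if noise.occlusion is not None:
        keep = ~np.asarray(noise.occlusion(pts), dtype=bool)
        pts = pts[keep]
    out_normals = cloud.normals[keep].copy() if cloud.normals is not None else None
    conf = cloud.confidence[keep].copy() if cloud.confidence is not None else None
    return PointCloud(pts, out_normals, conf)


def make_volume_weight_table(
    n: int,
    a: float = 1070.4,
    b: float = -1.6524,
    sigma_kg: float = 3.0,
    volume_range: tuple[float, float] = (0.08, 0.125),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded (volume, weight) pairs: weights = a*v + b + N(0, sigma_kg)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    volumes = rng.uniform(volume_range[0], volume_range[1], n)
    weights = a * volumes + b + rng.normal(0.0, sigma_kg, n)
    return volumes, weights
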