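"""Moving-least-squares smoothing of surface point clouds.

Each point is projected onto a weighted-least-squares polynomial height
field fitted over its k-neighborhood in a frame aligned with the
neighborhood's best-fit plane. Weights decay as a Gaussian of distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from cloudvol.geometry import PointCloud, knn

__all__ = ["MlsConfig", "mls_smooth"]

log = logging.getLogger(__name__)

_N_TERMS = {"linear": 3, "quadratic": 6}
# the quadratic fit needs at least as many neighbors as the full 3D
# quadratic basis has terms, with margin for a stable weighted solve
_MIN_K = {"linear": 4, "quadratic": 10}


@dataclass(frozen=True)
class MlsConfig:
    """Parameters of the moving-least-squares projection.

    k : neighborhood size; must be >= 10 for the quadratic basis.
    basis : "linear" or "quadratic" height-field polynomial.
    bandwidth : Gaussian kernel scale as a multiple of the mean neighbor
        distance within each neighborhood.
    """

    k: int = 30
    basis: str = "quadratic"
    bandwidth: float = 2.0

    def __post_init__(self) -> None:
        if self.basis not in _N_TERMS:
            raise ValueError(f"basis must be 'linear' or 'quadratic', got {self.basis!r}")
        if self.k < _MIN_K[self.basis]:
            raise ValueError(
                f"k={self.k} too small for the {self.basis} basis (need >= {_MIN_K[self.basis]})"
            )
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


def mls_smooth(cloud: PointCloud, config: MlsConfig | None = None) -> PointCloud:
    """Project every point onto its local MLS polynomial surface.

    Returns a cloud of the same cardinality; normals and confidence are
    dropped (they are stale after the points move). Rank-deficient local
    fits fall back to projection onto the best-fit plane, with a warning.
    """
    config = config or MlsConfig()
    n = len(cloud)
    if n < config.k + 1:
        raise ValueError(f"cloud has {n} points; need at least k+1={config.k + 1}")

    nbr = knn(cloud, config.k)
    pts = cloud.points
    neigh = pts[nbr.indices]  # (n, k, 3)
    center = neigh.mean(axis=1)  # (n, 3)
    local = neigh - center[:, None, :]

    # batched PCA frame: smallest-eigenvalue direction is the plane normal
    cov = np.einsum("nki,nkj->nij", local, local) / config.k
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    normal = evecs[:, :, 0]
    e1 = evecs[:, :, 2]
    e2 = evecs[:, :, 1]

    # degenerate neighborhoods: plane not even defined
    if np.any(evals[:, 1] <= 1e-30):
        bad = int(np.argmax(evals[:, 1] <= 1e-30))
        raise ValueError(f"neighborhood of point {bad} is degenerate (rank < 2)")

    # local coordinates of neighbors and the query point itself
    u = np.einsum("nkj,nj->nk", local, e1)
    v = np.einsum("nkj,nj->nk", local, e2)
    w = np.einsum("nkj,nj->nk", local, normal)
    d0 = pts - center
    u0 = np.einsum("nj,nj->n", d0, e1)
    v0 = np.einsum("nj,nj->n", d0, e2)

    h = config.bandwidth * nbr.distances.mean(axis=1)  # (n,)
    dist2 = np.einsum("nkj,nkj->nk", local - d0[:, None, :], local - d0[:, None, :])
    wgt = np.exp(-dist2 / np.maximum(h, 1e-300)[:, None] ** 2)

    m = _N_TERMS[config.basis]
    basis = _design(u, v, m)  # (n, k, m)
    basis0 = _design(u0[:, None], v0[:, None], m)[:, 0, :]  # (n, m)

    bw = basis * wgt[:, None, :].transpose(0, 2, 1)
    A = np.einsum("nkm,nkl->nml", bw, basis)
    b = np.einsum("nkm,nk->nm", bw, w)

    # ridge-regularized batched solve; detect rank deficiency via the
    # conditioning of the normal matrix
    scale = np.einsum("nmm->n", A) / m
    eye = np.eye(m)
    coef = np.linalg.solve(A + 1e-12 * scale[:, None, None] * eye, b[:, :, None])[:, :, 0]
    resid_ok = np.all(np.isfinite(coef), axis=1)
    cond_bad = ~resid_ok | (np.linalg.cond(A) > 1e12)
    if np.any(cond_bad):
        log.warning(
            "MLS fit rank-deficient at %d point(s); falling back to plane projection",
            int(cond_bad.sum()),
        )
        coef[cond_bad] = 0.0  # height 0 == best-fit plane

    w_fit = np.einsum("nm,nm->n", basis0, coef)
    new_pts = center + u0[:, None] * e1 + v0[:, None] * e2 + w_fit[:, None] * normal

    # guard: never move a point farther than its neighborhood radius
    radius = nbr.distances[:, -1]
    disp = new_pts - pts
    mag = np.linalg.norm(disp, axis=1)
    over = mag > radius
    if np.any(over):
        new_pts[over] = pts[over] + disp[over] * (radius[over] / mag[over])[:, None]

    return PointCloud(new_pts)


def _design(u: np.ndarray, v: np.ndarray, m: int) -> np.ndarray:
    cols = [np.ones_like(u), u, v]
    if m == 6:
        cols += [u * u, u * v, v * v]
    return np.stack(cols, axis=-1)
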