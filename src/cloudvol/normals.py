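"""Normal estimation by local PCA and global sign orientation.

Unoriented normals come from the smallest-eigenvalue direction of the
local covariance. Signs are made globally consistent by propagating along
a maximum spanning tree of the symmetrized KNN graph; edge weights reward
agreeing normal directions, optionally after projecting out the edge
direction (tangency correction) so thin plates and sharp features do not
leak wrong signs across nearby-but-unrelated sheets.

The adopted global convention is *inward*: at the seed (the point with
maximal z) the normal is forced to point against +z, into the shape.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

from cloudvol.geometry import PointCloud, knn

__all__ = ["OrientationGraph", "estimate_normals_pca", "orient_normals_mst"]

log = logging.getLogger(__name__)


@dataclass
class OrientationGraph:
    """Symmetrized KNN graph with orientation-affinity edge weights."""

    n_vertices: int
    edges: np.ndarray  # (m, 2) int, i < j
    weights: np.ndarray  # (m,) float


def estimate_normals_pca(cloud: PointCloud, k: int = 20) -> PointCloud:
    """Per-point unoriented unit normals from local covariance analysis.

    The normal at each point is the unit eigenvector of C = (1/k) X^T X
    (X = neighbor offsets from the query point) with the smallest
    eigenvalue; its sign is arbitrary at this stage.
    """
    if k < 3:
        raise ValueError("k must be >= 3 for a stable plane fit")
    nbr = knn(cloud, k)
    pts = cloud.points
    offsets = pts[nbr.indices] - pts[:, None, :]  # (n, k, 3)
    cov = np.einsum("nki,nkj->nij", offsets, offsets) / k
    tr = np.einsum("nii->n", cov)
    if np.any(tr <= 1e-300):
        bad = int(np.argmax(tr <= 1e-300))
        raise ValueError(f"coincident neighborhood at point {bad}: zero covariance")
    _evals, evecs = np.linalg.eigh(cov)
    normals = evecs[:, :, 0]
    normals /= np.linalg.norm(normals, axis=1)[:, None]
    return PointCloud(pts.copy(), normals, cloud.confidence)


def build_orientation_graph(
    cloud: PointCloud, k: int, mode: str = "tangency"
) -> OrientationGraph:
    """Edge weights E(i,j) = psi(i,j) * omega(|xi-xj|) on the KNN graph.

    psi is the absolute normal affinity: |<ni, nj>| in ``distance`` mode;
    in ``tangency`` mode the lower-index endpoint's normal is first
    stripped of its component along the edge direction. omega is a
    Gaussian of edge length with scale = mean k-NN distance.
    """
    if mode not in ("distance", "tangency"):
        raise ValueError(f"mode must be 'distance' or 'tangency', got {mode!r}")
    if cloud.normals is None:
        raise ValueError("cloud must carry normals")
    nbr = knn(cloud, k)
    n = len(cloud)
    src = np.repeat(np.arange(n), k)
    dst = nbr.indices.ravel()
    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    pairs = np.unique(np.column_stack([lo, hi]), axis=0)

    pts, nrm = cloud.points, cloud.normals
    i, j = pairs[:, 0], pairs[:, 1]
    dvec = pts[i] - pts[j]
    dlen = np.linalg.norm(dvec, axis=1)
    h = nbr.distances.mean()
    omega = np.exp(-((dlen / max(h, 1e-300)) ** 2))

    ni = nrm[i]
    if mode == "tangency":
        with np.errstate(invalid="ignore"):
            e = dvec / np.where(dlen > 0, dlen, 1.0)[:, None]
        ni = ni - e * np.einsum("mj,mj->m", e, ni)[:, None]
    psi = np.abs(np.einsum("mj,mj->m", ni, nrm[j]))
    return OrientationGraph(n_vertices=n, edges=pairs, weights=psi * omega)


def orient_normals_mst(
    cloud: PointCloud, k: int = 10, mode: str = "tangency"
) -> PointCloud:
    """Globally consistent (inward) normal signs via maximum-spanning-tree
    propagation over the KNN graph.

    Only signs change; normal magnitudes and point positions are
    untouched. Disconnected graphs are oriented per connected component
    with a warning.
    """
    graph = build_orientation_graph(cloud, k, mode)
    n = graph.n_vertices
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    # maximum spanning tree == minimum spanning tree on negated weights;
    # shift keeps entries strictly negative so zero-weight edges survive
    w = -(graph.weights + 1.0)
    adj = coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        log.warning(
            "orientation graph has %d components (sizes %s); orienting each independently",
            n_comp,
            sizes.tolist(),
        )
    mst = minimum_spanning_tree(adj)
    mst = mst + mst.T
    indptr, indices = mst.indptr, mst.indices

    pts = cloud.points
    normals = cloud.normals.copy()
    sign = np.zeros(n, dtype=np.int8)  # 0 = unvisited

    for comp in range(n_comp):
        members = np.nonzero(labels == comp)[0]
        seed = members[np.argmax(pts[members, 2])]
        # seed normal points against +z: inward at the top of the shape
        sign[seed] = -1 if normals[seed, 2] > 0 else 1
        queue = deque([seed])
        while queue:
            p = queue.popleft()
            np_oriented = sign[p] * normals[p]
            for c in indices[indptr[p]:indptr[p + 1]]:
                if sign[c] != 0:
                    continue
                ref = np_oriented
                if mode == "tangency":
                    e = pts[p] - pts[c]
                    elen = np.linalg.norm(e)
                    if elen > 0:
                        e = e / elen
                        ref = ref - e * (e @ ref)
                dot = ref @ normals[c]
                if dot == 0.0:  # degenerate: fall back to raw normal affinity
                    dot = np_oriented @ normals[c]
                # ref already carries the parent's propagated sign
                sign[c] = 1 if dot >= 0 else -1
                if dot == 0.0:
                    sign[c] = sign[p]
                queue.append(c)

    sign[sign == 0] = 1  # isolated vertices keep their sign
    return PointCloud(pts.copy(), normals * sign[:, None].astype(np.float64), cloud.confidence)
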