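"""Independent test oracles: brute-force neighbors, voxelization volume,
icosphere construction. Deliberately simple and separate from package code."""

from __future__ import annotations

import numpy as np

from cloudvol.geometry import TriangleMesh


def brute_force_knn(points: np.ndarray, k: int):
    """O(n^2) exact k-NN with (distance, index) lexicographic tie-break."""
    n = len(points)
    idx = np.empty((n, k), dtype=np.int64)
    dist = np.empty((n, k))
    for i in range(n):
        d = np.linalg.norm(points - points[i], axis=1)
        order = np.lexsort((np.arange(n), d))
        order = order[order != i][:k]
        idx[i] = order
        dist[i] = d[order]
    return idx, dist


def voxel_volume_oracle(mesh: TriangleMesh, resolution: int = 256) -> float:
    """Volume by counting voxel centers inside the mesh.

    Even-odd parity of ray-triangle crossings along z for every (x, y)
    voxel column; the grid is a cube over the padded bounding box with an
    irrational phase offset so rays avoid edge-exact hits.
    """
    verts, faces = mesh.vertices, mesh.faces
    lo = verts.min(axis=0)
    hi = verts.max(axis=0)
    span = float((hi - lo).max()) * 1.05
    lo = (lo + hi) / 2 - span / 2 + span * 1.3e-4 * np.sqrt(2.0)  # phase offset
    h = span / resolution

    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    det = (v1[:, 0] - v0[:, 0]) * (v2[:, 1] - v0[:, 1]) - (v2[:, 0] - v0[:, 0]) * (
        v1[:, 1] - v0[:, 1]
    )
    ok = np.abs(det) > 1e-14  # drop z-vertical triangles (measure-zero hits)
    v0, v1, v2, det = v0[ok], v1[ok], v2[ok], det[ok]

    # candidate columns per triangle from its projected bounding box
    txmin = np.minimum.reduce([v0[:, 0], v1[:, 0], v2[:, 0]])
    txmax = np.maximum.reduce([v0[:, 0], v1[:, 0], v2[:, 0]])
    tymin = np.minimum.reduce([v0[:, 1], v1[:, 1], v2[:, 1]])
    tymax = np.maximum.reduce([v0[:, 1], v1[:, 1], v2[:, 1]])
    ix0 = np.ceil((txmin - lo[0]) / h - 0.5).astype(np.int64)
    ix1 = np.floor((txmax - lo[0]) / h - 0.5).astype(np.int64)
    iy0 = np.ceil((tymin - lo[1]) / h - 0.5).astype(np.int64)
    iy1 = np.floor((tymax - lo[1]) / h - 0.5).astype(np.int64)
    nx = np.maximum(ix1 - ix0 + 1, 0)
    ny = np.maximum(iy1 - iy0 + 1, 0)
    per_tri = nx * ny
    keep = per_tri > 0
    if not np.any(keep):
        return 0.0
    tri_ids = np.repeat(np.nonzero(keep)[0], per_tri[keep])
    # local (dx, dy) cell offsets within each triangle's bbox
    offsets = np.concatenate([np.arange(c) for c in per_tri[keep]])
    dx = offsets // ny[tri_ids]
    dy = offsets % ny[tri_ids]
    ix = ix0[tri_ids] + dx
    iy = iy0[tri_ids] + dy
    cx = lo[0] + (ix + 0.5) * h
    cy = lo[1] + (iy + 0.5) * h

    a0, a1, a2 = v0[tri_ids], v1[tri_ids], v2[tri_ids]
    d = det[tri_ids]
    s = ((cx - a0[:, 0]) * (a2[:, 1] - a0[:, 1]) - (cy - a0[:, 1]) * (a2[:, 0] - a0[:, 0])) / d
    t = ((cy - a0[:, 1]) * (a1[:, 0] - a0[:, 0]) - (cx - a0[:, 0]) * (a1[:, 1] - a0[:, 1])) / d
    hit = (s >= 0) & (t >= 0) & (s + t <= 1)
    if not np.any(hit):
        return 0.0
    zc = a0[:, 2] + s * (a1[:, 2] - a0[:, 2]) + t * (a2[:, 2] - a0[:, 2])
    col = ix * np.int64(resolution) + iy
    col, zc = col[hit], zc[hit]

    order = np.lexsort((zc, col))
    col, zc = col[order], zc[order]
    _uniq, start, counts = np.unique(col, return_index=True, return_counts=True)
    pos = np.arange(len(col)) - np.repeat(start, counts)
    cnt = np.repeat(counts, counts)
    is_start = (pos % 2 == 0) & (pos + 1 < cnt)
    z_lo = zc[is_start]
    z_hi = zc[np.nonzero(is_start)[0] + 1]
    k0 = np.ceil((z_lo - lo[2]) / h - 0.5)
    k1 = np.floor((z_hi - lo[2]) / h - 0.5)
    inside = np.maximum(k1 - k0 + 1, 0).sum()
    return float(inside) * h**3


def icosphere(subdivisions: int = 4, radius: float = 1.0) -> TriangleMesh:
    """Subdivided icosahedron projected to the sphere (outward winding)."""
    phi = (1 + np.sqrt(5)) / 2
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = verts.tolist()
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = np.asarray(verts[i]) + np.asarray(verts[j])
                m /= np.linalg.norm(m)
                cache[key] = len(verts)
                verts.append(m.tolist())
            return cache[key]

        new_faces = []
        for i, j, k in faces:
            a, b, c = midpoint(i, j), midpoint(j, k), midpoint(k, i)
            new_faces += [(i, a, c), (j, b, a), (k, c, b), (a, b, c)]
        faces = new_faces
    return TriangleMesh(np.asarray(verts) * radius, np.asarray(faces, dtype=np.int64))


def unit_cube_mesh() -> TriangleMesh:
    """[0,1]^3 as 8 vertices / 12 consistently outward-wound triangles."""
    v = np.array(
        [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
    )
    # vertex index = 4x + 2y + z
    faces = np.array(
        [
            [0, 1, 3], [0, 3, 2],  # x = 0, outward -x
            [4, 7, 5], [4, 6, 7],  # x = 1, outward +x
            [0, 5, 1], [0, 4, 5],  # y = 0
            [2, 3, 7], [2, 7, 6],  # y = 1
            [0, 2, 6], [0, 6, 4],  # z = 0
            [1, 5, 7], [1, 7, 3],  # z = 1
        ],
        dtype=np.int64,
    )
    return TriangleMesh(v, faces)


def closed_cylinder_mesh(radius=1.0, height=1.0, segments=4096, caps="fan") -> TriangleMesh:
    """Closed cylinder: lateral quads split into triangles plus two caps.

    caps="fan" triangulates each cap as a fan from the axis (matches the
    "cap fans" construction); caps="rings" uses concentric rings, which
    keeps triangles compact for rasterizing oracles.
    """
    theta = 2 * np.pi * np.arange(segments) / segments
    ring_lo = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), np.zeros(segments)])
    ring_hi = ring_lo + [0.0, 0.0, height]
    verts = [ring_lo, ring_hi]
    faces = []
    for i in range(segments):
        j = (i + 1) % segments
        faces += [(i, j, segments + j), (i, segments + j, segments + i)]  # wall, outward
    n_base = 2 * segments
    if caps == "fan":
        verts.append(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, height]]))
        c_lo, c_hi = n_base, n_base + 1
        for i in range(segments):
            j = (i + 1) % segments
            faces.append((c_lo, j, i))  # bottom cap, outward -z
            faces.append((c_hi, segments + i, segments + j))  # top cap, outward +z
        return TriangleMesh(np.vstack(verts), np.asarray(faces, dtype=np.int64))
    # concentric-ring caps
    n_r = max(2, int(round(segments / (2 * np.pi))))
    for z, outward_up, outer_ring in ((0.0, False, np.arange(segments)),
                                      (height, True, segments + np.arange(segments))):
        ring_ids = [outer_ring]
        for k in range(n_r - 1, 0, -1):
            r_k = radius * k / n_r
            pts = np.column_stack(
                [r_k * np.cos(theta), r_k * np.sin(theta), np.full(segments, z)]
            )
            ring_ids.append(n_base + np.arange(segments))
            verts.append(pts)
            n_base += segments
        center = n_base
        verts.append(np.array([[0.0, 0.0, z]]))
        n_base += 1
        for outer, inner in zip(ring_ids[:-1], ring_ids[1:]):
            for i in range(segments):
                j = (i + 1) % segments
                quad = [(outer[i], inner[i], inner[j]), (outer[i], inner[j], outer[j])]
                if not outward_up:
                    quad = [tuple(reversed(t)) for t in quad]
                faces += quad
        inner = ring_ids[-1]
        for i in range(segments):
            j = (i + 1) % segments
            tri = (inner[i], center, inner[j])
            faces.append(tri if outward_up else tuple(reversed(tri)))
    return TriangleMesh(np.vstack(verts), np.asarray(faces, dtype=np.int64))
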