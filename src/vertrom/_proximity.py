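"""Low-level mesh proximity queries.

Vectorized point-to-triangle distance (Ericson's closest-point construction)
and a ray-parity point-in-mesh test.  These primitives back the bone-on-bone
contact detection; they are exact for the query they perform (vertex-to-surface
distance), so the only approximation relative to true surface-to-surface
distance is the mesh discretization itself, which callers account for.

Queries are brute force over point x triangle pairs, chunked to bound memory,
with a KD-tree vertex prescreen that prunes triangles that provably cannot
attain the minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

# point x triangle pairs evaluated per chunk
_CHUNK = 2_000_000

# fixed, axis-avoiding ray direction for the parity test
_RAY_DIR = np.array([0.5773502691896258, 0.5225731858857871, 0.6274950199005566])
_RAY_DIR = _RAY_DIR / np.linalg.norm(_RAY_DIR)


def closest_on_triangles(points: np.ndarray, triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on each triangle to each query point.

    Parameters
    ----------
    points : (n, 3) float array
    triangles : (m, 3, 3) float array

    Returns
    -------
    d2 : (n, m) squared distances
    closest : (n, m, 3) closest points on each triangle
    """
    p = np.asarray(points, dtype=float)[:, None, :]      # (n,1,3)
    a = np.asarray(triangles, dtype=float)[None, :, 0]   # (1,m,3)
    b = np.asarray(triangles, dtype=float)[None, :, 1]
    c = np.asarray(triangles, dtype=float)[None, :, 2]

    ab = b - a
    ac = c - a
    ap = p - a

    d1 = (ab * ap).sum(-1)
    d2_ = (ac * ap).sum(-1)

    bp = p - b
    d3 = (ab * bp).sum(-1)
    d4 = (ac * bp).sum(-1)

    cp = p - c
    d5 = (ab * cp).sum(-1)
    d6 = (ac * cp).sum(-1)

    n, m = d1.shape
    closest = np.empty((n, m, 3))
    done = np.zeros((n, m), dtype=bool)

    # vertex regions
    mask = (d1 <= 0) & (d2_ <= 0)
    closest[mask] = np.broadcast_to(a, (n, m, 3))[mask]
    done |= mask

    mask = (~done) & (d3 >= 0) & (d4 <= d3)
    closest[mask] = np.broadcast_to(b, (n, m, 3))[mask]
    done |= mask

    mask = (~done) & (d6 >= 0) & (d5 <= d6)
    closest[mask] = np.broadcast_to(c, (n, m, 3))[mask]
    done |= mask

    # edge AB
    vc = d1 * d4 - d3 * d2_
    mask = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(mask, d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3), 0.0)
    closest[mask] = (np.broadcast_to(a, (n, m, 3)) + v[..., None] * np.broadcast_to(ab, (n, m, 3)))[mask]
    done |= mask

    # edge AC
    vb = d5 * d2_ - d1 * d6
    mask = (~done) & (vb <= 0) & (d2_ >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(mask, d2_ / np.where(d2_ - d6 == 0, 1.0, d2_ - d6), 0.0)
    closest[mask] = (np.broadcast_to(a, (n, m, 3)) + w[..., None] * np.broadcast_to(ac, (n, m, 3)))[mask]
    done |= mask

    # edge BC
    va = d3 * d6 - d5 * d4
    mask = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(mask, (d4 - d3) / np.where(denom_bc == 0, 1.0, denom_bc), 0.0)
    closest[mask] = (np.broadcast_to(b, (n, m, 3)) + w[..., None] * np.broadcast_to(c - b, (n, m, 3)))[mask]
    done |= mask

    # interior
    mask = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        inv = np.where(denom == 0, 0.0, 1.0 / np.where(denom == 0, 1.0, denom))
    v = vb * inv
    w = vc * inv
    closest[mask] = (
        np.broadcast_to(a, (n, m, 3))
        + v[..., None] * np.broadcast_to(ab, (n, m, 3))
        + w[..., None] * np.broadcast_to(ac, (n, m, 3))
    )[mask]

    diff = np.asarray(points, dtype=float)[:, None, :] - closest
    d2 = np.einsum("nmk,nmk->nm", diff, diff)
    return d2, closest


def min_points_to_triangles(points: np.ndarray, triangles: np.ndarray) -> tuple[float, int, np.ndarray]:
    """Minimum distance from a point cloud to a triangle soup.

    Returns ``(distance, point_index, closest_point_on_surface)``.  Chunked
    over triangles to keep memory bounded.
    """
    points = np.asarray(points, dtype=float)
    triangles = np.asarray(triangles, dtype=float)
    n, m = len(points), len(triangles)
    if n == 0 or m == 0:
        return np.inf, -1, np.full(3, np.nan)
    step = max(1, _CHUNK // max(n, 1))
    best = (np.inf, -1, np.full(3, np.nan))
    for lo in range(0, m, step):
        d2, closest = closest_on_triangles(points, triangles[lo : lo + step])
        idx = np.unravel_index(np.argmin(d2), d2.shape)
        d = float(np.sqrt(d2[idx]))
        if d < best[0]:
            best = (d, int(idx[0]), closest[idx].copy())
    return best


def per_point_min_dist(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Distance from each point to a triangle soup, chunked over triangles."""
    points = np.asarray(points, dtype=float)
    triangles = np.asarray(triangles, dtype=float)
    n, m = len(points), len(triangles)
    if n == 0:
        return np.zeros(0)
    if m == 0:
        return np.full(n, np.inf)
    step = max(1, _CHUNK // n)
    best = np.full(n, np.inf)
    for lo in range(0, m, step):
        d2, _ = closest_on_triangles(points, triangles[lo : lo + step])
        best = np.minimum(best, np.sqrt(d2.min(axis=1)))
    return best


def points_in_mesh(points: np.ndarray, vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Ray-parity containment test for a closed triangle mesh.

    Casts one fixed-direction ray per point (Moeller-Trumbore) and counts
    crossings; odd parity means inside.  Assumes a watertight mesh; points
    exactly on the surface may land on either side.
    """
    points = np.asarray(points, dtype=float)
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces)
    if len(points) == 0:
        return np.zeros(0, dtype=bool)
    tri = vertices[faces]                        # (m,3,3)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0                                 # (m,3)
    e2 = v2 - v0
    d = _RAY_DIR
    pvec = np.cross(d, e2)                       # (m,3)
    det = np.einsum("mk,mk->m", e1, pvec)        # (m,)
    ok = np.abs(det) > 1e-14
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)

    n, m = len(points), len(tri)
    counts = np.zeros(n, dtype=int)
    step = max(1, _CHUNK // max(m, 1))
    for lo in range(0, n, step):
        p = points[lo : lo + step]
        tvec = p[:, None, :] - v0[None, :, :]     # (c,m,3)
        u = np.einsum("cmk,mk->cm", tvec, pvec) * inv_det[None, :]
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("cmk,k->cm", qvec, d) * inv_det[None, :]
        t = np.einsum("cmk,mk->cm", qvec, e2) * inv_det[None, :]
        hit = ok[None, :] & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-12)
        counts[lo : lo + step] = hit.sum(axis=1)
    return counts % 2 == 1


@dataclass
class PartSurface:
    """A triangle surface with cached quantities for fast pair queries."""

    vertices: np.ndarray
    faces: np.ndarray
    center: np.ndarray = field(init=False)
    radius: float = field(init=False)
    max_edge: float = field(init=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.center = self.vertices.mean(axis=0)
        self.radius = float(np.linalg.norm(self.vertices - self.center, axis=1).max())
        tri = self.vertices[self.faces]
        edges = np.concatenate(
            [tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 1], tri[:, 0] - tri[:, 2]]
        )
        self.max_edge = float(np.linalg.norm(edges, axis=1).max())

    def transformed(self, matrix: np.ndarray) -> np.ndarray:
        """Vertices under a 4x4 rigid transform."""
        return self.vertices @ matrix[:3, :3].T + matrix[:3, 3]


def sphere_gap(a: PartSurface, ta: np.ndarray, b: PartSurface, tb: np.ndarray) -> float:
    """Lower bound on the pair distance from bounding spheres."""
    ca = ta[:3, :3] @ a.center + ta[:3, 3]
    cb = tb[:3, :3] @ b.center + tb[:3, 3]
    return float(np.linalg.norm(ca - cb) - a.radius - b.radius)


def pair_min_distance(
    a: PartSurface,
    ta: np.ndarray,
    b: PartSurface,
    tb: np.ndarray,
    check_penetration: bool = True,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Signed minimum vertex-to-surface distance between two posed parts.

    Returns ``(distance, witness_on_a, witness_on_b)``.  The unsigned value is
    ``min`` over both directions of vertex-to-triangle distance; if any
    candidate vertex of one part lies inside the other (ray parity), the
    distance is returned negative (penetration depth of the deepest candidate).
    """
    va = a.transformed(ta)
    vb = b.transformed(tb)

    # vertex-vertex prescreen
    tree_a = cKDTree(va)
    tree_b = cKDTree(vb)
    d_ab, _ = tree_b.query(va, k=1)
    d_vv = float(d_ab.min())

    margin = max(a.max_edge, b.max_edge)
    cut = d_vv + margin

    pa_idx = np.flatnonzero(d_ab <= cut)
    d_ba, _ = tree_a.query(vb, k=1)
    pb_idx = np.flatnonzero(d_ba <= cut)

    tri_b_ok = np.flatnonzero(d_ba[b.faces].min(axis=1) <= cut)
    tri_a_ok = np.flatnonzero(d_ab[a.faces].min(axis=1) <= cut)

    best_d, wa, wb = np.inf, None, None
    d1, i1, c1 = min_points_to_triangles(va[pa_idx], vb[b.faces[tri_b_ok]])
    if d1 < best_d:
        best_d, wa, wb = d1, va[pa_idx[i1]], c1
    d2, i2, c2 = min_points_to_triangles(vb[pb_idx], va[a.faces[tri_a_ok]])
    if d2 < best_d:
        best_d, wa, wb = d2, c2, vb[pb_idx[i2]]

    if check_penetration and np.isfinite(best_d):
        inside_a = points_in_mesh(va[pa_idx], vb, b.faces)
        inside_b = points_in_mesh(vb[pb_idx], va, a.faces)
        if inside_a.any() or inside_b.any():
            depth = 0.0
            if inside_a.any():
                da = per_point_min_dist(va[pa_idx[inside_a]], vb[b.faces])
                depth = max(depth, float(da.max()))
                deepest = pa_idx[inside_a][int(np.argmax(da))]
                wa = va[deepest]
                _, j = tree_b.query(wa, k=1)
                wb = vb[j]
            if inside_b.any():
                db = per_point_min_dist(vb[pb_idx[inside_b]], va[a.faces])
                depth = max(depth, float(db.max()))
            return -depth, wa, wb
    return best_d, wa, wb


def penetration_depth(a: PartSurface, ta: np.ndarray, b: PartSurface, tb: np.ndarray) -> float:
    """Maximum depth of interpenetration between two posed closed parts (0 if none)."""
    va = a.transformed(ta)
    vb = b.transformed(tb)
    depth = 0.0
    inside = points_in_mesh(va, vb, b.faces)
    if inside.any():
        depth = max(depth, float(per_point_min_dist(va[inside], vb[b.faces]).max()))
    inside = points_in_mesh(vb, va, a.faces)
    if inside.any():
        depth = max(depth, float(per_point_min_dist(vb[inside], va[a.faces]).max()))
    return depth
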