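"""Vectorized geometric kernels: point-triangle distances and ray-triangle
intersection.

These are the two low-level queries the morphometry pipeline needs against
chromosome surface meshes. Both operate on raw (n, 3, 3) triangle arrays so
they carry no dependency beyond numpy.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "point_triangle_distance",
    "min_distance_to_triangles",
    "ray_triangle_hits",
    "segment_box_clip_length",
]


def _closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on each triangle for each query point.

    points: (m, 3); triangles: (n, 3, 3).
    Returns (m, n, 3) closest points. Implementation follows the standard
    region-classification of the point/triangle projection (Ericson,
    Real-Time Collision Detection, ch. 5), fully vectorized.
    """
    a = triangles[:, 0][None, :, :]  # (1, n, 3)
    b = triangles[:, 1][None, :, :]
    c = triangles[:, 2][None, :, :]
    p = points[:, None, :]  # (m, 1, 3)

    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)

    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)

    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    m, n = d1.shape
    out = np.empty((m, n, 3))
    done = np.zeros((m, n), dtype=bool)

    # vertex A region
    mask = (d1 <= 0) & (d2 <= 0)
    out[mask] = np.broadcast_to(a, (m, n, 3))[mask]
    done |= mask

    # vertex B region
    mask = (~done) & (d3 >= 0) & (d4 <= d3)
    out[mask] = np.broadcast_to(b, (m, n, 3))[mask]
    done |= mask

    # vertex C region
    mask = (~done) & (d6 >= 0) & (d5 <= d6)
    out[mask] = np.broadcast_to(c, (m, n, 3))[mask]
    done |= mask

    # edge AB
    mask = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1 - d3
    v = np.where(np.abs(denom) > 0, d1 / np.where(denom == 0, 1.0, denom), 0.0)
    cand = a + v[..., None] * ab
    out[mask] = cand[mask]
    done |= mask

    # edge AC
    mask = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2 - d6
    w = np.where(np.abs(denom) > 0, d2 / np.where(denom == 0, 1.0, denom), 0.0)
    cand = a + w[..., None] * ac
    out[mask] = cand[mask]
    done |= mask

    # edge BC
    mask = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    w = np.where(np.abs(denom) > 0, (d4 - d3) / np.where(denom == 0, 1.0, denom), 0.0)
    cand = b + w[..., None] * (c - b)
    out[mask] = cand[mask]
    done |= mask

    # interior
    mask = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    cand = a + v[..., None] * ab + w[..., None] * ac
    out[mask] = cand[mask]
    return out


def point_triangle_distance(points: np.ndarray, triangles: np.ndarray,
                            chunk: int = 128) -> np.ndarray:
    """Distance from each point to the nearest of the given triangles.

    Returns (m,) distances. Chunked over points to bound memory.
    """
    points = np.asarray(points, dtype=float)
    triangles = np.asarray(triangles, dtype=float)
    if points.ndim == 1:
        points = points[None, :]
    m = len(points)
    out = np.empty(m)
    for i in range(0, m, chunk):
        pts = points[i:i + chunk]
        closest = _closest_point_on_triangles(pts, triangles)
        d = np.linalg.norm(closest - pts[:, None, :], axis=-1)
        out[i:i + chunk] = d.min(axis=1)
    return out


def min_distance_to_triangles(points: np.ndarray, triangles: np.ndarray) -> float:
    """Minimum distance from any of the points to the triangle soup."""
    return float(point_triangle_distance(points, triangles).min())


def ray_triangle_hits(origin: np.ndarray, direction: np.ndarray,
                      triangles: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Möller–Trumbore: parametric hit distances of a single ray against
    a triangle soup. Returns the sorted array of non-negative hit distances
    (in the units of the inputs); empty if the ray misses everything.
    """
    origin = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ValueError("ray direction has zero length")
    d = d / nrm

    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0

    h = np.cross(d[None, :], e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > eps
    f = np.where(ok, 1.0 / np.where(a == 0, 1.0, a), 0.0)
    s = origin[None, :] - v0
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * (q @ d)
    t = f * np.einsum("ij,ij->i", e2, q)
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t >= 0)
    return np.sort(t[hit])


def segment_box_clip_length(p0: np.ndarray, p1: np.ndarray,
                            lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Length of each segment clipped to an axis-aligned box (slab method).

    p0, p1: (n, 3) segment endpoints; lo, hi: (3,) box corners.
    Returns (n,) clipped lengths.
    """
    p0 = np.atleast_2d(np.asarray(p0, dtype=float))
    p1 = np.atleast_2d(np.asarray(p1, dtype=float))
    d = p1 - p0
    seg_len = np.linalg.norm(d, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(d != 0, 1.0 / np.where(d == 0, 1.0, d), np.inf * np.sign(1.0))
        t0 = (lo[None, :] - p0) * inv
        t1 = (hi[None, :] - p0) * inv
    # handle zero direction components: inside slab -> (-inf, inf), else empty
    zero = d == 0
    inside = (p0 >= lo[None, :]) & (p0 <= hi[None, :])
    tmin_ax = np.minimum(t0, t1)
    tmax_ax = np.maximum(t0, t1)
    tmin_ax = np.where(zero, np.where(inside, -np.inf, np.inf), tmin_ax)
    tmax_ax = np.where(zero, np.where(inside, np.inf, -np.inf), tmax_ax)
    tmin = np.clip(tmin_ax.max(axis=1), 0.0, 1.0)
    tmax = np.clip(tmax_ax.min(axis=1), 0.0, 1.0)
    frac = np.maximum(tmax - tmin, 0.0)
    return frac * seg_len
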