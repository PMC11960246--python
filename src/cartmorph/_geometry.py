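"""Low-level geometric kernels shared across modules."""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Exact minimum distance from each point to a triangle soup.

    points : (n, 3); triangles : (m, 3, 3).  Returns (n,) distances.
    Full n×m evaluation (Ericson closest-point-on-triangle, vectorised);
    callers should prefilter when n·m is large.
    """
    P = np.asarray(points, dtype=float)[:, None, :]       # (n, 1, 3)
    A = np.asarray(triangles, dtype=float)[None, :, 0, :]  # (1, m, 3)
    B = np.asarray(triangles, dtype=float)[None, :, 1, :]
    C = np.asarray(triangles, dtype=float)[None, :, 2, :]
    AB = B - A
    AC = C - A
    AP = P - A

    d1 = np.einsum("nmk,nmk->nm", AB, AP)
    d2 = np.einsum("nmk,nmk->nm", AC, AP)
    BP = P - B
    d3 = np.einsum("nmk,nmk->nm", AB, BP)
    d4 = np.einsum("nmk,nmk->nm", AC, BP)
    CP = P - C
    d5 = np.einsum("nmk,nmk->nm", AB, CP)
    d6 = np.einsum("nmk,nmk->nm", AC, CP)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    # barycentric clamped coordinates, region by region
    denom_uv = np.where(vb + vc != 0, vb + vc, 1.0)
    u = np.zeros_like(d1)
    v = np.zeros_like(d1)

    # region vertex A
    mask_a = (d1 <= 0) & (d2 <= 0)
    # region vertex B
    mask_b = (d3 >= 0) & (d4 <= d3)
    # region vertex C
    mask_c = (d6 >= 0) & (d5 <= d6)
    # edge AB
    mask_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    # edge AC
    mask_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    # edge BC
    mask_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        t_bc_den = (d4 - d3) + (d5 - d6)
        t_bc = np.where(t_bc_den != 0, (d4 - d3) / t_bc_den, 0.0)
        denom = va + vb + vc
        v_in = np.where(denom != 0, vb / denom, 0.0)
        w_in = np.where(denom != 0, vc / denom, 0.0)

    # default: interior
    u = v_in
    v = w_in
    u = np.where(mask_bc, 1.0 - t_bc, u)
    v = np.where(mask_bc, t_bc, v)
    u = np.where(mask_ac, 0.0, u)
    v = np.where(mask_ac, t_ac, v)
    u = np.where(mask_ab, t_ab, u)
    v = np.where(mask_ab, 0.0, v)
    u = np.where(mask_c, 0.0, u)
    v = np.where(mask_c, 1.0, v)
    u = np.where(mask_b, 1.0, u)
    v = np.where(mask_b, 0.0, v)
    u = np.where(mask_a, 0.0, u)
    v = np.where(mask_a, 0.0, v)

    closest = A + u[..., None] * AB + v[..., None] * AC
    d = np.linalg.norm(P - closest, axis=-1)
    return d.min(axis=1)


def distance_to_surface(
    points: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    band: float | None = None,
) -> np.ndarray:
    """Distance from points to a triangulated surface.

    A KD-tree over vertices, face centroids and edge midpoints gives an
    upper bound; points whose bound cannot cross ``band`` (when given) keep
    the bound, the rest get the exact triangle distance.  With ``band=None``
    every point is resolved exactly.
    """
    points = np.asarray(points, dtype=float)
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    tris = vertices[faces]
    centroids = tris.mean(axis=1)
    mids = 0.5 * (tris + np.roll(tris, 1, axis=1)).reshape(-1, 3)
    samples = np.vstack([vertices, centroids, mids])
    ub, _ = cKDTree(samples).query(points)
    # the sample net covers the surface to within half the largest edge
    edge_len = np.linalg.norm(tris - np.roll(tris, 1, axis=1), axis=2).max() if len(tris) else 0.0
    cover = edge_len / 2.0
    if band is None:
        need = np.ones(len(points), dtype=bool)
    else:
        # ub - cover is a lower bound: points beyond it can never enter the
        # band, so only the rest need the exact test
        need = (ub - cover <= band) & (ub > 0)
    out = ub.copy()
    if need.any() and len(tris):
        out[need] = closest_point_on_triangles(points[need], tris)
    return out
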