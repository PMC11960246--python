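"""Local signed radii of curvature on the articulating surface.

The measurement construction: a least-squares cylinder is fitted to the
posterior articulating surface; its axis approximates the mediolateral
direction.  At a probe point two planes are erected — the anteroposterior
plane has the axis as its normal, the mediolateral plane contains the axis —
and an elliptical patch (default 2.7 cm², aspect 1.7, major axis
anteroposterior) is isolated around the probe.  A circle is fitted to the
patch section in each plane; the circle radii are the local AP and ML radii
of curvature.  Radii are signed: positive where the fitted centre lies on
the inward (bone) side of the surface (convex), negative on the outward
side (concave).  Radii beyond ``flat_cap`` (default 500 mm) are reported as
flat rather than as huge signed numbers.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .meshes import SurfaceMesh, _plane_basis, surface_area

__all__ = [
    "Plane",
    "CylinderFit",
    "CircleFitResult",
    "RocProbeResult",
    "LeastSquaresCylinder",
    "PlanarCircleFit",
    "fit_cylinder",
    "probe_planes",
    "patch_dimensions",
    "extract_elliptical_patch",
    "fit_circle_in_plane",
    "measure_roc",
    "place_probe_points",
    "select_posterior_articulating_surface",
]

FLAT_CAP_MM = 500.0


@dataclasses.dataclass
class Plane:
    """Plane through ``point`` with unit ``normal`` and a deterministic
    in-plane orthonormal basis (u, v)."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)
        self.u, self.v = _plane_basis(self.normal)

    def project_2d(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.point
        return np.column_stack([d @ self.u, d @ self.v])

    def lift_3d(self, coords_2d: np.ndarray) -> np.ndarray:
        coords_2d = np.atleast_2d(coords_2d)
        return self.point + np.outer(coords_2d[:, 0], self.u) + np.outer(coords_2d[:, 1], self.v)


# -- cylinder fitting ------------------------------------------------------

@dataclasses.dataclass
class CylinderFit:
    axis_point: np.ndarray
    axis_direction: np.ndarray   # unit
    radius: float
    rms_residual: float
    ill_conditioned: bool = False
    condition_number: float = float("nan")


class LeastSquaresCylinder(BaseEstimator):
    """Least-squares cylinder fit: minimise Σ (distance-to-axis − r)².

    The axis is seeded from each principal axis of the point covariance and
    refined by trust-region least squares; the best of the three seeds wins,
    which makes the fit deterministic.  Near-spherical or near-planar point
    sets are flagged ``ill_conditioned_`` (residual large relative to the
    radius, or a degenerate Jacobian).

    Attributes: ``axis_point_``, ``axis_direction_``, ``radius_``,
    ``rms_residual_``, ``ill_conditioned_``, ``condition_number_``.
    """

    def __init__(self, residual_fraction_gate: float = 0.02, condition_gate: float = 1e8):
        self.residual_fraction_gate = residual_fraction_gate
        self.condition_gate = condition_gate

    def fit(self, points, y=None) -> "LeastSquaresCylinder":
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 6:
            raise ValueError("need at least 6 points in 3-D")
        centroid = pts.mean(axis=0)
        cov = np.cov((pts - centroid).T)
        _, eigvecs = np.linalg.eigh(cov)
        best = None
        for k in range(3):
            d0 = eigvecs[:, k]
            e1, e2 = _plane_basis(d0)

            def residuals(params, d0=d0, e1=e1, e2=e2):
                a, b, u, v, r = params
                d = d0 + a * e1 + b * e2
                d = d / np.linalg.norm(d)
                c = centroid + u * e1 + v * e2
                rel = pts - c
                radial = rel - np.outer(rel @ d, d)
                return np.linalg.norm(radial, axis=1) - r

            rel0 = pts - centroid
            radial0 = rel0 - np.outer(rel0 @ d0, d0)
            r0 = float(np.linalg.norm(radial0, axis=1).mean())
            if r0 < 1e-9:
                continue
            try:
                res = least_squares(residuals, x0=[0.0, 0.0, 0.0, 0.0, r0], method="trf")
            except Exception:
                continue
            if best is None or res.cost < best[0].cost:
                best = (res, d0, e1, e2)
        if best is None:
            raise ValueError("cylinder fit failed: degenerate point set")
        res, d0, e1, e2 = best
        a, b, u, v, r = res.x
        d = d0 + a * e1 + b * e2
        d = d / np.linalg.norm(d)
        if d[np.argmax(np.abs(d))] < 0:  # deterministic sign
            d = -d
        c = centroid + u * e1 + v * e2
        c = c - (c - centroid) @ d * d  # gauge: closest axis point to centroid
        rms = float(np.sqrt(2.0 * res.cost / len(pts)))
        sv = np.linalg.svd(res.jac, compute_uv=False)
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
        self.axis_point_ = c
        self.axis_direction_ = d
        self.radius_ = float(abs(r))
        self.rms_residual_ = rms
        self.condition_number_ = cond
        self.ill_conditioned_ = bool(
            rms > self.residual_fraction_gate * self.radius_ or cond > self.condition_gate
        )
        return self

    def result(self) -> CylinderFit:
        return CylinderFit(
            axis_point=self.axis_point_,
            axis_direction=self.axis_direction_,
            radius=self.radius_,
            rms_residual=self.rms_residual_,
            ill_conditioned=self.ill_conditioned_,
            condition_number=self.condition_number_,
        )


def fit_cylinder(points) -> CylinderFit:
    return LeastSquaresCylinder().fit(points).result()


# -- circle fitting --------------------------------------------------------

@dataclasses.dataclass
class CircleFitResult:
    radius: float                # unsigned, mm
    signed_radius: float | None  # None when no sign reference was given
    center_2d: np.ndarray
    center_3d: np.ndarray | None
    residual: float              # RMS orthogonal distance, mm
    flat: bool
    n_points: int


class PlanarCircleFit(BaseEstimator):
    """Pratt algebraic circle fit refined by geometric Gauss–Newton.

    Fit on 2-D points; ``center_``, ``radius_``, ``residual_``, ``flat_``.
    Collinear inputs or radii beyond ``flat_cap`` set the flat flag.
    """

    def __init__(self, flat_cap: float = FLAT_CAP_MM):
        self.flat_cap = flat_cap

    def fit(self, points_2d, y=None) -> "PlanarCircleFit":
        pts = np.asarray(points_2d, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("need at least 3 distinct 2-D points")
        if len(np.unique(np.round(pts, 9), axis=0)) < 3:
            raise ValueError("need at least 3 distinct 2-D points")
        x, y_ = pts[:, 0], pts[:, 1]
        z = x**2 + y_**2
        # Pratt: A z + B x + C y + D = 0 with B² + C² − 4AD = 1
        Zmat = np.column_stack([z, x, y_, np.ones_like(x)])
        M = Zmat.T @ Zmat / len(pts)
        C = np.array([
            [0.0, 0.0, 0.0, -2.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [-2.0, 0.0, 0.0, 0.0],
        ])
        from scipy.linalg import eig

        w, vecs = eig(M, C)
        w = np.real(w)
        vecs = np.real(vecs)
        # exact data makes the Pratt eigenvalue ~0 (possibly a hair negative)
        good = np.isfinite(w) & (w > -1e-9 * max(1.0, float(np.abs(w[np.isfinite(w)]).max())))
        flat = False
        if not good.any():
            flat = True
        if not flat:
            sol = vecs[:, np.flatnonzero(good)[np.argmin(w[good])]]
            A, B, Cc, D = sol
            if abs(A) < 1e-12 * max(1.0, abs(B), abs(Cc)):
                flat = True
        if flat:
            self.center_ = np.full(2, np.nan)
            self.radius_ = float("inf")
            self.residual_ = float("nan")
            self.flat_ = True
            return self
        center = np.array([-B / (2 * A), -Cc / (2 * A)])
        radius = float(np.sqrt(max(B**2 + Cc**2 - 4 * A * D, 0.0)) / (2 * abs(A)))

        def geo(params):
            cx, cy, r = params
            return np.hypot(x - cx, y_ - cy) - r

        try:
            res = least_squares(geo, x0=[center[0], center[1], radius], method="lm")
            center = res.x[:2]
            radius = float(abs(res.x[2]))
            residual = float(np.sqrt(2.0 * res.cost / len(pts)))
        except Exception:
            residual = float(np.sqrt(np.mean(geo([*center, radius]) ** 2)))
        self.center_ = center
        self.radius_ = radius
        self.residual_ = residual
        self.flat_ = bool(radius > self.flat_cap)
        return self


def fit_circle_in_plane(
    points,
    plane: Plane,
    probe_point=None,
    probe_normal=None,
    flat_cap: float = FLAT_CAP_MM,
) -> CircleFitResult:
    """Project points orthogonally into the plane, fit a circle, and sign
    the radius: positive (convex) if the fitted centre lies on the inward
    (anti-normal) side of the surface at the probe."""
    pts2 = plane.project_2d(np.asarray(points, dtype=float))
    fitter = PlanarCircleFit(flat_cap=flat_cap).fit(pts2)
    if fitter.flat_:
        return CircleFitResult(
            radius=fitter.radius_, signed_radius=None, center_2d=fitter.center_,
            center_3d=None, residual=fitter.residual_, flat=True, n_points=len(pts2),
        )
    center3 = plane.lift_3d(fitter.center_)[0]
    signed = None
    if probe_point is not None and probe_normal is not None:
        towards = center3 - np.asarray(probe_point, dtype=float)
        sign = -1.0 if float(towards @ np.asarray(probe_normal, dtype=float)) > 0 else 1.0
        signed = sign * fitter.radius_
    return CircleFitResult(
        radius=fitter.radius_, signed_radius=signed, center_2d=fitter.center_,
        center_3d=center3, residual=fitter.residual_, flat=False, n_points=len(pts2),
    )


# -- planes and patches ----------------------------------------------------

def probe_planes(cyl: CylinderFit, probe_point) -> tuple[Plane, Plane]:
    """(AP plane, ML plane) at a probe point: the AP plane has the cylinder
    axis as its normal; the ML plane contains the whole axis line and the
    probe.  Undefined when the probe lies on the axis."""
    p = np.asarray(probe_point, dtype=float)
    d = cyl.axis_direction / np.linalg.norm(cyl.axis_direction)
    ap = Plane(point=p, normal=d)
    rel = p - cyl.axis_point
    radial = rel - (rel @ d) * d
    if np.linalg.norm(radial) < 1e-9:
        raise ValueError("probe point lies on the cylinder axis; ML plane undefined")
    ml_normal = np.cross(d, radial)
    return ap, Plane(point=p, normal=ml_normal / np.linalg.norm(ml_normal))


def patch_dimensions(area_mm2: float, aspect: float) -> tuple[float, float]:
    """Full major/minor axes of an ellipse with the given area and
    major:minor ratio: a = 2√(area·aspect/π), b = 2√(area/(π·aspect))."""
    if area_mm2 <= 0:
        raise ValueError("area must be > 0")
    if aspect < 1:
        raise ValueError("aspect ratio must be >= 1")
    a = 2.0 * np.sqrt(area_mm2 * aspect / np.pi)
    b = 2.0 * np.sqrt(area_mm2 / (np.pi * aspect))
    return float(a), float(b)


def _face_components(faces: np.ndarray) -> np.ndarray:
    """Connected-component label per face (faces sharing an edge connect)."""
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    edges = {}
    pairs = []
    for fi, f in enumerate(faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (a, b) if a < b else (b, a)
            if key in edges:
                pairs.append((edges[key], fi))
            else:
                edges[key] = fi
    n = len(faces)
    if pairs:
        pairs = np.asarray(pairs)
        g = sp.coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        g = sp.coo_matrix((n, n))
    return connected_components(g, directed=False)[1]


def extract_elliptical_patch(
    mesh: SurfaceMesh,
    probe_point,
    axes: tuple,
    ap_direction,
    probe_normal=None,
) -> tuple[SurfaceMesh, np.ndarray, bool]:
    """Isolate the elliptical patch centred on the probe.

    Face centroids are projected onto the probe's tangent frame (AP tangent
    = given in-surface AP direction, ML tangent orthogonal to it and the
    normal); faces satisfying the ellipse inequality and connected to the
    probe are kept.  Returns (patch, face_mask, boundary_clipped).
    """
    p = np.asarray(probe_point, dtype=float)
    major, minor = axes
    if probe_normal is None:
        vi = int(np.argmin(np.linalg.norm(mesh.vertices - p, axis=1)))
        probe_normal = mesh.vertex_normals()[vi]
    n = np.asarray(probe_normal, dtype=float)
    n = n / np.linalg.norm(n)
    t_ap = np.asarray(ap_direction, dtype=float)
    t_ap = t_ap - (t_ap @ n) * n
    if np.linalg.norm(t_ap) < 1e-9:
        raise ValueError("AP direction is parallel to the surface normal")
    t_ap /= np.linalg.norm(t_ap)
    t_ml = np.cross(n, t_ap)

    fc = mesh.vertices[mesh.faces].mean(axis=1) - p
    u = fc @ t_ap
    v = fc @ t_ml
    inside = (u / (major / 2.0)) ** 2 + (v / (minor / 2.0)) ** 2 <= 1.0
    if not inside.any():
        raise ValueError("elliptical patch selects no faces")
    # largest connected component containing (or nearest to) the probe
    idx = np.flatnonzero(inside)
    comp = _face_components(mesh.faces[idx])
    d2 = (fc[idx] ** 2).sum(axis=1)
    probe_comp = comp[np.argmin(d2)]
    keep = idx[comp == probe_comp]
    mask = np.zeros(mesh.n_faces, dtype=bool)
    mask[keep] = True
    patch = mesh.submesh(mask)

    # clipped if the patch boundary coincides with the parent mesh boundary
    parent_boundary = set(map(tuple, mesh.vertices[mesh.boundary_vertices()].round(9)))
    patch_boundary = set(map(tuple, patch.vertices[patch.boundary_vertices()].round(9)))
    clipped = bool(parent_boundary & patch_boundary)
    return patch, mask, clipped


# -- plane sections --------------------------------------------------------

def _plane_section_points(mesh: SurfaceMesh, plane: Plane) -> np.ndarray:
    """Unique intersection points of the mesh with a plane."""
    import trimesh.intersections as ti

    segments = ti.mesh_plane(mesh.as_trimesh(), plane.normal, plane.point)
    if len(segments) == 0:
        return np.empty((0, 3))
    pts = segments.reshape(-1, 3)
    return np.unique(pts.round(9), axis=0)


def _order_segments(segments: np.ndarray) -> list:
    """Chain (n, 2, 3) unordered segments into ordered polylines."""
    import networkx as nx

    g = nx.Graph()
    key = lambda p: tuple(np.round(p, 7))
    coords = {}
    for seg in segments:
        a, b = key(seg[0]), key(seg[1])
        coords[a], coords[b] = seg[0], seg[1]
        g.add_edge(a, b)
    lines = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        ends = [n for n in sub if sub.degree(n) == 1]
        start = ends[0] if ends else next(iter(sub))
        path = [start]
        prev = None
        cur = start
        while True:
            nbrs = [n for n in sub.neighbors(cur) if n != prev]
            if not nbrs:
                break
            prev, cur = cur, nbrs[0]
            if cur == start:
                break
            path.append(cur)
        lines.append(np.asarray([coords[p] for p in path]))
    return lines


# -- full probe measurement ------------------------------------------------

@dataclasses.dataclass
class RocProbeResult:
    probe_point: np.ndarray
    patch_area_mm2: float
    patch_aspect: float
    ap_radius: float      # signed mm; nan when flat
    ml_radius: float
    ap_residual: float
    ml_residual: float
    ap_flat: bool
    ml_flat: bool
    boundary_clipped: bool


def measure_roc(
    mesh: SurfaceMesh,
    probe_point,
    cyl: CylinderFit,
    patch_area_mm2: float = 270.0,
    patch_aspect: float = 1.7,
    flat_cap: float = FLAT_CAP_MM,
) -> RocProbeResult:
    """Signed AP and ML radii of curvature at a probe point.

    Composes the plane construction, elliptical patch isolation and circle
    fitting.  Circles are fitted to the patch's section curve in each plane
    (the in-plane slice of the isolated surface)."""
    p = np.asarray(probe_point, dtype=float)
    ap_plane, ml_plane = probe_planes(cyl, p)
    vi = int(np.argmin(np.linalg.norm(mesh.vertices - p, axis=1)))
    normal = mesh.vertex_normals()[vi]
    # AP tangent: intersection of the AP plane with the tangent plane
    t_ap = np.cross(ap_plane.normal, normal)
    if np.linalg.norm(t_ap) < 1e-9:
        raise ValueError("degenerate probe: surface normal parallel to the axis")
    t_ap /= np.linalg.norm(t_ap)
    major, minor = patch_dimensions(patch_area_mm2, patch_aspect)
    patch, _, clipped = extract_elliptical_patch(
        mesh, p, (major, minor), t_ap, probe_normal=normal
    )

    def section_fit(plane: Plane) -> CircleFitResult:
        pts = _plane_section_points(patch, plane)
        if len(pts) < 3:
            return CircleFitResult(
                radius=float("inf"), signed_radius=None, center_2d=np.full(2, np.nan),
                center_3d=None, residual=float("nan"), flat=True, n_points=len(pts),
            )
        return fit_circle_in_plane(pts, plane, probe_point=p, probe_normal=normal,
                                   flat_cap=flat_cap)

    ap_fit = section_fit(ap_plane)
    ml_fit = section_fit(ml_plane)
    return RocProbeResult(
        probe_point=p,
        patch_area_mm2=patch_area_mm2,
        patch_aspect=patch_aspect,
        ap_radius=float("nan") if ap_fit.flat else float(ap_fit.signed_radius),
        ml_radius=float("nan") if ml_fit.flat else float(ml_fit.signed_radius),
        ap_residual=ap_fit.residual,
        ml_residual=ml_fit.residual,
        ap_flat=ap_fit.flat,
        ml_flat=ml_fit.flat,
        boundary_clipped=clipped,
    )


def select_posterior_articulating_surface(
    mesh: SurfaceMesh,
    labels: tuple = ("medial_condyle", "lateral_condyle"),
    plane_point=(0.0, 0.0, 0.0),
    plane_normal=(0.0, -1.0, 0.0),
) -> tuple[SurfaceMesh, np.ndarray]:
    """Faces of the condylar lobes posterior-distal of a frame plane.

    Uses region labels when present, otherwise the plane test alone.
    Returns (submesh, face_mask); raises if the selection is empty.
    """
    fc = mesh.vertices[mesh.faces].mean(axis=1)
    pp = np.asarray(plane_point, dtype=float)
    pn = np.asarray(plane_normal, dtype=float)
    pn = pn / np.linalg.norm(pn)
    mask = (fc - pp) @ pn >= 0
    if mesh.face_labels is not None and labels:
        mask &= np.isin(mesh.face_labels, labels)
    if not mask.any():
        raise ValueError("posterior articulating selection is empty")
    return mesh.submesh(mask), mask


def _ap_section_polyline(mesh: SurfaceMesh, anchor: np.ndarray, cyl: CylinderFit):
    """Ordered AP-plane section polyline through the anchor, with its
    arc-length parametrisation and the anchor's arc position."""
    import trimesh.intersections as ti

    d = cyl.axis_direction / np.linalg.norm(cyl.axis_direction)
    segments = ti.mesh_plane(mesh.as_trimesh(), d, anchor)
    if len(segments) == 0:
        raise ValueError("AP plane through the anchor misses the surface")
    lines = _order_segments(segments)
    best = min(lines, key=lambda L: np.min(np.linalg.norm(L - anchor, axis=1)))
    deltas = np.linalg.norm(np.diff(best, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(deltas)])
    k = int(np.argmin(np.linalg.norm(best - anchor, axis=1)))
    return best, s, s[k]


def feasible_probe_spacing(mesh: SurfaceMesh, anchor, cyl: CylinderFit, n: int) -> float:
    """Largest spacing for which n probe points centred on the anchor stay
    on the AP section through it."""
    if n < 2:
        return float("inf")
    _, s, s0 = _ap_section_polyline(mesh, np.asarray(anchor, dtype=float), cyl)
    room = min(s0 - s.min(), s.max() - s0)
    return 2.0 * room / (n - 1)


def place_probe_points(
    mesh: SurfaceMesh,
    anchor_point,
    cyl: CylinderFit,
    n: int = 5,
    spacing: float | None = None,
) -> np.ndarray:
    """n on-surface points equally spaced in arc length along the AP
    direction through the anchor (the section of the surface by the AP
    plane at the anchor).  Default spacing is half the default patch major
    axis.  The anchor maps to the middle point for odd n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if spacing is None:
        spacing = patch_dimensions(270.0, 1.7)[0] / 2.0
    anchor = np.asarray(anchor_point, dtype=float)
    best, s, s0 = _ap_section_polyline(mesh, anchor, cyl)
    deltas = np.linalg.norm(np.diff(best, axis=0), axis=1)
    offsets = (np.arange(n) - (n - 1) / 2.0) * spacing
    targets = s0 + offsets
    if targets.min() < s.min() - 1e-9 or targets.max() > s.max() + 1e-9:
        raise ValueError("region too small for the requested probe spacing")
    out = np.empty((n, 3))
    for i, t in enumerate(targets):
        j = int(np.clip(np.searchsorted(s, t) - 1, 0, len(deltas) - 1))
        w = 0.0 if deltas[j] == 0 else (t - s[j]) / deltas[j]
        out[i] = best[j] * (1 - w) + best[j + 1] * w
    return out
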