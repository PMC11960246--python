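"""Synthetic condylar cartilage cohorts with known ground truth.

The base shape is a surface of revolution about the mediolateral (x) axis
with a radial profile ``r(x)`` made of two Gaussian condylar lobes and a
central Gaussian groove.  This choice ties the geometry directly to the
curvature-measurement construction used downstream:

* a plane perpendicular to the axis (the anteroposterior measurement plane)
  cuts the surface in an exact circle of radius ``r(x)`` — always convex;
* a plane containing the axis (the mediolateral plane) cuts it in the
  profile curve, whose signed curvature radius is the closed form
  ``-(1 + r'²)^{3/2} / r''`` — convex (+) on the condylar lobes, concave (−)
  in the groove.

Cohort members are the base surface deformed along a small set of fixed,
orthonormalised smooth displacement fields (so the planted PCA structure is
known exactly), plus optional vertex noise and a random rigid transform.
Right-sided members are mirrored in the sagittal plane before export, as
scanned data would be.  Analytic fixtures (sphere cap, cylinder patch, torus
saddle patch, planar ellipse, exact circle points) provide closed-form
oracles for the curvature estimators.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .meshes import SurfaceMesh, mirror_sagittal, write_mesh

__all__ = [
    "CohortConfig",
    "SyntheticModelTruth",
    "CohortSample",
    "SyntheticCohort",
    "generate_base_surface",
    "generate_cohort",
    "analytic_fixture",
    "FixtureResult",
    "write_cohort",
]


@dataclasses.dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the population the pipeline is meant for: ~70 knees,
    defect areas log-normal around a 2.7 cm² median, aspect ratios around
    1.6, defect centres clustered at a medial-condyle hotspot.  All lengths
    in mm; ``seed`` fixes every random draw.
    """

    n_models: int = 70
    # base geometry
    condyle_radius: float = 22.0       # profile radius at a condylar apex
    condyle_separation: float = 46.0   # distance between lobe centres
    groove_depth: float = 5.0          # radial dip of the central groove
    ap_extent: float = 60.0            # arc length covered in AP direction
    ml_extent: float = 80.0            # width along the axis
    lobe_height: float = 3.0           # radial prominence of each lobe
    lobe_width: float = 8.0            # Gaussian sigma of the lobes
    groove_width: float = 9.0          # Gaussian sigma of the groove
    theta_offset: float = 0.35         # centre of the AP angular window (rad)
    probe_theta: float = 0.9           # angular coordinate of truth probes
    # planted variation
    mode_amplitudes: tuple = (2.0, 1.0, 0.5)  # per-mode SD in mm
    vertex_noise_sd: float = 0.05
    rigid_rotation_sd_deg: float = 5.0
    rigid_translation_sd: float = 5.0
    # defects
    defect_area_median: float = 270.0  # mm²
    defect_area_log_sd: float = 0.60   # log-normal spread (matches the
    defect_aspect_median: float = 1.6  # right-skewed clinical distribution)
    defect_aspect_log_sd: float = 0.25
    defect_depth: float = 2.0
    hotspot_center: tuple = (23.0, 0.9)  # (x mm, theta rad) on the surface
    hotspot_spread: float = 5.0          # SD of centre scatter, mm
    side_mix: float = 0.5                # fraction of right-sided knees
    # discretisation
    n_grid_u: int = 48  # along the axis (ML)
    n_grid_v: int = 36  # around the axis (AP)
    seed: int = 0

    def validate(self) -> None:
        if self.n_models < 3:
            raise ValueError("n_models must be >= 3")
        for name in (
            "condyle_radius", "condyle_separation", "ap_extent", "ml_extent",
            "lobe_width", "groove_width", "defect_area_median", "defect_depth",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.groove_depth < 0 or self.groove_depth >= self.condyle_radius:
            raise ValueError("groove depth must be in [0, condyle_radius)")
        if self.defect_aspect_median < 1:
            raise ValueError("defect_aspect_median must be >= 1")
        if not 0.0 <= self.side_mix <= 1.0:
            raise ValueError("side_mix must be in [0, 1]")
        if self.n_grid_u < 4 or self.n_grid_v < 4:
            raise ValueError("grid must be at least 4x4")
        r0 = self.condyle_radius - self.lobe_height
        if r0 - self.groove_depth <= 1.0:
            raise ValueError("groove too deep for the chosen base radius")


@dataclasses.dataclass
class SyntheticModelTruth:
    """Everything needed to score downstream estimates for one model."""

    model_id: str
    mode_coefficients: np.ndarray        # amplitude-scaled, mm
    rotation: np.ndarray                 # (3, 3) applied rigid rotation
    translation: np.ndarray              # (3,)
    side: str                            # "left" | "right"
    defect_center_param: tuple           # (x mm, theta rad)
    defect_center_xyz: np.ndarray        # on the undeformed base surface
    defect_area_mm2: float               # drawn target area
    defect_aspect: float


@dataclasses.dataclass
class CohortSample:
    model_id: str
    native: SurfaceMesh
    defect: SurfaceMesh
    truth: SyntheticModelTruth

    @property
    def articulating_mask(self) -> np.ndarray:
        return self.defect.face_labels == "articulating"


@dataclasses.dataclass
class SyntheticCohort:
    config: CohortConfig
    base: SurfaceMesh
    base_params: np.ndarray          # (m, 2) per-vertex (x, theta)
    mode_basis: np.ndarray           # (3m, q) orthonormal planted modes
    mode_variances: np.ndarray       # planted per-mode variances, mm²
    probe_truth: dict                # name -> dict(point, ap_radius, ml_radius)
    samples: list

    @property
    def native_meshes(self):
        return [s.native for s in self.samples]


# -- base geometry ---------------------------------------------------------

def radial_profile(config: CohortConfig, x):
    """Radial profile r(x) of the base surface with first two derivatives."""
    x = np.asarray(x, dtype=float)
    r0 = config.condyle_radius - config.lobe_height
    r = np.full_like(x, r0, dtype=float)
    dr = np.zeros_like(x, dtype=float)
    d2r = np.zeros_like(x, dtype=float)
    c = config.condyle_separation / 2.0
    terms = [
        (config.lobe_height, c, config.lobe_width),
        (config.lobe_height, -c, config.lobe_width),
        (-config.groove_depth, 0.0, config.groove_width),
    ]
    for amp, mu, w in terms:
        g = amp * np.exp(-((x - mu) ** 2) / (2.0 * w**2))
        r += g
        dr += -(x - mu) / w**2 * g
        d2r += ((x - mu) ** 2 / w**4 - 1.0 / w**2) * g
    return r, dr, d2r


def surface_point(config: CohortConfig, x, theta) -> np.ndarray:
    """Map surface coordinates (x, theta) to 3-D points on the base surface."""
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=float)
    r, _, _ = radial_profile(config, x)
    return np.stack([x, -r * np.sin(theta), -r * np.cos(theta)], axis=-1)


def surface_normal(config: CohortConfig, x, theta) -> np.ndarray:
    """Outward (away from the axis) unit normal at (x, theta)."""
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=float)
    _, dr, _ = radial_profile(config, x)
    n = np.stack(
        [-dr, -np.sin(theta) * np.ones_like(dr), -np.cos(theta) * np.ones_like(dr)],
        axis=-1,
    )
    return n / np.linalg.norm(n, axis=-1, keepdims=True)


def closed_form_probe_radii(config: CohortConfig, x: float) -> tuple:
    """Signed (AP, ML) plane-section curvature radii at axial position x.

    AP sections (plane ⊥ axis) are circles of radius r(x), always convex.
    ML sections (plane through the axis) follow the profile curve; sign is
    positive where the profile is convex (r'' < 0).
    """
    r, dr, d2r = radial_profile(config, np.atleast_1d(float(x)))
    r, dr, d2r = float(r[0]), float(dr[0]), float(d2r[0])
    ap = r
    if abs(d2r) < 1e-12:
        ml = float("inf")
    else:
        ml = -((1.0 + dr**2) ** 1.5) / d2r
    return ap, ml


def _theta_range(config: CohortConfig) -> tuple:
    half = config.ap_extent / config.condyle_radius / 2.0
    return config.theta_offset - half, config.theta_offset + half


def _grid(config: CohortConfig):
    xs = np.linspace(-config.ml_extent / 2.0, config.ml_extent / 2.0, config.n_grid_u)
    t0, t1 = _theta_range(config)
    ts = np.linspace(t0, t1, config.n_grid_v)
    X, T = np.meshgrid(xs, ts, indexing="ij")
    params = np.column_stack([X.ravel(), T.ravel()])
    verts = surface_point(config, params[:, 0], params[:, 1])
    nu, nv = config.n_grid_u, config.n_grid_v
    faces = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            a = i * nv + j
            b = (i + 1) * nv + j
            faces.append([a, b, a + 1])
            faces.append([a + 1, b, b + 1])
    faces = np.asarray(faces, dtype=np.int64)
    # orient windings so face normals point outward (away from the axis)
    fc = verts[faces].mean(axis=1)
    fn = np.cross(verts[faces[:, 1]] - verts[faces[:, 0]], verts[faces[:, 2]] - verts[faces[:, 0]])
    radial = fc.copy()
    radial[:, 0] = 0.0
    if np.median(np.einsum("ij,ij->i", fn, radial)) < 0:
        faces = faces[:, [0, 2, 1]]
    return verts, faces, params


def _face_labels(config: CohortConfig, verts, faces) -> np.ndarray:
    cx = verts[faces].mean(axis=1)[:, 0]
    quarter = config.condyle_separation / 4.0
    labels = np.full(len(faces), "trochlea", dtype=object)
    labels[cx > quarter] = "medial_condyle"
    labels[cx < -quarter] = "lateral_condyle"
    return labels.astype(str)


def default_probes(config: CohortConfig) -> dict:
    c = config.condyle_separation / 2.0
    t = config.probe_theta
    return {
        "medial_apex": (c, t),
        "lateral_apex": (-c, t),
        "groove": (0.0, t),
    }


def generate_base_surface(config: CohortConfig) -> SurfaceMesh:
    """Build the labelled base surface (no deformation, no noise)."""
    config.validate()
    verts, faces, _ = _grid(config)
    return SurfaceMesh(verts, faces, face_labels=_face_labels(config, verts, faces))


def probe_truth(config: CohortConfig) -> dict:
    """Closed-form signed AP/ML radii at the designated probe points."""
    out = {}
    for name, (x, theta) in default_probes(config).items():
        ap, ml = closed_form_probe_radii(config, x)
        out[name] = {
            "point": surface_point(config, x, theta),
            "param": (x, theta),
            "ap_radius": ap,
            "ml_radius": ml,
        }
    return out


# -- planted deformation modes --------------------------------------------

def _rigid_tangent_basis(verts: np.ndarray) -> np.ndarray:
    """Orthonormal basis of infinitesimal rigid motions (3 translations +
    3 rotations) of a vertex set, as flattened 3m-vectors."""
    m = len(verts)
    c = verts.mean(axis=0)
    rel = verts - c
    fields = []
    for k in range(3):
        t = np.zeros((m, 3))
        t[:, k] = 1.0
        fields.append(t.ravel())
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        fields.append(np.cross(e, rel).ravel())
    qmat, _ = np.linalg.qr(np.stack(fields, axis=1))
    return qmat


def _mode_basis(config: CohortConfig, params: np.ndarray, normals: np.ndarray) -> np.ndarray:
    """Fixed smooth displacement fields, orthonormalised over the vertices
    and orthogonal to rigid motions of the base shape (so alignment does not
    absorb planted variance)."""
    q = len(config.mode_amplitudes)
    u = (params[:, 0] + config.ml_extent / 2.0) / config.ml_extent
    t0, t1 = _theta_range(config)
    v = (params[:, 1] - t0) / (t1 - t0)
    scalars = [
        np.sin(np.pi * u),
        np.cos(np.pi * v),
        np.sin(2.0 * np.pi * u) * np.sin(np.pi * v),
        np.cos(2.0 * np.pi * v) * np.sin(np.pi * u),
        np.sin(3.0 * np.pi * u) * np.cos(np.pi * v),
    ]
    if q > len(scalars):
        raise ValueError(f"at most {len(scalars)} planted modes supported")
    fields = np.stack([(s[:, None] * normals).ravel() for s in scalars[:q]], axis=1)
    verts = surface_point(config, params[:, 0], params[:, 1])
    rigid = _rigid_tangent_basis(verts)
    fields = fields - rigid @ (rigid.T @ fields)
    qmat, rmat = np.linalg.qr(fields)
    qmat = qmat * np.sign(np.diag(rmat))[None, :]  # deterministic sign
    return qmat


# -- cohort generation -----------------------------------------------------

def _build_defect(
    config: CohortConfig,
    native: SurfaceMesh,
    params: np.ndarray,
    center: tuple,
    area: float,
    aspect: float,
) -> SurfaceMesh:
    """Cut the elliptical defect patch out of the native surface and extrude
    it inward.  Articulating faces come first in the face list."""
    xc, tc = center
    rc, _, _ = radial_profile(config, np.atleast_1d(xc))
    rc = float(rc[0])
    major = 2.0 * np.sqrt(area * aspect / np.pi)
    minor = 2.0 * np.sqrt(area / (np.pi * aspect))
    fc_param = params[native.faces].mean(axis=1)
    du = fc_param[:, 0] - xc          # ML offset, mm
    dv = (fc_param[:, 1] - tc) * rc   # AP arc offset, mm; major axis along AP
    inside = (dv / (major / 2.0)) ** 2 + (du / (minor / 2.0)) ** 2 <= 1.0
    if not inside.any():
        # guarantee a non-empty patch: take the face nearest the centre
        inside[np.argmin(du**2 + dv**2)] = True
    top = native.submesh(inside)
    m = top.n_vertices
    normals = top.vertex_normals()
    bottom_verts = top.vertices - config.defect_depth * normals
    verts = np.vstack([top.vertices, bottom_verts])
    top_faces = top.faces
    bottom_faces = top.faces[:, [0, 2, 1]] + m
    # wall faces along the open boundary of the patch
    e = np.vstack([top_faces[:, [0, 1]], top_faces[:, [1, 2]], top_faces[:, [2, 0]]])
    key = np.sort(e, axis=1)
    uniq, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    boundary = e[idx[counts == 1]]
    walls = []
    for i, j in boundary:
        walls.append([i, j, j + m])
        walls.append([i, j + m, i + m])
    walls = np.asarray(walls, dtype=np.int64).reshape(-1, 3)
    faces = np.vstack([top_faces, bottom_faces, walls])
    labels = np.concatenate([
        np.full(len(top_faces), "articulating"),
        np.full(len(bottom_faces), "bottom"),
        np.full(len(walls), "wall"),
    ])
    return SurfaceMesh(verts, faces, face_labels=labels)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate native + defect model pairs with full truth records."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    base_verts, faces, params = _grid(config)
    labels = _face_labels(config, base_verts, faces)
    base = SurfaceMesh(base_verts, faces, face_labels=labels)
    basis = _mode_basis(config, params, base.vertex_normals())
    amps = np.asarray(config.mode_amplitudes, dtype=float)
    t0, t1 = _theta_range(config)

    # keep defect centres far enough inside the parameter window
    major_med = 2.0 * np.sqrt(config.defect_area_median * config.defect_aspect_median / np.pi)
    x_lim = config.ml_extent / 2.0 - major_med / 2.0
    r_hot, _, _ = radial_profile(config, np.atleast_1d(config.hotspot_center[0]))
    t_margin = (major_med / 2.0) / float(r_hot[0])

    samples = []
    for i in range(config.n_models):
        coeffs = rng.standard_normal(len(amps)) * amps
        verts = base_verts + (basis @ coeffs).reshape(-1, 3)
        verts = verts + rng.standard_normal(verts.shape) * config.vertex_noise_sd
        native = SurfaceMesh(verts, faces, face_labels=labels)

        center_off = rng.standard_normal(2) * config.hotspot_spread
        xc = float(np.clip(config.hotspot_center[0] + center_off[0], -x_lim, x_lim))
        tc = float(np.clip(
            config.hotspot_center[1] + center_off[1] / float(r_hot[0]),
            t0 + t_margin, t1 - t_margin,
        ))
        area = float(config.defect_area_median * np.exp(rng.standard_normal() * config.defect_area_log_sd))
        aspect = float(max(1.0, config.defect_aspect_median * np.exp(rng.standard_normal() * config.defect_aspect_log_sd)))
        defect = _build_defect(config, native, params, (xc, tc), area, aspect)

        rotvec = rng.standard_normal(3) * np.deg2rad(config.rigid_rotation_sd_deg)
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        trans = rng.standard_normal(3) * config.rigid_translation_sd
        native = native.transformed(rotation=rot, translation=trans)
        defect = defect.transformed(rotation=rot, translation=trans)

        side = "right" if rng.random() < config.side_mix else "left"
        if side == "right":
            native = mirror_sagittal(native)
            defect = mirror_sagittal(defect)

        truth = SyntheticModelTruth(
            model_id=f"model_{i:03d}",
            mode_coefficients=coeffs,
            rotation=rot,
            translation=trans,
            side=side,
            defect_center_param=(xc, tc),
            defect_center_xyz=surface_point(config, xc, tc),
            defect_area_mm2=area,
            defect_aspect=aspect,
        )
        samples.append(CohortSample(truth.model_id, native, defect, truth))

    return SyntheticCohort(
        config=config,
        base=base,
        base_params=params,
        mode_basis=basis,
        mode_variances=amps**2,
        probe_truth=probe_truth(config),
        samples=samples,
    )


# -- serialisation ---------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write meshes (binary PLY), a manifest CSV and a truth JSON."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    truths = {}
    for s in cohort.samples:
        native_path = out_dir / f"{s.model_id}_native.ply"
        defect_path = out_dir / f"{s.model_id}_defect.ply"
        write_mesh(s.native, native_path)
        write_mesh(s.defect, defect_path)
        rows.append({
            "model_id": s.model_id,
            "side": s.truth.side,
            "native_path": native_path.name,
            "defect_path": defect_path.name,
            "n_articulating_faces": int((s.defect.face_labels == "articulating").sum()),
        })
        truths[s.model_id] = {
            "mode_coefficients": s.truth.mode_coefficients.tolist(),
            "rotation": s.truth.rotation.tolist(),
            "translation": s.truth.translation.tolist(),
            "side": s.truth.side,
            "defect_center_param": list(s.truth.defect_center_param),
            "defect_center_xyz": s.truth.defect_center_xyz.tolist(),
            "defect_area_mm2": s.truth.defect_area_mm2,
            "defect_aspect": s.truth.defect_aspect,
        }
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    payload = {
        "mode_variances": cohort.mode_variances.tolist(),
        "probes": {
            k: {
                "point": v["point"].tolist(),
                "param": list(v["param"]),
                "ap_radius": v["ap_radius"],
                "ml_radius": None if np.isinf(v["ml_radius"]) else v["ml_radius"],
            }
            for k, v in cohort.probe_truth.items()
        },
        "models": truths,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return out_dir


# -- analytic fixtures -----------------------------------------------------

@dataclasses.dataclass
class FixtureResult:
    mesh: SurfaceMesh | None
    points: np.ndarray | None
    truth: dict


def _check_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be > 0")


def _grid_mesh(U, V, fn) -> SurfaceMesh:
    nu, nv = len(U), len(V)
    UU, VV = np.meshgrid(U, V, indexing="ij")
    verts = fn(UU.ravel(), VV.ravel())
    faces = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            a = i * nv + j
            b = (i + 1) * nv + j
            faces.append([a, b, a + 1])
            faces.append([a + 1, b, b + 1])
    return SurfaceMesh(verts, np.asarray(faces, dtype=np.int64))


def _orient(mesh: SurfaceMesh, outward_at: np.ndarray, normal: np.ndarray) -> SurfaceMesh:
    """Flip winding if the face nearest ``outward_at`` disagrees with the
    analytic normal there."""
    fc = mesh.vertices[mesh.faces].mean(axis=1)
    k = int(np.argmin(np.linalg.norm(fc - outward_at, axis=1)))
    if float(mesh.face_normals()[k] @ normal) < 0:
        mesh = mesh.copy()
        mesh.faces = mesh.faces[:, [0, 2, 1]]
    return mesh


def analytic_fixture(kind: str, **params) -> FixtureResult:
    """Closed-form oracles for the curvature estimators.

    kinds: ``sphere_cap``, ``cylinder_patch``, ``saddle_patch``,
    ``planar_ellipse``, ``exact_circle_points``.
    """
    if kind == "sphere_cap":
        R = params.get("radius", 20.0)
        cap = np.deg2rad(params.get("cap_angle_deg", 50.0))
        n = params.get("n", 48)
        _check_positive(radius=R, cap_angle_deg=cap)
        polar = np.linspace(1e-3, cap, n)
        azim = np.linspace(0.0, 2.0 * np.pi, 2 * n, endpoint=False)

        def f(p, a):
            return np.stack(
                [R * np.sin(p) * np.cos(a), R * np.sin(p) * np.sin(a), R * np.cos(p)], axis=-1
            )

        mesh = _grid_mesh(polar, azim, f)
        # close the azimuthal seam
        nv = len(azim)
        seam = []
        for i in range(n - 1):
            a = i * nv + (nv - 1)
            b = (i + 1) * nv + (nv - 1)
            seam.append([a, b, i * nv])
            seam.append([i * nv, b, (i + 1) * nv])
        mesh = SurfaceMesh(mesh.vertices, np.vstack([mesh.faces, np.asarray(seam)]))
        apex = np.array([0.0, 0.0, R])
        mesh = _orient(mesh, apex, np.array([0.0, 0.0, 1.0]))
        truth = {
            "radius": R,
            "principal_radii": (R, R),
            "area": 2.0 * np.pi * R**2 * (1.0 - np.cos(cap)),
            "center": np.zeros(3),
        }
        return FixtureResult(mesh, None, truth)

    if kind == "cylinder_patch":
        R = params.get("radius", 20.0)
        height = params.get("height", 40.0)
        arc = np.deg2rad(params.get("arc_deg", 120.0))
        n = params.get("n", 40)
        _check_positive(radius=R, height=height, arc_deg=arc)
        zs = np.linspace(-height / 2.0, height / 2.0, n)
        ts = np.linspace(-arc / 2.0, arc / 2.0, n)

        def f(z, t):
            return np.stack([R * np.cos(t), R * np.sin(t), z], axis=-1)

        mesh = _grid_mesh(zs, ts, f)
        mesh = _orient(mesh, np.array([R, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]))
        truth = {
            "radius": R,
            "axis_point": np.zeros(3),
            "axis_direction": np.array([0.0, 0.0, 1.0]),
            "principal_radii": (R, float("inf")),
        }
        return FixtureResult(mesh, None, truth)

    if kind == "saddle_patch":
        # Inner-equator patch of a torus: both measurement-plane sections
        # through the probe are exact circles, one convex (+r_convex) and
        # one concave (r_concave < 0).
        r_convex = params.get("r_convex", 25.6)
        r_concave = params.get("r_concave", -15.7)
        n = params.get("n", 40)
        meridian = np.deg2rad(params.get("meridian_deg", 60.0))
        azimuth = np.deg2rad(params.get("azimuth_deg", 60.0))
        _check_positive(r_convex=r_convex)
        if r_concave >= 0:
            raise ValueError("r_concave must be negative for a saddle")
        a = r_convex
        R0 = a + abs(r_concave)
        psis = np.linspace(-meridian / 2.0, meridian / 2.0, n)
        phis = np.linspace(-azimuth / 2.0, azimuth / 2.0, n)

        def f(psi, phi):
            # torus about the x-axis; tube-centre circle in the yz-plane
            c = np.stack([np.zeros_like(phi), np.sin(phi), -np.cos(phi)], axis=-1)
            out = (R0 - a * np.cos(psi))[:, None] * c
            out[:, 0] = a * np.sin(psi)
            return out

        mesh = _grid_mesh(psis, phis, f)
        probe = np.array([0.0, 0.0, -(R0 - a)])
        mesh = _orient(mesh, probe, np.array([0.0, 0.0, 1.0]))
        truth = {
            "probe_point": probe,
            "probe_normal": np.array([0.0, 0.0, 1.0]),
            # measurement axis: AP plane ⊥ y gives the meridian circle (+a);
            # ML plane through the y-axis gives the equator circle (concave)
            "axis_point": np.zeros(3),
            "axis_direction": np.array([0.0, 1.0, 0.0]),
            "ap_radius": a,
            "ml_radius": -(R0 - a),
        }
        return FixtureResult(mesh, None, truth)

    if kind == "planar_ellipse":
        major = params.get("major_full", 24.2)
        minor = params.get("minor_full", 14.2)
        n_rings = params.get("n_rings", 30)
        n_seg = params.get("n_seg", 64)
        _check_positive(major_full=major, minor_full=minor)
        a, b = major / 2.0, minor / 2.0
        verts = [np.zeros(3)]
        for ring in range(1, n_rings + 1):
            s = ring / n_rings
            ang = np.linspace(0.0, 2.0 * np.pi, n_seg, endpoint=False)
            verts.append(np.column_stack([s * a * np.cos(ang), s * b * np.sin(ang), np.zeros(n_seg)]))
        verts = np.vstack(verts)
        faces = []
        for j in range(n_seg):
            faces.append([0, 1 + j, 1 + (j + 1) % n_seg])
        for ring in range(1, n_rings):
            o0 = 1 + (ring - 1) * n_seg
            o1 = 1 + ring * n_seg
            for j in range(n_seg):
                jn = (j + 1) % n_seg
                faces.append([o0 + j, o1 + j, o0 + jn])
                faces.append([o0 + jn, o1 + j, o1 + jn])
        mesh = SurfaceMesh(verts, np.asarray(faces, dtype=np.int64))
        truth = {
            "area": np.pi * a * b,
            "major_full": major,
            "minor_full": minor,
            "normal": np.array([0.0, 0.0, 1.0]),
        }
        return FixtureResult(mesh, None, truth)

    if kind == "exact_circle_points":
        R = params.get("radius", 5.0)
        n = params.get("n", 32)
        center = np.asarray(params.get("center", (0.0, 0.0, 0.0)), dtype=float)
        normal = np.asarray(params.get("normal", (0.0, 0.0, 1.0)), dtype=float)
        _check_positive(radius=R, n=n)
        normal = normal / np.linalg.norm(normal)
        helper = np.array([1.0, 0.0, 0.0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(normal, helper)
        u /= np.linalg.norm(u)
        v = np.cross(normal, u)
        ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        pts = center + R * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
        return FixtureResult(None, pts, {"radius": R, "center": center, "normal": normal})

    raise ValueError(f"unknown fixture kind {kind!r}")
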