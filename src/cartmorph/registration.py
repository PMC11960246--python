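"""Dense correspondence by rigid then non-rigid ICP registration.

The non-rigid stage is a stiffness-relaxed, locally affine ICP: every
reference vertex carries its own 3x4 affine transform, neighbouring
transforms are penalised for disagreeing (weighted by a stiffness that is
relaxed over a fixed schedule), and each step solves a sparse linear
least-squares system against the current closest-point matches.  The
deformed reference inherits the reference topology exactly, which is what
makes the downstream shape statistics possible.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .meshes import SurfaceMesh

__all__ = [
    "RigidICP",
    "NonRigidICP",
    "CorrespondedShapeSet",
    "rigid_icp",
    "nonrigid_correspond",
    "build_corresponded_set",
]


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, SurfaceMesh):
        return obj.vertices
    return np.asarray(obj, dtype=float)


def _target_samples(target) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample points on the target (vertices + face centroids) with normals
    and an on-boundary flag per sample."""
    if isinstance(target, SurfaceMesh):
        v = target.vertices
        centroids = v[target.faces].mean(axis=1)
        pts = np.vstack([v, centroids])
        normals = np.vstack([target.vertex_normals(), target.face_normals()])
        boundary = np.zeros(len(pts), dtype=bool)
        boundary[target.boundary_vertices()] = True
        return pts, normals, boundary
    pts = np.asarray(target, dtype=float)
    return pts, np.zeros_like(pts), np.zeros(len(pts), dtype=bool)


def _kabsch(src: np.ndarray, dst: np.ndarray, weights: np.ndarray | None = None):
    """Optimal rotation/translation mapping src onto dst (least squares)."""
    if weights is None:
        weights = np.ones(len(src))
    w = weights / weights.sum()
    cs = (src * w[:, None]).sum(axis=0)
    cd = (dst * w[:, None]).sum(axis=0)
    H = (src - cs).T @ ((dst - cd) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cd - R @ cs
    return R, t


class RigidICP(BaseEstimator):
    """Rigid iterative-closest-point registration.

    Parameters
    ----------
    max_iter : int
        Iteration cap.
    tol : float
        Stop when the mean closest-point residual improves by less than this
        (mm).

    Attributes
    ----------
    rotation_ : (3, 3) ndarray
    translation_ : (3,) ndarray
    residual_ : float, final mean closest-point distance (mm)
    residual_history_ : list of per-iteration residuals (non-increasing)
    n_iter_ : int
    """

    def __init__(self, max_iter: int = 60, tol: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, source, target) -> "RigidICP":
        src = _as_points(source)
        tgt_pts, _, _ = _target_samples(target)
        if len(src) < 3 or len(tgt_pts) < 3:
            raise ValueError("need at least 3 points on both source and target")
        tree = cKDTree(tgt_pts)
        R = np.eye(3)
        t = tgt_pts.mean(axis=0) - src.mean(axis=0)  # centroid pre-alignment
        history = []
        cur = src + t
        for it in range(self.max_iter):
            dists, idx = tree.query(cur)
            if len(np.unique(idx)) < 3:
                raise ValueError("fewer than 3 distinct closest-point pairs")
            history.append(float(dists.mean()))
            if it > 0 and history[-2] - history[-1] < self.tol:
                break
            Rs, ts = _kabsch(src, tgt_pts[idx])
            cur = src @ Rs.T + ts
            R, t = Rs, ts
        dists, _ = tree.query(cur)
        self.rotation_ = R
        self.translation_ = t
        self.residual_ = float(dists.mean())
        self.residual_history_ = history
        self.n_iter_ = len(history)
        return self

    def transform(self, points) -> np.ndarray:
        return _as_points(points) @ self.rotation_.T + self.translation_


def rigid_icp(source, target, max_iter: int = 60, tol: float = 1e-8):
    """Functional wrapper: returns (rotation, translation, residual)."""
    est = RigidICP(max_iter=max_iter, tol=tol).fit(source, target)
    return est.rotation_, est.translation_, est.residual_


class NonRigidICP(BaseEstimator):
    """Locally affine non-rigid ICP with a decreasing stiffness schedule.

    Each reference vertex i carries an affine X_i (4x3); the objective is

        || W (D X - U) ||²  +  alpha² || (M ⊗ G) X ||²

    where D stacks homogeneous vertex rows, U the matched target points, W
    correspondence weights, M the edge incidence matrix of the reference and
    G = diag(1, 1, 1, gamma).  alpha walks down ``stiffness_schedule``.
    Matches are gated on normal compatibility (> ``normal_gate_deg`` apart
    rejected) and matches landing on the target boundary are flagged rather
    than trusted.

    Attributes
    ----------
    vertices_ : (m, 3) deformed reference vertices (reference topology)
    valid_mask_ : (m,) bool, False where the final match was gated/boundary
    residual_ : float, mean distance of valid vertices to their matches (mm)
    converged_ : bool
    """

    def __init__(
        self,
        stiffness_schedule: tuple = (50.0, 25.0, 12.0, 6.0, 3.0, 1.5, 0.8, 0.4),
        inner_iter: int = 10,
        tol: float = 1e-4,
        gamma: float = 1.0,
        normal_gate_deg: float = 60.0,
        distance_gate: float | None = None,
    ):
        self.stiffness_schedule = stiffness_schedule
        self.inner_iter = inner_iter
        self.tol = tol
        self.gamma = gamma
        self.normal_gate_deg = normal_gate_deg
        self.distance_gate = distance_gate

    def fit(self, reference: SurfaceMesh, target: SurfaceMesh) -> "NonRigidICP":
        ref = reference
        m = ref.n_vertices
        edges = ref.edges_unique()
        n_e = len(edges)

        tgt_pts, tgt_normals, tgt_boundary = _target_samples(target)
        tree = cKDTree(tgt_pts)
        gate_cos = np.cos(np.deg2rad(self.normal_gate_deg))
        dist_gate = self.distance_gate
        if dist_gate is None:
            dist_gate = 10.0 * ref.mean_edge_length()

        # stiffness block: M ⊗ G
        rows = np.repeat(np.arange(n_e), 2)
        cols = edges.ravel()
        vals = np.tile([1.0, -1.0], n_e)
        M = sp.coo_matrix((vals, (rows, cols)), shape=(n_e, m))
        G = sp.diags([1.0, 1.0, 1.0, self.gamma])
        MG = sp.kron(M, G).tocsr()

        X = np.tile(np.vstack([np.eye(3), np.zeros(3)]), (m, 1))  # (4m, 3)
        faces = ref.faces
        converged = True
        for alpha in self.stiffness_schedule:
            stiff = (alpha * MG).tocsr()
            prev = None
            for _ in range(self.inner_iter):
                cur = self._deform(ref.vertices, X)
                cur_mesh = SurfaceMesh(cur, faces)
                src_normals = cur_mesh.vertex_normals()
                dists, idx = tree.query(cur)
                w = np.ones(m)
                ncos = np.einsum("ij,ij->i", src_normals, tgt_normals[idx])
                w[ncos < gate_cos] = 0.0
                w[dists > dist_gate] = 0.0
                w[tgt_boundary[idx]] = 0.0
                if w.sum() < 4:
                    w = np.ones(m)  # fully gated: fall back to unweighted
                D = self._dmatrix(ref.vertices)
                WD = sp.diags(w) @ D
                U = tgt_pts[idx] * w[:, None]
                A = sp.vstack([stiff, WD]).tocsc()
                B = np.vstack([np.zeros((stiff.shape[0], 3)), U])
                AtA = (A.T @ A).tocsc()
                AtB = A.T @ B
                X_new = np.column_stack([spsolve(AtA, AtB[:, k]) for k in range(3)])
                delta = float(np.abs(X_new - X).max())
                X = X_new
                if prev is not None and delta < self.tol:
                    break
                prev = delta
            else:
                converged = converged and (prev is not None and prev < 10 * self.tol)

        cur = self._deform(ref.vertices, X)
        dists, idx = tree.query(cur)
        src_normals = SurfaceMesh(cur, faces).vertex_normals()
        ncos = np.einsum("ij,ij->i", src_normals, tgt_normals[idx])
        valid = (ncos >= gate_cos) & (dists <= dist_gate) & (~tgt_boundary[idx])
        self.vertices_ = cur
        self.valid_mask_ = valid
        self.residual_ = float(dists[valid].mean()) if valid.any() else float(dists.mean())
        self.converged_ = converged
        return self

    @staticmethod
    def _dmatrix(vertices: np.ndarray) -> sp.csr_matrix:
        m = len(vertices)
        rows = np.repeat(np.arange(m), 4)
        cols = np.arange(4 * m)
        vals = np.column_stack([vertices, np.ones(m)]).ravel()
        return sp.coo_matrix((vals, (rows, cols)), shape=(m, 4 * m)).tocsr()

    @staticmethod
    def _deform(vertices: np.ndarray, X: np.ndarray) -> np.ndarray:
        m = len(vertices)
        H = np.column_stack([vertices, np.ones(m)])  # (m, 4)
        Xb = X.reshape(m, 4, 3)
        return np.einsum("mk,mkj->mj", H, Xb)


def nonrigid_correspond(reference: SurfaceMesh, target: SurfaceMesh, **kwargs):
    """Deform ``reference`` onto ``target``; returns (vertices, valid_mask,
    residual).  The output shares the reference topology."""
    est = NonRigidICP(**kwargs).fit(reference, target)
    return est.vertices_, est.valid_mask_, est.residual_


@dataclasses.dataclass
class CorrespondedShapeSet:
    """k shapes sharing one topology: the input to GPA/PCA."""

    shapes: np.ndarray               # (k, m, 3)
    faces: np.ndarray                # shared face list
    reference_index: int
    residuals: np.ndarray            # per-shape registration residual, mm
    excluded: list                   # indices failing the residual tolerance
    face_labels: np.ndarray | None = None

    @property
    def n_shapes(self) -> int:
        return len(self.shapes)

    @property
    def n_vertices(self) -> int:
        return self.shapes.shape[1]

    def meshes(self):
        return [SurfaceMesh(s, self.faces, face_labels=self.face_labels) for s in self.shapes]


def build_corresponded_set(
    meshes,
    reference_index: int | None = None,
    seed: int | None = None,
    residual_tolerance: float = 1.0,
    skip_nonrigid: bool = False,
    rigid_kwargs: dict | None = None,
    nonrigid_kwargs: dict | None = None,
) -> CorrespondedShapeSet:
    """Register every mesh to a reference and collect corresponded shapes.

    The reference is ``reference_index`` if given, otherwise a seeded random
    choice.  The reference is rigidly aligned to each target, then deformed
    non-rigidly; the deformed reference vertices are that target's
    corresponded shape.  With ``skip_nonrigid=True`` the meshes are assumed
    to already share the reference topology (e.g. a synthetic cohort) and
    only the shape arrays are collected; alignment is left to GPA.
    """
    meshes = list(meshes)
    if len(meshes) < 3:
        raise ValueError("need at least 3 meshes")
    if reference_index is None:
        rng = np.random.default_rng(seed)
        reference_index = int(rng.integers(len(meshes)))
    ref = meshes[reference_index]

    if skip_nonrigid:
        for mesh in meshes:
            if mesh.n_vertices != ref.n_vertices:
                raise ValueError("skip_nonrigid requires a shared topology")
        shapes = np.stack([m.vertices for m in meshes])
        residuals = np.zeros(len(meshes))
        return CorrespondedShapeSet(
            shapes, ref.faces.copy(), reference_index, residuals, [],
            face_labels=ref.face_labels,
        )

    shapes = []
    residuals = []
    excluded = []
    for i, mesh in enumerate(meshes):
        if i == reference_index:
            shapes.append(ref.vertices.copy())
            residuals.append(0.0)
            continue
        rigid = RigidICP(**(rigid_kwargs or {})).fit(ref, mesh)
        moved = SurfaceMesh(rigid.transform(ref.vertices), ref.faces)
        nr = NonRigidICP(**(nonrigid_kwargs or {})).fit(moved, mesh)
        shapes.append(nr.vertices_)
        residuals.append(nr.residual_)
        if nr.residual_ > residual_tolerance:
            excluded.append(i)
    return CorrespondedShapeSet(
        np.stack(shapes), ref.faces.copy(), reference_index,
        np.asarray(residuals), excluded, face_labels=ref.face_labels,
    )
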