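"""Generalised Procrustes alignment and the PCA statistical shape model.

A corresponded shape set (k shapes, m shared vertices) is aligned by
iterative GPA — translations and rotations are removed; scale is kept by
default because overall cartilage size is real anatomical variation — and
decomposed by PCA of the vertex covariance.  A new instance is synthesised
as ``S = S̄ + P b`` where S̄ is the mean shape, the columns of P are the
orthonormal modes of variation and b the per-mode coefficients.  Sampling b
from N(0, diag(λ)) generates an artificial population.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .meshes import SurfaceMesh

__all__ = [
    "GeneralizedProcrustes",
    "StatisticalShapeModel",
    "SsmEvaluation",
    "gpa",
    "build_ssm",
    "evaluate_ssm",
    "similarity_procrustes",
    "ap_ml_dimensions",
]


def _as_stack(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:  # (k, 3m)
        X = X.reshape(len(X), -1, 3)
    if X.ndim != 3 or X.shape[2] != 3:
        raise ValueError("expected shapes of form (k, m, 3) or (k, 3m)")
    return X


def _orthogonal_polar(A: np.ndarray) -> np.ndarray:
    """Nearest rotation to A (special orthogonal polar factor)."""
    U, _, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


def similarity_procrustes(source: np.ndarray, target: np.ndarray, with_scaling: bool = True):
    """Closed-form similarity (or rigid) Procrustes fit of corresponded
    point sets: returns (scale, rotation, translation) minimising
    ``|| s R x + t - y ||²``."""
    src = np.asarray(source, dtype=float)
    dst = np.asarray(target, dtype=float)
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    A = (dst - cd).T @ (src - cs)
    U, S, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    if with_scaling:
        denom = ((src - cs) ** 2).sum()
        scale = float((S * [1.0, 1.0, d]).sum() / denom)
    else:
        scale = 1.0
    t = cd - scale * R @ cs
    return scale, R, t


class GeneralizedProcrustes(BaseEstimator, TransformerMixin):
    """Iterative generalised Procrustes alignment of corresponded shapes.

    ``with_scaling=False`` (the default) preserves each shape's centroid
    size exactly; only translation and rotation are removed.

    Attributes
    ----------
    aligned_ : (k, m, 3) aligned shapes
    mean_ : (m, 3) mean shape of the aligned set
    rotations_, translations_, scales_ : per-shape applied transforms
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, with_scaling: bool = False, tol: float = 1e-9, max_iter: int = 200):
        self.with_scaling = with_scaling
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None) -> "GeneralizedProcrustes":
        shapes = _as_stack(X)
        k, m, _ = shapes.shape
        if k < 2:
            raise ValueError("need at least 2 shapes")
        centroids = shapes.mean(axis=1)
        centered = shapes - centroids[:, None, :]
        sizes = np.sqrt((centered**2).sum(axis=(1, 2)))

        aligned = centered.copy()
        rotations = np.tile(np.eye(3), (k, 1, 1))
        scales = np.ones(k)
        mean = aligned[0].copy()
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            for i in range(k):
                A = mean.T @ centered[i]
                U, S, Vt = np.linalg.svd(A)
                d = np.sign(np.linalg.det(U @ Vt))
                R = U @ np.diag([1.0, 1.0, d]) @ Vt
                if self.with_scaling:
                    s = float((S * [1.0, 1.0, d]).sum() / (centered[i] ** 2).sum())
                else:
                    s = 1.0
                rotations[i] = R
                scales[i] = s
                aligned[i] = s * centered[i] @ R.T
            new_mean = aligned.mean(axis=0)
            if self.with_scaling:
                # keep the mean at the average input centroid size
                target_size = sizes.mean()
                new_mean *= target_size / np.sqrt((new_mean**2).sum())
            delta = float(np.abs(new_mean - mean).max())
            mean = new_mean
            if delta < self.tol:
                converged = True
                break
        self.aligned_ = aligned
        self.mean_ = mean
        self.rotations_ = rotations
        self.scales_ = scales
        self.translations_ = -np.einsum("kij,kj->ki", rotations, centroids) * scales[:, None]
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.final_delta_ = delta
        return self

    def transform(self, X) -> np.ndarray:
        """Align new corresponded shapes to the fitted mean (no scaling
        unless the aligner was built with scaling)."""
        shapes = _as_stack(X)
        out = np.empty_like(shapes)
        for i, shape in enumerate(shapes):
            s, R, t = similarity_procrustes(shape, self.mean_, with_scaling=self.with_scaling)
            out[i] = s * shape @ R.T + t
        return out

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X).aligned_


def gpa(shapes, with_scaling: bool = False):
    """Functional wrapper: returns (aligned, per-shape transforms, mean)."""
    est = GeneralizedProcrustes(with_scaling=with_scaling).fit(shapes)
    transforms = [
        {"scale": float(s), "rotation": R, "translation": t}
        for s, R, t in zip(est.scales_, est.rotations_, est.translations_)
    ]
    return est.aligned_, transforms, est.mean_


class StatisticalShapeModel(BaseEstimator, TransformerMixin):
    """PCA statistical shape model of corresponded, aligned shapes.

    Fitting performs a thin SVD of the centred (k, 3m) data matrix; modes
    with negligible variance are dropped.  ``transform`` projects shapes to
    mode coefficients b, ``inverse_transform`` synthesises ``S̄ + P b``.

    Attributes
    ----------
    mean_ : (3m,) mean shape vector
    components_ : (q, 3m) orthonormal modes (rows)
    explained_variance_ : (q,) mode variances λ, descending, mm²
    n_modes_ : int
    faces_ : shared topology if provided at fit time
    """

    def __init__(self, n_modes: int | None = None, variance_tol: float = 1e-12):
        self.n_modes = n_modes
        self.variance_tol = variance_tol

    def fit(self, X, y=None, faces=None, face_labels=None) -> "StatisticalShapeModel":
        shapes = _as_stack(X)
        k = len(shapes)
        if k < 3:
            raise ValueError("need at least 3 shapes")
        flat = shapes.reshape(k, -1)
        mean = flat.mean(axis=0)
        centered = flat - mean
        U, S, Vt = np.linalg.svd(centered, full_matrices=False)
        variances = S**2 / (k - 1)
        # negligible relative to the leading mode, with an absolute floor
        # tied to the shape scale (an all-identical set has zero modes)
        floor = self.variance_tol * max(1.0, float((mean**2).mean()))
        scale = variances[0] if variances.size and variances[0] > floor else np.inf
        keep = variances > self.variance_tol * scale
        keep[min(k - 1, len(keep)):] = False  # at most k-1 meaningful modes
        q = int(keep.sum())
        if self.n_modes is not None:
            q = min(q, self.n_modes)
        self.mean_ = mean
        self.components_ = Vt[:q]
        self.explained_variance_ = variances[:q]
        self.n_modes_ = q
        self.n_vertices_ = shapes.shape[1]
        self.faces_ = faces
        self.face_labels_ = face_labels
        self.total_variance_ = float(variances.sum())
        return self

    # -- Eq. S = S̄ + P b -------------------------------------------------
    def transform(self, X) -> np.ndarray:
        shapes = _as_stack(X).reshape(-1, 3 * self.n_vertices_)
        return (shapes - self.mean_) @ self.components_.T

    def inverse_transform(self, b, n_modes: int | None = None) -> np.ndarray:
        b = np.atleast_2d(np.asarray(b, dtype=float))
        if b.shape[1] > self.n_modes_:
            raise ValueError(f"b has {b.shape[1]} entries but the model has {self.n_modes_} modes")
        q = b.shape[1] if n_modes is None else min(n_modes, b.shape[1])
        flat = self.mean_ + b[:, :q] @ self.components_[:q]
        return flat.reshape(len(b), self.n_vertices_, 3)

    def synthesize(self, b) -> SurfaceMesh:
        """Instantiate one shape from coefficients b on the model topology."""
        verts = self.inverse_transform(np.zeros(0) if b is None else b)[0]
        return SurfaceMesh(verts, self.faces_, face_labels=self.face_labels_)

    def mean_mesh(self) -> SurfaceMesh:
        return SurfaceMesh(
            self.mean_.reshape(-1, 3), self.faces_, face_labels=self.face_labels_
        )

    def sample_coefficients(
        self, n: int, random_state=None, truncation_sd: float = 3.0
    ) -> np.ndarray:
        """Draw b_i ~ N(0, λ_i), truncated at ±truncation_sd·√λ_i."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(random_state)
        sd = np.sqrt(self.explained_variance_)
        z = rng.standard_normal((n, self.n_modes_))
        z = np.clip(z, -truncation_sd, truncation_sd)
        return z * sd

    def sample_population(
        self, n: int, random_state=None, truncation_sd: float = 3.0
    ) -> list:
        """Generate n artificial shape instances (all modes used)."""
        b = self.sample_coefficients(n, random_state=random_state, truncation_sd=truncation_sd)
        shapes = self.inverse_transform(b)
        return [SurfaceMesh(s, self.faces_, face_labels=self.face_labels_) for s in shapes]


def build_ssm(aligned_shapes, faces=None, face_labels=None) -> StatisticalShapeModel:
    return StatisticalShapeModel().fit(aligned_shapes, faces=faces, face_labels=face_labels)


@dataclasses.dataclass
class SsmEvaluation:
    """Compactness / accuracy / generalisation curves vs number of modes."""

    mode_counts: np.ndarray
    compactness: np.ndarray       # cumulative variance fraction
    accuracy_rms: np.ndarray      # training reconstruction RMS, mm
    generalisation_rms: np.ndarray | None  # leave-one-out RMS, mm

    def to_frame(self):
        import pandas as pd

        data = {
            "n_modes": self.mode_counts,
            "compactness": self.compactness,
            "accuracy_rms_mm": self.accuracy_rms,
        }
        if self.generalisation_rms is not None:
            data["generalisation_rms_mm"] = self.generalisation_rms
        return pd.DataFrame(data)


def _reconstruction_rms(model: StatisticalShapeModel, shapes: np.ndarray, q: int) -> float:
    """RMS vertex distance between shapes and their q-mode reconstructions."""
    b = model.transform(shapes)
    rec = model.inverse_transform(b[:, :q] if q else np.zeros((len(b), 0)))
    d2 = ((rec - shapes.reshape(rec.shape)) ** 2).sum(axis=2)
    return float(np.sqrt(d2.mean()))


def evaluate_ssm(
    aligned_shapes, model: StatisticalShapeModel | None = None, leave_one_out: bool = True
) -> SsmEvaluation:
    """Assess compactness, accuracy and (leave-one-out) generalisation."""
    shapes = _as_stack(aligned_shapes)
    k = len(shapes)
    if model is None:
        model = StatisticalShapeModel().fit(shapes)
    q_max = model.n_modes_
    counts = np.arange(1, q_max + 1)

    total = model.total_variance_
    compact = np.cumsum(model.explained_variance_) / total if total > 0 else np.ones(q_max)
    # the retained modes span all non-negligible variance: close the curve
    if q_max and total > 0:
        compact = compact / compact[-1]

    accuracy = np.array([_reconstruction_rms(model, shapes, q) for q in counts])

    generalisation = None
    if leave_one_out and k >= 4:
        q_loo = min(q_max, k - 2)
        errs = np.zeros((k, q_loo))
        for i in range(k):
            rest = np.delete(shapes, i, axis=0)
            sub = StatisticalShapeModel().fit(rest)
            held = shapes[i][None]
            for j, q in enumerate(range(1, q_loo + 1)):
                if q > sub.n_modes_:
                    errs[i, j] = errs[i, j - 1] if j else _reconstruction_rms(sub, held, sub.n_modes_)
                else:
                    errs[i, j] = _reconstruction_rms(sub, held, q)
        mean_err = errs.mean(axis=0)
        generalisation = np.concatenate([mean_err, np.full(q_max - q_loo, mean_err[-1])])
    return SsmEvaluation(counts, compact, accuracy, generalisation)


# -- anatomical dimensions -------------------------------------------------

def _point_line_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    d = b - a
    n = np.linalg.norm(d)
    if n < 1e-12:
        return float(np.linalg.norm(p - a))
    return float(np.linalg.norm(np.cross(p - a, d)) / n)


def ap_ml_dimensions(mesh: SurfaceMesh) -> tuple[float, float]:
    """Anteroposterior length and mediolateral width of a labelled mesh.

    AP: distance from the most anterior point (max y) to the line joining
    the most posterior point of each condyle.  ML: x-extent between the most
    medial point of the medial condyle and the most lateral point of the
    lateral condyle.  Requires ``medial_condyle`` / ``lateral_condyle`` face
    labels and the working frame (+x medial, +y anterior).
    """
    if mesh.face_labels is None:
        raise ValueError("condyle labels required")
    v = mesh.vertices
    med_idx = np.unique(mesh.faces[mesh.face_labels == "medial_condyle"])
    lat_idx = np.unique(mesh.faces[mesh.face_labels == "lateral_condyle"])
    if len(med_idx) == 0 or len(lat_idx) == 0:
        raise ValueError("both condyle labels must be present")
    anterior = v[np.argmax(v[:, 1])]
    post_med = v[med_idx[np.argmin(v[med_idx, 1])]]
    post_lat = v[lat_idx[np.argmin(v[lat_idx, 1])]]
    ap = _point_line_distance(anterior, post_med, post_lat)
    ml = float(v[med_idx, 0].max() - v[lat_idx, 0].min())
    return ap, ml
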