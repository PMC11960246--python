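"""Defect-location frequency heat maps on the mean shape.

Each native model is aligned to the mean shape with a similarity Procrustes
fit (scaling IS applied here, unlike during model construction), the same
transform is transferred verbatim to its paired defect model, and every
mean-shape vertex counts the defect surfaces passing within a distance
tolerance τ of it.  τ defaults to 1.0 mm — the coarsest voxel dimension of
the source imaging — because "overlap" needs an explicit metric on open
surface meshes where inside/outside is undefined.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .meshes import SurfaceMesh
from .shape_model import similarity_procrustes

__all__ = [
    "HeatMap",
    "align_to_mean",
    "transfer_to_defect",
    "defect_frequency",
    "export_heatmap",
]


@dataclasses.dataclass
class HeatMap:
    """Per-vertex defect overlap counts on the mean shape."""

    mean_mesh: SurfaceMesh
    counts: np.ndarray            # (m,) non-negative ints
    n_defects: int
    tau: float
    region_mask: np.ndarray | None = None  # vertices inside the region

    def argmax_vertex(self, region: str | None = None) -> int:
        """Index of the highest-count vertex, optionally within a labelled
        region of the mean mesh."""
        counts = self.counts
        if region is not None:
            mask = self.vertex_region_mask(region)
            if not mask.any():
                raise ValueError(f"no vertices in region {region!r}")
            idx = np.flatnonzero(mask)
            return int(idx[np.argmax(counts[idx])])
        return int(np.argmax(counts))

    def vertex_region_mask(self, region: str) -> np.ndarray:
        if self.mean_mesh.face_labels is None:
            raise ValueError("mean mesh carries no region labels")
        faces = self.mean_mesh.faces[self.mean_mesh.face_labels == region]
        mask = np.zeros(self.mean_mesh.n_vertices, dtype=bool)
        mask[np.unique(faces)] = True
        return mask


def align_to_mean(native_shapes, mean_shape: np.ndarray):
    """Similarity transforms (scale, rotation, translation) aligning each
    corresponded native shape to the mean shape."""
    mean = np.asarray(mean_shape, dtype=float)
    out = []
    for shape in native_shapes:
        s, R, t = similarity_procrustes(np.asarray(shape, dtype=float), mean, with_scaling=True)
        out.append({"scale": s, "rotation": R, "translation": t})
    return out


def transfer_to_defect(defect: SurfaceMesh, transform: dict) -> SurfaceMesh:
    """Apply a native model's alignment transform verbatim to its defect."""
    return defect.transformed(
        rotation=transform["rotation"],
        translation=transform["translation"],
        scale=transform["scale"],
    )


def _defect_distance(
    mean_vertices: np.ndarray, defect: SurfaceMesh, mask, band: float | None = None
) -> np.ndarray:
    """Unsigned closest-point distance from each mean vertex to the defect's
    articulating surface (exact point-to-triangle near the band)."""
    if mask is not None:
        sub = defect.submesh(np.asarray(mask, dtype=bool))
    else:
        sub = defect
    from ._geometry import distance_to_surface

    return distance_to_surface(mean_vertices, sub.vertices, sub.faces, band=band)


def defect_frequency(
    mean_mesh: SurfaceMesh,
    defects,
    tau: float = 1.0,
    articulating_masks=None,
) -> HeatMap:
    """Count, per mean-shape vertex, the defects passing within τ of it.

    ``defects`` are meshes already transformed to the mean-shape frame.
    ``articulating_masks`` optionally restricts each defect to its
    articulating faces (recommended; walls and bottom are segmentation
    artefacts, not surface damage).
    """
    defects = list(defects)
    if not defects:
        raise ValueError("empty defect list")
    if articulating_masks is None:
        articulating_masks = [
            (d.face_labels == "articulating") if d.face_labels is not None else None
            for d in defects
        ]
    counts = np.zeros(mean_mesh.n_vertices, dtype=np.int64)
    for defect, mask in zip(defects, articulating_masks):
        dist = _defect_distance(mean_mesh.vertices, defect, mask, band=tau)
        counts += (dist <= tau).astype(np.int64)
    return HeatMap(mean_mesh=mean_mesh, counts=counts, n_defects=len(defects), tau=tau)


def _colormap(values: np.ndarray, cmap: str = "viridis") -> np.ndarray:
    import matplotlib

    vmax = values.max()
    norm = values / vmax if vmax > 0 else np.zeros_like(values, dtype=float)
    rgba = matplotlib.colormaps[cmap](norm)
    return (rgba[:, :3] * 255).astype(np.uint8)


def export_heatmap(heatmap: HeatMap, path, cmap: str = "viridis", region: str | None = None):
    """Write the heat map as ASCII PLY (per-vertex count + 8-bit colour),
    a CSV of vertex index → count, and a JSON summary.

    Returns the three paths.  With ``region`` set, counts outside the region
    are still written but flagged in the CSV (in_region = 0).
    """
    path = Path(path)
    mesh = heatmap.mean_mesh
    counts = heatmap.counts.astype(float)
    colors = _colormap(counts, cmap)
    ply_path = path.with_suffix(".ply")
    with open(ply_path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float quality\n")
        fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v, c, col in zip(mesh.vertices, heatmap.counts, colors):
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {c} {col[0]} {col[1]} {col[2]}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")

    import pandas as pd

    in_region = np.ones(mesh.n_vertices, dtype=int)
    if region is not None:
        in_region = heatmap.vertex_region_mask(region).astype(int)
    csv_path = path.with_suffix(".csv")
    pd.DataFrame(
        {"vertex": np.arange(mesh.n_vertices), "count": heatmap.counts, "in_region": in_region}
    ).to_csv(csv_path, index=False)

    summary = {
        "n_defects": heatmap.n_defects,
        "tau_mm": heatmap.tau,
        "max_count": int(heatmap.counts.max()),
        "argmax_vertex": heatmap.argmax_vertex(region),
        "argmax_point": mesh.vertices[heatmap.argmax_vertex(region)].tolist(),
    }
    json_path = path.with_suffix(".json")
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return ply_path, csv_path, json_path
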