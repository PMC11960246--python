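"""End-to-end orchestration: cohort → correspondence → SSM → samples →
heat map → probe curvatures → reports.

Every stage reads and writes plain files under the run directory, so stages
can be re-run individually (the CLI exposes one subcommand per stage) and a
rerun from cached upstream outputs is bit-identical.  All randomness flows
from the single run seed through named child seeds.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .curvature import (
    feasible_probe_spacing,
    fit_cylinder,
    measure_roc,
    patch_dimensions,
    place_probe_points,
    select_posterior_articulating_surface,
)
from .heatmap import align_to_mean, defect_frequency, export_heatmap, transfer_to_defect
from .meshes import SurfaceMesh, defect_axes, defect_metrics_table, mirror_sagittal, read_mesh, write_mesh
from .registration import CorrespondedShapeSet, build_corresponded_set
from .shape_model import GeneralizedProcrustes, StatisticalShapeModel, ap_ml_dimensions, evaluate_ssm
from .synthetic import CohortConfig, generate_cohort, write_cohort

__all__ = ["RunConfig", "run_pipeline", "summarise_metrics", "load_cohort_dir"]

log = logging.getLogger("cartmorph")


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML round-trippable)."""

    mode: str = "synthetic"              # "synthetic" | "meshdir"
    out_dir: str = "cartmorph_run"
    seed: int = 0
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    mesh_dir: str | None = None          # meshdir mode: directory + manifest
    n_samples: int = 200
    tau_mm: float = 1.0
    patch_area_mm2: float = 270.0
    patch_aspect: float = 1.7
    n_probe_points: int = 5
    probe_spacing_mm: float | None = None
    correspondence: str = "auto"         # auto | skip | full
    residual_tolerance_mm: float = 1.0
    truncation_sd: float = 3.0
    trochlea_anchor: list | None = None  # optional (x, y, z) in mean frame
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("synthetic", "meshdir"):
            raise ValueError("mode must be 'synthetic' or 'meshdir'")
        if self.mode == "meshdir" and not self.mesh_dir:
            raise ValueError("meshdir mode requires mesh_dir")
        if self.mode == "synthetic" and self.mesh_dir:
            raise ValueError("exactly one input mode: drop mesh_dir for synthetic runs")
        if self.correspondence not in ("auto", "skip", "full"):
            raise ValueError("correspondence must be auto|skip|full")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def to_yaml(self, path) -> Path:
        import yaml

        payload = dataclasses.asdict(self)
        payload["cohort"]["mode_amplitudes"] = list(self.cohort.mode_amplitudes)
        payload["cohort"]["hotspot_center"] = list(self.cohort.hotspot_center)
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        cohort = payload.pop("cohort", {})
        cohort["mode_amplitudes"] = tuple(cohort.get("mode_amplitudes", (2.0, 1.0, 0.5)))
        cohort["hotspot_center"] = tuple(cohort.get("hotspot_center", (23.0, 0.9)))
        cfg = cls(**{**payload, "cohort": CohortConfig(**cohort)})
        cfg.validate()
        return cfg


def _child_seed(seed: int, stage: str) -> int:
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


# -- cohort I/O ------------------------------------------------------------

def load_cohort_dir(mesh_dir) -> list:
    """Load a cohort from a manifest directory, mirroring right-sided models
    back into the left-knee working frame."""
    mesh_dir = Path(mesh_dir)
    manifest = pd.read_csv(mesh_dir / "manifest.csv")
    out = []
    for row in manifest.itertuples():
        native = read_mesh(mesh_dir / row.native_path)
        defect = read_mesh(mesh_dir / row.defect_path)
        if row.side == "right":
            native = mirror_sagittal(native)
            defect = mirror_sagittal(defect)
        n_art = int(row.n_articulating_faces)
        mask = np.zeros(defect.n_faces, dtype=bool)
        mask[:n_art] = True
        out.append({"model_id": row.model_id, "native": native, "defect": defect,
                    "articulating_mask": mask, "side": row.side})
    return out


# -- stages ----------------------------------------------------------------

def stage_simulate(config: RunConfig, workdir: Path):
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    cohort = generate_cohort(cohort_cfg)
    write_cohort(cohort, workdir / "cohort")
    return cohort


def stage_correspond(config: RunConfig, workdir: Path, records: list) -> CorrespondedShapeSet:
    natives = [r["native"] for r in records]
    same_topo = len({m.n_vertices for m in natives}) == 1
    mode = config.correspondence
    skip = mode == "skip" or (mode == "auto" and same_topo)
    cset = build_corresponded_set(
        natives,
        seed=_child_seed(config.seed, "reference"),
        residual_tolerance=config.residual_tolerance_mm,
        skip_nonrigid=skip,
    )
    np.savez(
        workdir / "corresponded.npz",
        shapes=cset.shapes,
        faces=cset.faces,
        residuals=cset.residuals,
        reference_index=cset.reference_index,
        excluded=np.asarray(cset.excluded, dtype=np.int64),
    )
    return cset


def stage_ssm(config: RunConfig, workdir: Path, cset: CorrespondedShapeSet):
    aligner = GeneralizedProcrustes(with_scaling=False).fit(cset.shapes)
    model = StatisticalShapeModel().fit(
        aligner.aligned_, faces=cset.faces, face_labels=cset.face_labels
    )
    evaluation = evaluate_ssm(aligner.aligned_, model, leave_one_out=len(cset.shapes) >= 4)
    np.savez(
        workdir / "model.npz",
        mean=model.mean_,
        components=model.components_,
        variances=model.explained_variance_,
        faces=model.faces_,
    )
    write_mesh(model.mean_mesh(), workdir / "mean_shape.ply")
    evaluation.to_frame().to_csv(workdir / "ssm_evaluation.csv", index=False)
    return aligner, model, evaluation


def stage_sample(config: RunConfig, workdir: Path, model: StatisticalShapeModel, aligned):
    samples = model.sample_population(
        config.n_samples,
        random_state=_child_seed(config.seed, "sample"),
        truncation_sd=config.truncation_sd,
    )
    sample_dir = workdir / "samples"
    sample_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, mesh in enumerate(samples):
        write_mesh(mesh, sample_dir / f"sample_{i:03d}.ply")
        if mesh.face_labels is not None:
            ap, ml = ap_ml_dimensions(mesh)
            rows.append({"source": "sampled", "id": f"sample_{i:03d}", "ap_mm": ap, "ml_mm": ml})
    if model.face_labels_ is not None:
        for i, shape in enumerate(aligned):
            m = SurfaceMesh(shape, model.faces_, face_labels=model.face_labels_)
            ap, ml = ap_ml_dimensions(m)
            rows.append({"source": "input", "id": f"input_{i:03d}", "ap_mm": ap, "ml_mm": ml})
    if rows:
        pd.DataFrame(rows).to_csv(workdir / "ap_ml_dimensions.csv", index=False)
    return samples


def stage_heatmap(config: RunConfig, workdir: Path, cset, model, records):
    mean_shape = model.mean_.reshape(-1, 3)
    transforms = align_to_mean(cset.shapes, mean_shape)
    moved = [
        transfer_to_defect(
            SurfaceMesh(r["defect"].vertices, r["defect"].faces, face_labels=r["defect"].face_labels),
            tr,
        )
        for r, tr in zip(records, transforms)
    ]
    masks = [r["articulating_mask"] for r in records]
    mean_mesh = model.mean_mesh()
    hm = defect_frequency(mean_mesh, moved, tau=config.tau_mm, articulating_masks=masks)
    export_heatmap(hm, workdir / "heatmap_all")
    if mean_mesh.face_labels is not None:
        for region in ("medial_condyle", "lateral_condyle"):
            export_heatmap(hm, workdir / f"heatmap_{region}", region=region)
    return hm, moved, transforms


def stage_metrics(config: RunConfig, workdir: Path, records, moved_defects):
    recs = []
    sides = []
    for r, moved in zip(records, moved_defects):
        recs.append(defect_axes(r["defect"], r["articulating_mask"]))
        art_idx = np.unique(moved.faces[r["articulating_mask"]])
        sides.append("medial" if moved.vertices[art_idx, 0].mean() > 0 else "lateral")
    table = defect_metrics_table(recs, [r["model_id"] for r in records])
    table["condyle"] = sides
    table.to_csv(workdir / "defect_metrics.csv", index=False)
    summary = summarise_metrics(table, value_cols=("area_mm2", "major_mm", "minor_mm", "aspect"),
                                group_col="condyle")
    summary.to_csv(workdir / "defect_metrics_summary.csv", index=False)
    return table, summary


def _probe_anchors(config: RunConfig, hm, model):
    """Per-region probe anchor points on the mean shape: heat-map argmax for
    the condyles, user-supplied anchor for the trochlea."""
    mean_mesh = model.mean_mesh()
    anchors = {}
    if mean_mesh.face_labels is not None:
        for region, short in (("medial_condyle", "medial"), ("lateral_condyle", "lateral")):
            vi = hm.argmax_vertex(region)
            if hm.counts[vi] == 0:
                # no defect coverage in this region: a hotspot anchor would
                # be arbitrary, so no probes are placed there
                log.info("region %s has no defect overlap; skipping probes", region)
                continue
            anchors[short] = mean_mesh.vertices[vi]
    else:
        anchors["all"] = mean_mesh.vertices[hm.argmax_vertex()]
    if config.trochlea_anchor is not None:
        anchors["trochlea"] = np.asarray(config.trochlea_anchor, dtype=float)
    return anchors


def stage_curvature(config: RunConfig, workdir: Path, model, hm, samples):
    mean_mesh = model.mean_mesh()
    post_mean, _ = select_posterior_articulating_surface(
        mean_mesh, labels=("medial_condyle", "lateral_condyle") if mean_mesh.face_labels is not None else (),
    )
    cyl_mean = fit_cylinder(post_mean.vertices)
    anchors = _probe_anchors(config, hm, model)
    probe_vertex_ids = {}
    for region, anchor in anchors.items():
        spacing = config.probe_spacing_mm
        if spacing is None:
            # default: half the patch major axis, shrunk to fit the arc
            default = patch_dimensions(config.patch_area_mm2, config.patch_aspect)[0] / 2.0
            room = feasible_probe_spacing(mean_mesh, anchor, cyl_mean, config.n_probe_points)
            spacing = min(default, 0.98 * room)
        pts = place_probe_points(
            mean_mesh, anchor, cyl_mean, n=config.n_probe_points, spacing=spacing,
        )
        probe_vertex_ids[region] = [
            int(np.argmin(np.linalg.norm(mean_mesh.vertices - p, axis=1))) for p in pts
        ]

    rows = []
    for si, mesh in enumerate(samples):
        try:
            post, _ = select_posterior_articulating_surface(
                mesh, labels=("medial_condyle", "lateral_condyle") if mesh.face_labels is not None else (),
            )
            cyl = fit_cylinder(post.vertices)
        except ValueError:
            cyl = cyl_mean
        for region, vids in probe_vertex_ids.items():
            for pi, vid in enumerate(vids, start=1):
                probe = mesh.vertices[vid]
                try:
                    res = measure_roc(
                        mesh, probe, cyl,
                        patch_area_mm2=config.patch_area_mm2,
                        patch_aspect=config.patch_aspect,
                    )
                except ValueError:
                    continue
                rows.append({
                    "sample_id": f"sample_{si:03d}",
                    "region": region,
                    "probe_id": pi,
                    "x": probe[0], "y": probe[1], "z": probe[2],
                    "ap_radius_mm": res.ap_radius,
                    "ml_radius_mm": res.ml_radius,
                    "ap_residual_mm": res.ap_residual,
                    "ml_residual_mm": res.ml_residual,
                    "ap_flat": res.ap_flat,
                    "ml_flat": res.ml_flat,
                    "boundary_clipped": res.boundary_clipped,
                })
    long = pd.DataFrame(rows)
    long.to_csv(workdir / "roc_long.csv", index=False)
    if len(long):
        summary = (
            long.groupby(["region", "probe_id"])[["ap_radius_mm", "ml_radius_mm"]]
            .quantile([0.25, 0.5, 0.75])
            .unstack()
        )
        summary.columns = [f"{col}_q{int(q * 100)}" for col, q in summary.columns]
        summary.reset_index().to_csv(workdir / "roc_summary.csv", index=False)
    return long


def summarise_metrics(table, value_cols, group_col=None) -> pd.DataFrame:
    """Descriptive statistics (median, quartiles by linear interpolation,
    min/max) per metric and group; a pooled 'all' group is always included."""
    if isinstance(table, (list, np.ndarray)):
        table = pd.DataFrame({"value": np.asarray(table, dtype=float)})
        value_cols = ("value",)
    if len(table) == 0:
        raise ValueError("empty input")
    groups = [("all", table)]
    if group_col is not None:
        groups += [(name, g) for name, g in table.groupby(group_col)]
    rows = []
    for name, g in groups:
        for col in value_cols:
            v = g[col].to_numpy(dtype=float)
            rows.append({
                "group": name,
                "metric": col,
                "n": len(v),
                "median": float(np.quantile(v, 0.5)),
                "q1": float(np.quantile(v, 0.25)),
                "q3": float(np.quantile(v, 0.75)),
                "min": float(v.min()),
                "max": float(v.max()),
                "quantile_method": "linear",
            })
    return pd.DataFrame(rows)


# -- full run --------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run report."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    workdir = Path(config.out_dir)
    workdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(workdir / "run_config.yaml")
    report = {"version": __version__, "seed": config.seed, "stages": {}, "outputs": []}
    t_all = time.time()
    stage = "simulate"
    try:
        t0 = time.time()
        if config.mode == "synthetic":
            cohort = stage_simulate(config, workdir)
            records = [
                {"model_id": s.model_id, "native": s.native, "defect": s.defect,
                 "articulating_mask": s.articulating_mask, "side": s.truth.side}
                for s in cohort.samples
            ]
            # mirror right-sided members back into the working frame, as a
            # consumer of the exported cohort would using the manifest
            for r in records:
                if r["side"] == "right":
                    r["native"] = mirror_sagittal(r["native"])
                    r["defect"] = mirror_sagittal(r["defect"])
        else:
            records = load_cohort_dir(config.mesh_dir)
        report["stages"]["simulate"] = {"seconds": time.time() - t0, "n_models": len(records)}

        stage = "correspond"
        t0 = time.time()
        cset = stage_correspond(config, workdir, records)
        report["stages"]["correspond"] = {
            "seconds": time.time() - t0,
            "reference_index": cset.reference_index,
            "excluded": cset.excluded,
            "max_residual_mm": float(cset.residuals.max()),
        }

        stage = "ssm"
        t0 = time.time()
        aligner, model, evaluation = stage_ssm(config, workdir, cset)
        report["stages"]["ssm"] = {
            "seconds": time.time() - t0,
            "n_modes": model.n_modes_,
            "compactness_2_modes": float(evaluation.compactness[min(1, len(evaluation.compactness) - 1)])
            if len(evaluation.compactness) else None,
        }

        stage = "sample"
        t0 = time.time()
        samples = stage_sample(config, workdir, model, aligner.aligned_)
        report["stages"]["sample"] = {"seconds": time.time() - t0, "n_samples": len(samples)}

        stage = "heatmap"
        t0 = time.time()
        hm, moved, transforms = stage_heatmap(config, workdir, cset, model, records)
        report["stages"]["heatmap"] = {
            "seconds": time.time() - t0,
            "max_count": int(hm.counts.max()),
            "argmax_point": model.mean_.reshape(-1, 3)[hm.argmax_vertex()].tolist(),
        }

        stage = "metrics"
        t0 = time.time()
        table, summary = stage_metrics(config, workdir, records, moved)
        med = summary[(summary.group == "all") & (summary.metric == "area_mm2")]["median"]
        report["stages"]["metrics"] = {
            "seconds": time.time() - t0,
            "median_defect_area_mm2": float(med.iloc[0]),
        }

        stage = "curvature"
        t0 = time.time()
        roc = stage_curvature(config, workdir, model, hm, samples)
        report["stages"]["curvature"] = {"seconds": time.time() - t0, "n_measurements": len(roc)}
    except Exception as exc:
        (workdir / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    report["seconds_total"] = time.time() - t_all
    report["outputs"] = sorted(
        str(p.relative_to(workdir)) for p in workdir.rglob("*") if p.is_file()
    )
    with open(workdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
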