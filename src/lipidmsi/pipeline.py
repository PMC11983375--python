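"""End-to-end orchestration of the imaging-lipidomics analysis.

Stage order follows the processing chain used for calibrated SIMS images:
per-image averaged TIC spectra -> dual-range peak table -> per-pixel
centroiding -> sum-normalization + square root -> k=2 substrate mask ->
composite assembly -> imaging PCA / k-means with difference spectra ->
accurate-mass annotation -> report.  Every stage's outputs are written with a
manifest (config hash, seeds, stage artifacts) so deterministic stages rerun
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, msio, mva, peaks, preprocess, synthetic

logger = logging.getLogger(__name__)


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name and a remediation hint."""

    def __init__(self, stage: str, cause: Exception, hint: str):
        super().__init__(f"stage {stage!r} failed: {cause} (hint: {hint})")
        self.stage = stage
        self.hint = hint


@dataclass
class PipelineConfig:
    """Everything the pipeline needs beyond its inputs; all seeds recorded."""

    picker: peaks.PickerParams = field(default_factory=peaks.PickerParams)
    analysis_range: tuple[float, float] = (590.0, 1190.0)
    mask_seed: int = 0
    n_components: int = 8
    k: int = 3
    k_sweep: tuple[int, int] | None = None
    mva_seed: int = 0
    annotation_window: float = 0.01
    ps_threshold_frac: float = 0.01
    ion_image_peaks: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["picker"] = dataclasses.asdict(self.picker)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "picker" in d and isinstance(d["picker"], dict):
            p = dict(d["picker"])
            if "ranges" in p:
                p["ranges"] = tuple(tuple(r) for r in p["ranges"])
            d["picker"] = peaks.PickerParams(**p)
        if "analysis_range" in d:
            d["analysis_range"] = tuple(d["analysis_range"])
        if "k_sweep" in d and d["k_sweep"] is not None:
            d["k_sweep"] = tuple(d["k_sweep"])
        if "ion_image_peaks" in d:
            d["ion_image_peaks"] = tuple(d["ion_image_peaks"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineRun:
    """In-memory handles plus the on-disk manifest of one pipeline execution."""

    config: PipelineConfig
    outdir: Path
    manifest: dict
    peak_table: peaks.PeakTable
    composite: msio.CompositeImage
    pca: mva.PcaModel
    kmeans: mva.ClusterModel
    sweep: dict[int, mva.ClusterModel]
    differences: mva.DifferenceSpectra
    assignments: list[annotation.Assignment]
    accuracy: annotation.AccuracySummary | None


def _stage(name: str, hint: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageFailure:
                raise
            except Exception as exc:
                raise StageFailure(name, exc, hint) from exc

        return wrapped

    return deco


def run_pipeline(
    config: PipelineConfig,
    scene_spec: synthetic.SceneSpec | None = None,
    imzml_paths: list | None = None,
    outdir: str | Path = "lipidmsi_run",
) -> PipelineRun:
    """Execute the full analysis on a synthetic scene or a set of imzML files."""
    if (scene_spec is None) == (imzml_paths is None):
        raise ValueError("provide exactly one of scene_spec or imzml_paths")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def record(name: str, artifacts: list[str], **info):
        stages.append({"stage": name, "artifacts": artifacts, **info})
        logger.info("stage %s done (%s)", name, ", ".join(artifacts) or "no files")

    # --- stage 1: inputs -------------------------------------------------
    ground_truth = None
    if scene_spec is not None:
        scene = synthetic.make_scene(scene_spec)
        cube, ground_truth = synthetic.simulate_cube(scene)
        cubes = synthetic.member_cubes(cube, scene_spec)
        gt_path = outdir / "ground_truth.csv"
        pd.DataFrame(
            {
                "pixel": np.arange(len(ground_truth.region_labels)),
                "member": ground_truth.member_index,
                "region": [
                    ground_truth.region_names[c] for c in ground_truth.region_labels
                ],
            }
        ).to_csv(gt_path, index=False)
        record(
            "input",
            [gt_path.name],
            kind="synthetic",
            seed=scene_spec.seed,
            n_pixels=cube.n_pixels,
            n_members=len(cubes),
        )
    else:
        cubes = [msio.read_imzml(p) for p in imzml_paths]
        record(
            "input",
            [],
            kind="imzml",
            n_members=len(cubes),
            n_pixels=sum(c.n_pixels for c in cubes),
        )

    # --- stage 2: averaged spectra + dual-range peak table ----------------
    @_stage("peak_table", "check analysis_range against the data's m/z range")
    def _peak_table():
        lo, hi = config.analysis_range
        pp = config.picker
        pp = dataclasses.replace(
            pp, ranges=tuple((max(a, lo), min(b, hi)) for a, b in pp.ranges if a < hi and b > lo)
        )
        grid = pp.grid()
        means = [peaks.mean_tic_spectrum(c, grid) for c in cubes]
        table = peaks.build_peak_tables(means, grid, pp)
        return table

    table = _peak_table()
    table_path = outdir / "peak_table.csv"
    table.to_csv(table_path)
    record("peak_table", [table_path.name], n_centroids=len(table))

    # --- stage 3: per-pixel centroiding -----------------------------------
    @_stage("centroid", "peak table windows must lie within the cube's m/z range")
    def _centroid():
        return [peaks.centroid_image(c, table) for c in cubes]

    raw_images = _centroid()
    record("centroid", [], n_images=len(raw_images))

    # --- stage 4: normalization + substrate masking ------------------------
    @_stage("preprocess", "images with a single uniform profile cannot be masked")
    def _preprocess():
        normed = [preprocess.normalize_pixels(fi) for fi in raw_images]
        composite_raw = msio.assemble_composite(raw_images)
        composite_norm = msio.assemble_composite(normed)
        mask = preprocess.substrate_mask(
            composite_norm.image, tic=composite_raw.image.tic(), seed=config.mask_seed
        )
        composite_norm.image = preprocess.apply_mask(composite_norm.image, mask)
        return composite_norm, mask

    composite, mask = _preprocess()
    mask_path = outdir / "mask.csv"
    pd.DataFrame(
        {"pixel": np.arange(len(mask.mask)), "tissue": mask.mask.astype(int)}
    ).to_csv(mask_path, index=False)
    record(
        "preprocess",
        [mask_path.name],
        n_tissue=int(mask.mask.sum()),
        n_substrate=int((~mask.mask).sum()),
        mask_seed=config.mask_seed,
    )

    # --- stage 5: composite manifest ---------------------------------------
    manifest_path = outdir / "composite_manifest.csv"
    composite.manifest().to_csv(manifest_path, index=False)
    record("composite", [manifest_path.name], n_pixels=composite.n_member_pixels)

    # --- stage 6: multivariate analysis -------------------------------------
    @_stage("mva", "reduce n_components or k for very small images")
    def _mva():
        pca = mva.run_pca(composite.image, n_components=config.n_components)
        km = mva.run_kmeans(composite.image, k=config.k, seed=config.mva_seed)
        sweep = {}
        if config.k_sweep is not None:
            a, b = config.k_sweep
            sweep = mva.kmeans_sweep(composite.image, range(a, b + 1), seed=config.mva_seed)
        diffs = mva.difference_spectra(km, composite.image)
        return pca, km, sweep, diffs

    pca, km, sweep, diffs = _mva()
    mva_files = []
    loadings_path = outdir / "pca_loadings.csv"
    pd.DataFrame(
        pca.loadings.T,
        columns=[f"PC{i + 1}" for i in range(pca.n_components)],
    ).assign(mz_center=table.mz_center).to_csv(loadings_path, index=False)
    mva_files.append(loadings_path.name)
    labels_path = outdir / "kmeans_labels.csv"
    np.savetxt(labels_path, km.label_image(), fmt="%d", delimiter=",")
    mva_files.append(labels_path.name)
    diff_path = outdir / "difference_spectra.csv"
    pd.DataFrame(
        {"mz_center": table.mz_center}
        | {f"cluster{c}": v for c, v in diffs.per_cluster.items()}
    ).to_csv(diff_path, index=False)
    mva_files.append(diff_path.name)
    record(
        "mva",
        mva_files,
        n_components=pca.n_components,
        k=km.k,
        inertia=km.inertia,
        mva_seed=config.mva_seed,
    )

    # --- stage 7: annotation -------------------------------------------------
    @_stage("annotation", "provide a lipid table covering the analysis range")
    def _annotate():
        db = annotation.build_hypotheses(annotation.load_lipid_table())
        assigns = annotation.annotate_peaks(
            table,
            db,
            window=config.annotation_window,
            ps_rule=True,
            ps_threshold=config.ps_threshold_frac * float(table.apex_intensity.max())
            if len(table)
            else None,
        )
        return assigns

    assignments = _annotate()
    assign_path = outdir / "assignments.csv"
    annotation.assignments_frame(assignments).to_csv(assign_path, index=False)
    accuracy = annotation.accuracy_summary(assignments) if assignments else None
    acc_path = outdir / "accuracy.json"
    with open(acc_path, "w") as fh:
        json.dump(
            {
                "mean_abs_ppm": accuracy.mean_abs_ppm if accuracy else None,
                "pct_below_5ppm": accuracy.pct_below_5ppm if accuracy else None,
                "n_assigned": len(assignments),
            },
            fh,
            indent=2,
        )
    record("annotation", [assign_path.name, acc_path.name], n_assigned=len(assignments))

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": {
            "scene": scene_spec.seed if scene_spec is not None else None,
            "mask": config.mask_seed,
            "mva": config.mva_seed,
        },
        "stages": stages,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return PipelineRun(
        config=config,
        outdir=outdir,
        manifest=manifest,
        peak_table=table,
        composite=composite,
        pca=pca,
        kmeans=km,
        sweep=sweep,
        differences=diffs,
        assignments=assignments,
        accuracy=accuracy,
    )


def report(run: PipelineRun, components: tuple[int, ...] = (1, 2), top_n: int = 12) -> Path:
    """Render a human-readable summary of a completed run.

    Writes score/label images (PNG), difference-spectra plots, and annotated
    loading tables; returns the path of the Markdown report.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = run.outdir
    lines = ["# lipidmsi run report", ""]
    lines.append(f"Config hash: `{run.manifest['config_hash']}`")
    lines.append(f"Centroids: {len(run.peak_table)}; members: {len(run.composite.members)}")
    lines.append("")

    by_measured = {round(a.measured_mz, 6): a for a in run.assignments}

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.imshow(run.kmeans.label_image(), interpolation="nearest")
    ax.set_title(f"k-means labels (k={run.kmeans.k})")
    ax.axis("off")
    fig.savefig(outdir / "kmeans_labels.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    lines.append("![k-means labels](kmeans_labels.png)")

    for comp in components:
        if comp > run.pca.n_components:
            continue
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.imshow(run.pca.score_image(comp), interpolation="nearest", cmap="PiYG")
        ax.set_title(f"PC{comp} scores")
        ax.axis("off")
        fig.savefig(outdir / f"pc{comp}_scores.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        lines.append(f"![PC{comp} scores](pc{comp}_scores.png)")

        rep = mva.loading_report(run.pca, comp, top_n)
        lines.append("")
        lines.append(f"## PC{comp} loading peaks")
        lines.append("")
        if run.assignments:
            names = []
            for mz in rep["mz_center"]:
                a = by_measured.get(round(float(mz), 6))
                names.append(a.hypothesis.species.name if a else "")
            rep = rep.assign(lipid=names)
        else:
            lines.append("(unannotated: annotation stage not run)")
        lines.append("```")
        lines.append(rep.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        lines.append("```")
        lines.append("")

    if run.accuracy is not None:
        lines.append(
            f"Mean mass accuracy of assignments: {run.accuracy.mean_abs_ppm:.1f} ppm; "
            f"{run.accuracy.pct_below_5ppm:.0f}% of assignments under 5 ppm."
        )

    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path
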