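"""End-to-end orchestration: register -> QC -> bin -> maps -> statistics.

``run_pipeline`` reads a study manifest, registers every marker set to the
shared contour, runs the alignment QC battery when a Feret table is
present, bins markers with the 2*A/n rule (or a manual bin side), writes
mean/CV/difference/q maps with sidecars, detects micro-regions of interest
and runs PCA.  Identical inputs + config yield identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment_qc import QcReport, run_qc
from .binning import (BinMatrix, MarkerSet, assemble_matrix,
                      grid_from_marker_sets, optimal_bin_area)
from .density_maps import (cv_map, difference_map, mean_map, qvalue_map,
                           render_map, write_sidecar)
from .geometry import Contour, polygon_area, register_to_anchor
from .io import (StudyManifest, read_contour, read_manifest, read_markers,
                 read_feret, write_bin_matrix)
from .topo_stats import MroiResult, detect_mroi, pca_topography

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Hard pipeline failure (e.g. QC rejects the section alignment)."""


@dataclass
class PipelineConfig:
    q_threshold: float = 0.1
    alpha: float = 0.05
    z_threshold: float = 3.0
    bin_side: float | None = None       # None -> 2*A/n formula
    n_policy: str = "mean"              # 'mean' per subject | 'total' pooled
    test: str = "anova"                 # per-bin test: 'anova' | 'kruskal'
    fdr_method: str = "bh"              # 'bh' | 'by'
    mask_out_of_contour: bool = True
    exclude_outliers: bool = False
    normalize: bool = False             # per-subject rate maps
    make_plots: bool = True
    force: bool = False                 # continue past QC hard failures
    seed: int = 0


@dataclass
class PipelineResult:
    out_dir: Path
    matrix: BinMatrix
    mroi: MroiResult
    qc: QcReport | None
    contour: Contour
    bin_side: float
    bin_policy: str
    paths: dict


def _registered_marker_sets(
    manifest: StudyManifest,
) -> tuple[list[MarkerSet], Contour]:
    entries = manifest.marker_entries
    if entries.empty:
        raise PipelineError("manifest contains no marker files")
    regions = entries[["region", "bregma_mm"]].drop_duplicates()
    if len(regions) > 1:
        raise PipelineError(
            "multiple (region, plane) combinations in one run are not "
            f"supported: {regions.values.tolist()}")
    region = entries["region"].iloc[0]
    bregma = entries["bregma_mm"].iloc[0]
    contour_raw = read_contour(manifest.contour_path(region, bregma))
    marker_sets = []
    contour = contour_raw
    for _, row in entries.iterrows():
        m = read_markers(manifest.resolve(row["path"]),
                         subject_id=row["subject_id"],
                         condition=row["condition"],
                         bregma_mm=row["bregma_mm"], region=row["region"])
        pts, contour = register_to_anchor(m.points, contour_raw)
        marker_sets.append(MarkerSet(
            subject_id=m.subject_id, condition=m.condition,
            bregma_mm=m.bregma_mm, region=m.region, points=pts, z=m.z,
            registered=True))
    return marker_sets, contour


def run_pipeline(
    manifest: StudyManifest | str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute the full analysis for one study manifest.

    Writes bin matrices, all maps with sidecars, the MROI table, PCA
    outputs, QC tables and a run log under ``out_dir``.  Raises
    :class:`PipelineError` on QC hard failure unless ``config.force``;
    partial results stay on disk next to a ``FAILED`` marker.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    if not isinstance(manifest, StudyManifest):
        manifest = read_manifest(manifest)
    try:
        return _run(manifest, out, cfg, paths)
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise


def _run(manifest: StudyManifest, out: Path, cfg: PipelineConfig,
         paths: dict) -> PipelineResult:
    logger.info("step 1/5: registering marker sets to the contour anchor")
    marker_sets, contour = _registered_marker_sets(manifest)

    logger.info("step 2/5: alignment QC on landmark Feret lengths")
    qc: QcReport | None = None
    if manifest.feret_path is not None:
        feret = read_feret(manifest.feret_path)
        qc = run_qc(feret, z_threshold=cfg.z_threshold, alpha=cfg.alpha,
                    exclude_outliers=cfg.exclude_outliers)
        qc.records.to_csv(out / "qc_records.tsv", sep="\t", index=False,
                          float_format="%.10g")
        qc.pair_tests.to_csv(out / "qc_plane_pairs.tsv", sep="\t", index=False,
                             float_format="%.10g")
        qc.condition_tests.to_csv(out / "qc_condition_anova.tsv", sep="\t",
                                  index=False, float_format="%.10g")
        paths["qc"] = "qc_records.tsv"
        if not qc.all_planes_distinct and not cfg.force:
            raise PipelineError(
                "QC failure: some Bregma planes are statistically "
                "indistinct; re-check section assignment or pass force")
        if not qc.all_planes_aligned and not cfg.force:
            raise PipelineError(
                "QC failure: Feret length differs across conditions at some "
                "plane (evidence of misalignment); pass force to continue")
        if cfg.exclude_outliers and qc.excluded:
            excluded_subjects = {s for s, _ in qc.excluded}
            marker_sets = [m for m in marker_sets
                           if m.subject_id not in excluded_subjects]
            logger.warning("excluded flagged subjects: %s",
                           sorted(excluded_subjects))

    logger.info("step 3/5: binning marker coordinates")
    area = polygon_area(contour)
    counts = [m.n_markers for m in marker_sets]
    if cfg.bin_side is not None:
        bin_side = float(cfg.bin_side)
        policy = "manual"
    else:
        n = float(np.mean(counts)) if cfg.n_policy == "mean" else float(sum(counts))
        bin_side = optimal_bin_area(area, n).bin_side
        policy = f"formula(n_policy={cfg.n_policy})"
    grid = grid_from_marker_sets(marker_sets, bin_side)
    matrix = assemble_matrix(marker_sets, grid)
    write_bin_matrix(matrix, out / "bin_matrix.tsv")
    paths["bin_matrix"] = "bin_matrix.tsv"

    logger.info("step 4/5: density, CV and difference maps")
    family = (grid.contour_mask(contour).ravel()
              if cfg.mask_out_of_contour else None)
    conditions = matrix.conditions
    maps = {}
    for cond in conditions:
        maps[cond] = mean_map(matrix, cond, normalize=cfg.normalize)
        _emit_map(maps[cond], out, f"mean_{cond}", cfg, contour, paths)
        if (matrix.meta["condition"] == cond).sum() >= 2:
            _emit_map(cv_map(matrix, cond), out, f"cv_{cond}", cfg, contour,
                      paths)
    if len(conditions) >= 2:
        diff = difference_map(maps[conditions[0]], maps[conditions[1]])
        _emit_map(diff, out, f"difference_{conditions[0]}_vs_{conditions[1]}",
                  cfg, contour, paths)

    logger.info("step 5/5: micro-ROI statistics and PCA")
    mroi = detect_mroi(matrix, q_threshold=cfg.q_threshold, family_mask=family,
                       test=cfg.test, fdr_method=cfg.fdr_method)
    mroi.table().to_csv(out / "mroi.tsv", sep="\t", index=False,
                        float_format="%.10g")
    paths["mroi"] = "mroi.tsv"
    qmap = qvalue_map(grid, np.nan_to_num(mroi.q, nan=1.0), mroi.family_mask)
    _emit_map(qmap, out, "qvalues", cfg, contour, paths)

    try:
        pca = pca_topography(matrix)
        pd.DataFrame(pca.scores,
                     index=pca.subject_ids).to_csv(out / "pca_scores.tsv",
                                                   sep="\t",
                                                   float_format="%.10g")
        pd.DataFrame(pca.loadings,
                     columns=grid.column_labels()).to_csv(
            out / "pca_loadings.tsv", sep="\t", index=False,
            float_format="%.10g")
        pd.DataFrame({"explained_variance_ratio":
                      pca.explained_variance_ratio}).to_csv(
            out / "pca_variance.tsv", sep="\t", index=False,
            float_format="%.10g")
        paths["pca"] = "pca_scores.tsv"
    except ValueError as exc:
        logger.warning("PCA skipped: %s", exc)

    run_log = {
        "package_version": __version__,
        "config": asdict(PipelineConfig(**asdict(cfg))),
        "bin_side_um": bin_side,
        "bin_policy": policy,
        "contour_area_um2": area,
        "n_marker_sets": len(marker_sets),
        "n_markers": counts,
        "conditions": conditions,
        "n_significant_bins": int(mroi.significant.sum()),
        "outputs": paths,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2,
                                                 sort_keys=True) + "\n")
    return PipelineResult(out, matrix, mroi, qc, contour, bin_side, policy,
                          paths)


def analyze_bundle(bundle, config: PipelineConfig | None = None):
    """In-memory register -> bin -> MROI for a synthetic study bundle.

    The computational core of :func:`run_pipeline` without file I/O or
    rendering; useful for simulation studies over many seeds.  Returns
    (MroiResult, BinMatrix).
    """
    cfg = config or PipelineConfig()
    contour_raw = bundle.contour
    marker_sets = []
    contour = contour_raw
    for m in bundle.marker_sets:
        pts, contour = register_to_anchor(m.points, contour_raw)
        marker_sets.append(MarkerSet(
            subject_id=m.subject_id, condition=m.condition,
            bregma_mm=m.bregma_mm, region=m.region, points=pts,
            registered=True))
    area = polygon_area(contour)
    counts = [m.n_markers for m in marker_sets]
    if cfg.bin_side is not None:
        bin_side = float(cfg.bin_side)
    else:
        n = float(np.mean(counts)) if cfg.n_policy == "mean" else float(sum(counts))
        bin_side = optimal_bin_area(area, n).bin_side
    grid = grid_from_marker_sets(marker_sets, bin_side)
    matrix = assemble_matrix(marker_sets, grid)
    family = (grid.contour_mask(contour).ravel()
              if cfg.mask_out_of_contour else None)
    mroi = detect_mroi(matrix, q_threshold=cfg.q_threshold, family_mask=family,
                       test=cfg.test, fdr_method=cfg.fdr_method)
    return mroi, matrix


def _emit_map(dmap, out: Path, stem: str, cfg: PipelineConfig,
              contour: Contour, paths: dict) -> None:
    if cfg.make_plots:
        render_map(dmap, out / f"{stem}.png", contour=contour)
    else:
        write_sidecar(dmap, out / f"{stem}.png.tsv")
    paths[stem] = f"{stem}.png.tsv"
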