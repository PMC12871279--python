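"""Orchestration of the automated four-step processing pipeline.

Stage order: (1) cell segmentation, (2) removal of low-quality cells,
(3) doublet detection, (4) mapping-score filtering. Filters annotate the
cell-by-gene matrix with boolean columns (``pass_qc``, ``pass_doublet``,
``pass_mapping``) rather than deleting rows; cells are dropped only in the
final export, so per-stage diagnostics stay reproducible from one artifact.
All thresholds are echoed into the output's unstructured metadata.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import assemble_cell_matrix
from .density import DensityParams, VolumeImage, bin_transcripts, smooth_density
from .doublets import call_doublets, score_doublets
from .mapping_filter import BimodalityParams, DoubleMadParams, filter_mapped_cells
from .qc import QcThresholds, apply_quality_filter, compute_cell_metrics
from .segmentation import (
    assign_transcripts,
    build_cell_polygons,
    make_tiles,
    segment_tile,
    stitch_and_merge,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "process_section", "run_pipeline"]


@dataclass
class RunConfig:
    """Serializable pipeline configuration (YAML-friendly)."""

    spots_path: Optional[str] = None
    dialect: str = "merscope_csv"
    mapping_scores_path: Optional[str] = None
    out_path: Optional[str] = None
    tile_size_um: float = 350.0
    overlap_um: float = 50.0
    backend: str = "builtin"
    qc: QcThresholds = field(default_factory=QcThresholds)
    density: DensityParams = field(default_factory=DensityParams)
    double_mad: DoubleMadParams = field(default_factory=DoubleMadParams)
    bimodality: BimodalityParams = field(default_factory=BimodalityParams)
    alpha_scale: float = 0.75
    seed: int = 0
    drop_filtered_on_export: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, typ in (("qc", QcThresholds), ("density", DensityParams),
                         ("double_mad", DoubleMadParams), ("bimodality", BimodalityParams)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        return cls(**kwargs)


def process_section(
    spots: pd.DataFrame,
    dapi: VolumeImage,
    cfg: RunConfig | None = None,
    mapping_scores: Optional[pd.DataFrame] = None,
):
    """Run segmentation and all filter stages on one section in memory.

    Returns the annotated cell-by-gene AnnData (flags, metrics and thresholds
    attached) without dropping any cell; export-time dropping is the caller's
    choice. Stage failures raise with the stage name.
    """
    cfg = cfg or RunConfig()
    report: dict = {}

    # ---- stage 1: segmentation -------------------------------------------
    try:
        density = smooth_density(bin_transcripts(spots, dapi), cfg.density)
        x0, y0, _ = dapi.origin
        nz, ny, nx = dapi.shape
        vx, vy, vz = dapi.voxel_size
        extent = (x0, y0, x0 + nx * vx, y0 + ny * vy)
        tiles = make_tiles(extent, cfg.tile_size_um, cfg.overlap_um)
        per_tile = []
        for tile in tiles:
            ix0 = int(np.floor((tile.x0 - x0) / vx))
            ix1 = int(np.ceil((tile.x1 - x0) / vx))
            iy0 = int(np.floor((tile.y0 - y0) / vy))
            iy1 = int(np.ceil((tile.y1 - y0) / vy))
            sub_density = VolumeImage(
                density.values[:, iy0:iy1, ix0:ix1],
                origin=(x0 + ix0 * vx, y0 + iy0 * vy, dapi.origin[2]),
                voxel_size=dapi.voxel_size,
            )
            sub_dapi = VolumeImage(dapi.values[:, iy0:iy1, ix0:ix1],
                                   origin=sub_density.origin, voxel_size=dapi.voxel_size)
            labels = segment_tile(sub_dapi, sub_density, backend=cfg.backend)
            in_tile = spots[tile.contains(spots["x"], spots["y"])]
            per_tile.append(assign_transcripts(in_tile, labels, tile_index=tile.index))
        assignments = stitch_and_merge(per_tile)
        spots_idx = spots.set_index("transcript_id")
        polygons = {}
        assigned = assignments.dropna(subset=["cell_id"])
        for cell_id, group in assigned.groupby("cell_id"):
            cell_spots = spots_idx.loc[group["transcript_id"]]
            polygons[cell_id] = build_cell_polygons(cell_spots, alpha_scale=cfg.alpha_scale)
        adata = assemble_cell_matrix(
            assignments, spots, polygons,
            params={"tile_size_um": cfg.tile_size_um, "overlap_um": cfg.overlap_um,
                    "backend": cfg.backend, "alpha_scale": cfg.alpha_scale},
            z_spacing=dapi.voxel_size[2],
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'segmentation' failed: {exc}") from exc
    report["n_cells_segmented"] = int(adata.n_obs)

    # ---- stage 2: low-quality filtering ----------------------------------
    try:
        metrics = compute_cell_metrics(adata)
        for col in metrics.columns:
            adata.obs[col] = metrics[col]
        keep_qc = apply_quality_filter(metrics, cfg.qc)
        adata.obs["pass_qc"] = keep_qc.to_numpy()
        if not keep_qc.any():
            logger.warning("quality filter retained zero cells; thresholds may be impossible "
                           "for this panel")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'qc' failed: {exc}") from exc
    report["n_removed_qc"] = int((~adata.obs["pass_qc"]).sum())

    # ---- stage 3: doublet detection --------------------------------------
    try:
        if adata.n_obs >= 50:
            scores = score_doublets(adata, backend="builtin", seed=cfg.seed)
            threshold, flags = call_doublets(scores["dif"])
            adata.obs["doublet_dif"] = scores["dif"].to_numpy()
            adata.obs["pass_doublet"] = ~flags
            adata.uns["doublet_threshold"] = float(threshold)
        else:
            logger.warning("fewer than 50 cells; doublet stage skipped")
            adata.obs["pass_doublet"] = True
            adata.uns["doublet_threshold"] = float("nan")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'doublets' failed: {exc}") from exc
    report["n_removed_doublet"] = int((~adata.obs["pass_doublet"]).sum())

    # ---- stage 4: mapping-score filtering --------------------------------
    try:
        adata.obs["pass_mapping"] = True
        if mapping_scores is not None:
            upstream = adata.obs["pass_qc"] & adata.obs["pass_doublet"]
            scored = mapping_scores.reindex(adata.obs.index[upstream]).dropna(
                subset=["supertype", "avg_correlation"]
            )
            keep, reports = filter_mapped_cells(scored, cfg.double_mad, cfg.bimodality)
            adata.obs.loc[keep.index[~keep], "pass_mapping"] = False
            adata.uns["mapping_thresholds"] = {
                r.supertype: r.threshold for r in reports
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'mapping_filter' failed: {exc}") from exc
    report["n_removed_mapping"] = int((~adata.obs["pass_mapping"]).sum())

    adata.uns["run_config"] = {
        "min_genes": cfg.qc.min_genes,
        "min_transcripts": cfg.qc.min_transcripts,
        "max_blank_fraction": cfg.qc.max_blank_fraction,
        "k_mad": cfg.double_mad.k_mad,
        "tile_size_um": cfg.tile_size_um,
        "overlap_um": cfg.overlap_um,
        "seed": cfg.seed,
    }
    adata.uns["stage_report"] = {k: int(v) for k, v in report.items()}
    for k, v in report.items():
        logger.info("%s = %d", k, v)
    return adata


def run_pipeline(cfg: RunConfig):
    """File-driven pipeline entry point; returns the annotated AnnData.

    Reads the spot table (and optional mapping scores), processes the
    section, writes the result to ``cfg.out_path`` when set (dropping flagged
    cells if ``drop_filtered_on_export``).
    """
    from .core import read_spot_table, write_cell_matrix
    from .density import grid_from_extent

    if cfg.spots_path is None:
        raise ValueError("cfg.spots_path is required")
    spots = read_spot_table(cfg.spots_path, dialect=cfg.dialect)
    pad = 5.0
    extent = (
        float(spots["x"].min() - pad) if len(spots) else 0.0,
        float(spots["y"].min() - pad) if len(spots) else 0.0,
        float(spots["x"].max() + pad) if len(spots) else 10.0,
        float(spots["y"].max() + pad) if len(spots) else 10.0,
    )
    n_z = max(int(np.ceil(spots["z"].max())) if len(spots) else 1, 1)
    dapi = grid_from_extent(extent, 2.0, n_z=min(n_z, 7))
    mapping = None
    if cfg.mapping_scores_path:
        mapping = pd.read_csv(cfg.mapping_scores_path, index_col=0)
    adata = process_section(spots, dapi, cfg, mapping_scores=mapping)
    if cfg.out_path:
        out = adata
        if cfg.drop_filtered_on_export:
            mask = adata.obs["pass_qc"] & adata.obs["pass_doublet"] & adata.obs["pass_mapping"]
            out = adata[mask].copy()
        write_cell_matrix(out, cfg.out_path)
    return adata
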