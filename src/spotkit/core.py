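"""Transcript tables and cell-by-gene matrices.

A spot table is a :class:`pandas.DataFrame` with one row per detected
transcript and canonical columns::

    transcript_id  int      unique within a section
    gene           str      decoded gene name ("Blank-*" for blank codewords)
    x, y, z        float    position in micrometers, section-local frame
    section_id     str
    is_blank       bool     gene name matches the blank-codeword pattern
    cell_id        object   assigned cell or None

Cell-by-gene matrices are :class:`anndata.AnnData` objects: ``X`` holds
non-blank transcript counts, ``obs`` the per-cell metadata (centroids, volume,
area, ids, blank counts), ``var`` the per-gene tallies, and ``uns`` the cell
polygons (GeoJSON FeatureCollection), segmentation parameters and package
version. Blank transcripts are carried through assignment but excluded from
the counts matrix; they feed QC only.
"""

from __future__ import annotations

import json
import re
from typing import Mapping, Optional

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ConsistencyError",
    "ConfigurationError",
    "BLANK_PATTERN",
    "read_spot_table",
    "make_spot_table",
    "assemble_cell_matrix",
    "write_cell_matrix",
    "read_cell_matrix",
]


class FormatError(ValueError):
    """An input file does not conform to the expected dialect."""


class ConsistencyError(ValueError):
    """Cross-references between tables do not resolve."""


class ConfigurationError(ValueError):
    """Invalid parameter combination."""


#: Gene names starting with "Blank" (case-insensitive) are blank codewords.
BLANK_PATTERN = re.compile(r"^blank", re.IGNORECASE)

SPOT_COLUMNS = ["transcript_id", "gene", "x", "y", "z", "section_id", "is_blank", "cell_id"]

_DIALECTS = {
    "merscope_csv": {"gene": "gene", "x": "global_x", "y": "global_y", "z": "global_z"},
    "generic_csv": {"gene": "gene", "x": "x", "y": "y", "z": "z"},
}


def make_spot_table(
    gene,
    x,
    y,
    z=None,
    section_id: str = "S0",
    transcript_id=None,
    blank_pattern: re.Pattern = BLANK_PATTERN,
) -> pd.DataFrame:
    """Build a canonical spot table from raw columns."""
    gene = pd.Series(gene, dtype=str).reset_index(drop=True)
    n = len(gene)
    if z is None:
        z = np.zeros(n)
    if transcript_id is None:
        transcript_id = np.arange(n)
    df = pd.DataFrame(
        {
            "transcript_id": np.asarray(transcript_id),
            "gene": gene,
            "x": np.asarray(x, dtype=float),
            "y": np.asarray(y, dtype=float),
            "z": np.asarray(z, dtype=float),
            "section_id": section_id,
            "is_blank": gene.str.match(blank_pattern).astype(bool),
            "cell_id": None,
        }
    )
    if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
        raise FormatError("non-finite coordinate in spot table")
    return df


def read_spot_table(
    path,
    dialect: str = "merscope_csv",
    section_id: Optional[str] = None,
    blank_pattern: re.Pattern = BLANK_PATTERN,
) -> pd.DataFrame:
    """Read a detected-transcripts CSV into a canonical spot table.

    Parameters
    ----------
    path
        CSV file with one row per decoded transcript.
    dialect
        ``"merscope_csv"`` (columns ``gene, global_x, global_y, global_z``) or
        ``"generic_csv"`` (columns ``gene, x, y, z``). A ``section``/
        ``section_id`` column is used when present.
    """
    if dialect not in _DIALECTS:
        raise ConfigurationError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    cols = _DIALECTS[dialect]
    raw = pd.read_csv(path)
    for key in ("gene", "x", "y"):
        if cols[key] not in raw.columns:
            raise FormatError(f"missing required column {cols[key]!r} in {path}")
    for key in ("x", "y", "z"):
        col = cols[key]
        if col not in raw.columns:
            continue
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"non-numeric coordinate in column {col!r} at row {row}")
        raw[col] = coerced
    if section_id is None:
        for cand in ("section_id", "section"):
            if cand in raw.columns:
                section_id = str(raw[cand].iloc[0]) if len(raw) else "S0"
                break
        else:
            section_id = "S0"
    z = raw[cols["z"]] if cols["z"] in raw.columns else None
    tid = raw["transcript_id"] if "transcript_id" in raw.columns else None
    return make_spot_table(
        raw[cols["gene"]], raw[cols["x"]], raw[cols["y"]], z,
        section_id=section_id, transcript_id=tid, blank_pattern=blank_pattern,
    )


def _polygon_geojson(polygons: Mapping) -> str:
    """Serialize per-cell polygon stacks into a GeoJSON FeatureCollection string."""
    from shapely.geometry import mapping as shp_mapping

    features = []
    for cell_id, stack in polygons.items():
        if stack is None:
            continue
        for plane in stack.planes:
            if plane.polygon is None:
                continue
            features.append(
                {
                    "type": "Feature",
                    "geometry": shp_mapping(plane.polygon),
                    "properties": {
                        "cell_id": str(cell_id),
                        "z": float(plane.z),
                        "alpha_used": None if plane.alpha_used is None else float(plane.alpha_used),
                    },
                }
            )
    return json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True)


def assemble_cell_matrix(
    assignments: pd.DataFrame,
    spots: pd.DataFrame,
    polygons: Optional[Mapping] = None,
    params: Optional[dict] = None,
    z_spacing: float = 1.0,
) -> ad.AnnData:
    """Assemble the final cell-by-gene matrix from assignments and polygons.

    ``assignments`` has columns ``transcript_id, cell_id, tile_index``; every
    row must reference an existing transcript. Counts cover non-blank genes
    only; per-cell blank tallies land in ``obs["n_blanks"]``. ``gene_meta``
    records, per gene, how many transcripts were left unsegmented.
    """
    from .segmentation import compute_geometry

    polygons = polygons or {}
    params = dict(params or {})
    spots = spots.set_index("transcript_id", drop=False)
    unknown = ~assignments["transcript_id"].isin(spots.index)
    if unknown.any():
        raise ConsistencyError(
            f"{int(unknown.sum())} assignment rows reference unknown transcripts"
        )

    merged = spots.copy()
    merged["cell_id"] = None
    merged["tile_index"] = -1
    assigned = assignments.dropna(subset=["cell_id"])
    merged.loc[assigned["transcript_id"].to_numpy(), "cell_id"] = assigned["cell_id"].to_numpy()
    merged.loc[assigned["transcript_id"].to_numpy(), "tile_index"] = assigned["tile_index"].to_numpy()

    genes = sorted(merged.loc[~merged["is_blank"], "gene"].unique())
    gene_index = {g: i for i, g in enumerate(genes)}
    in_cell = merged["cell_id"].notna()
    cells = sorted(merged.loc[in_cell, "cell_id"].unique(), key=str)
    cell_index = {c: i for i, c in enumerate(cells)}

    counts = np.zeros((len(cells), len(genes)), dtype=np.int64)
    sub = merged[in_cell & ~merged["is_blank"]]
    if len(sub):
        np.add.at(
            counts,
            (sub["cell_id"].map(cell_index).to_numpy(), sub["gene"].map(gene_index).to_numpy()),
            1,
        )

    obs = pd.DataFrame(index=pd.Index([str(c) for c in cells], name="cell_id"))
    cent = merged[in_cell].groupby("cell_id")[["x", "y", "z"]].mean()
    for ax in "xyz":
        obs[f"transcript_centroid_{ax}"] = [cent.loc[c, ax] for c in cells] if cells else []
    blanks = merged[in_cell & merged["is_blank"]].groupby("cell_id").size()
    obs["n_blanks"] = [int(blanks.get(c, 0)) for c in cells]
    tile_of = merged[in_cell].groupby("cell_id")["tile_index"].first()

    vols, areas, pcx, pcy, pcz = [], [], [], [], []
    for c in cells:
        stack = polygons.get(c)
        if stack is None:
            vols.append(0.0)
            areas.append(0.0)
            pcx.append(np.nan), pcy.append(np.nan), pcz.append(np.nan)
        else:
            vol, area, centroid = compute_geometry(stack, z_spacing=z_spacing)
            vols.append(vol), areas.append(area)
            pcx.append(centroid[0]), pcy.append(centroid[1]), pcz.append(centroid[2])
    obs["polygon_centroid_x"] = pcx
    obs["polygon_centroid_y"] = pcy
    obs["polygon_centroid_z"] = pcz
    obs["volume_um3"] = vols
    obs["area_um2"] = areas
    obs["original_cell_id"] = [str(c) for c in cells]
    section = str(spots["section_id"].iloc[0]) if len(spots) else "S0"
    obs["production_cell_id"] = [
        f"{section}-{int(tile_of.get(c, -1))}-{c}" for c in cells
    ]

    unseg = merged[~in_cell & ~merged["is_blank"]].groupby("gene").size()
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["name"] = genes
    var["n_cells_expressing"] = (counts > 0).sum(axis=0)
    var["total_segmented"] = counts.sum(axis=0)
    var["total_unsegmented"] = [int(unseg.get(g, 0)) for g in genes]

    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.uns["polygons_geojson"] = _polygon_geojson(polygons)
    adata.uns["segmentation_params"] = {k: str(v) for k, v in params.items()}
    from . import __version__

    adata.uns["spotkit_version"] = __version__
    return adata


def write_cell_matrix(adata: ad.AnnData, path) -> None:
    """Write a cell-by-gene matrix to an ``.h5ad`` file."""
    adata.write_h5ad(path)


def read_cell_matrix(path) -> ad.AnnData:
    """Read a cell-by-gene matrix from an ``.h5ad`` file."""
    return ad.read_h5ad(path)
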