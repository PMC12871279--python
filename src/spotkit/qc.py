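"""Per-cell quality metrics, fixed-threshold filtering and incongruent genes.

Low-quality cells are removed with fixed thresholds (defaults: at least 6
genes and 30 transcripts per soma, blank-codeword fraction below 2%). The
incongruent-gene score counts transcripts of marker genes that belong to a
different taxonomic division than the cell and are paired against one of the
cell's own division markers — mutually exclusive expression, so their presence
indicates segmentation contamination.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import ranksums

logger = logging.getLogger(__name__)

__all__ = [
    "QcThresholds",
    "compute_cell_metrics",
    "apply_quality_filter",
    "derive_division_markers",
    "build_incongruent_pairs",
    "incongruent_fraction",
]


@dataclass
class QcThresholds:
    min_genes: int = 6
    min_transcripts: int = 30
    max_blank_fraction: float = 0.02

    def __post_init__(self):
        if min(self.min_genes, self.min_transcripts, self.max_blank_fraction) < 0:
            raise ValueError("thresholds must be non-negative")


def compute_cell_metrics(adata, volume_key: str = "volume_um3", blanks_key: str = "n_blanks") -> pd.DataFrame:
    """Per-cell QC metrics from a cell-by-gene matrix.

    Returns a frame indexed like ``adata.obs`` with columns ``n_genes``,
    ``n_transcripts`` (both over non-blank genes), ``blank_fraction`` and
    ``density`` (transcripts per μm³; NaN when the cell has no volume).
    """
    X = np.asarray(adata.X)
    n_genes = (X > 0).sum(axis=1)
    n_tx = X.sum(axis=1)
    blanks = adata.obs[blanks_key].to_numpy(dtype=float) if blanks_key in adata.obs else np.zeros(adata.n_obs)
    denom = blanks + n_tx
    blank_fraction = np.divide(blanks, denom, out=np.zeros_like(denom, dtype=float), where=denom > 0)
    if volume_key in adata.obs:
        vol = adata.obs[volume_key].to_numpy(dtype=float)
        density = np.divide(n_tx, vol, out=np.full(len(vol), np.nan), where=vol > 0)
    else:
        density = np.full(adata.n_obs, np.nan)
    return pd.DataFrame(
        {
            "n_genes": n_genes.astype(int),
            "n_transcripts": n_tx.astype(int),
            "blank_fraction": blank_fraction,
            "density": density,
        },
        index=adata.obs.index,
    )


def apply_quality_filter(metrics: pd.DataFrame, t: QcThresholds | None = None) -> pd.Series:
    """Boolean keep mask; a cell is removed iff it has fewer genes or
    transcripts than the minimum, or a blank fraction at or above the cap."""
    t = t or QcThresholds()
    remove = (
        (metrics["n_genes"] < t.min_genes)
        | (metrics["n_transcripts"] < t.min_transcripts)
        | (metrics["blank_fraction"] >= t.max_blank_fraction)
    )
    return ~remove


def derive_division_markers(
    cluster_medians: pd.DataFrame,
    division_of: Mapping[str, str],
    top_n: int = 10,
) -> Dict[str, List[str]]:
    """One-vs-rest Wilcoxon rank-sum markers per division on cluster medians.

    The observations are clusters (rows of the median matrix), not cells.
    Genes are ranked per division by the rank-sum statistic, ties broken by
    gene name; the top ``top_n`` per division are returned.
    """
    divisions = sorted(set(division_of.values()))
    if len(divisions) < 2:
        raise ValueError("need at least two divisions")
    if top_n > cluster_medians.shape[1]:
        logger.warning("top_n=%d exceeds panel size %d; returning all genes", top_n, cluster_medians.shape[1])
        top_n = cluster_medians.shape[1]
    div_labels = cluster_medians.index.map(lambda c: division_of[c])
    markers: Dict[str, List[str]] = {}
    for div in divisions:
        in_div = cluster_medians.loc[div_labels == div]
        rest = cluster_medians.loc[div_labels != div]
        stats = []
        for gene in cluster_medians.columns:
            stat = ranksums(in_div[gene].to_numpy(), rest[gene].to_numpy()).statistic
            if not np.isfinite(stat):
                stat = 0.0
            stats.append((-stat, gene))
        stats.sort()
        markers[div] = [g for _, g in stats[:top_n]]
    return markers


def build_incongruent_pairs(markers: Mapping[str, Iterable[str]]) -> Set[frozenset]:
    """All cross-division marker pairs (no pair within a single division)."""
    pairs: Set[frozenset] = set()
    for (da, ga), (db, gb) in itertools.combinations(
        [(d, g) for d, genes in markers.items() for g in genes], 2
    ):
        if da != db and ga != gb:
            pairs.add(frozenset((ga, gb)))
    return pairs


def incongruent_fraction(
    adata,
    pairs: Set[frozenset],
    division_label: pd.Series,
    marker_division: Mapping[str, str],
) -> pd.Series:
    """Incongruent transcripts as a percentage of total non-blank transcripts.

    For a cell of division D the incongruent genes are markers of another
    division that are paired (in ``pairs``) against some D marker. Unlabeled
    or zero-transcript cells get NaN.
    """
    X = np.asarray(adata.X)
    genes = list(adata.var_names)
    out = np.full(adata.n_obs, np.nan)
    gene_div = {g: marker_division.get(g) for g in genes}
    # per division: column indices of incongruent genes
    cache: Dict[str, np.ndarray] = {}

    def incongruent_cols(div: str) -> np.ndarray:
        if div not in cache:
            own = {g for g, d in marker_division.items() if d == div}
            cols = [
                i
                for i, g in enumerate(genes)
                if gene_div.get(g) not in (None, div)
                and any(frozenset((g, o)) in pairs for o in own)
            ]
            cache[div] = np.asarray(cols, dtype=int)
        return cache[div]

    labels = division_label.reindex(adata.obs.index)
    totals = X.sum(axis=1)
    for i, div in enumerate(labels):
        if pd.isna(div) or totals[i] == 0:
            continue
        cols = incongruent_cols(str(div))
        bad = X[i, cols].sum() if len(cols) else 0.0
        out[i] = 100.0 * bad / totals[i]
    return pd.Series(out, index=adata.obs.index, name="incongruent_pct")
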