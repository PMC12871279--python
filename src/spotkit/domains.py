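"""Spatial-domain preparation: grid aggregation, QC, graphs, stability.

Transcripts are aggregated into 30 μm spatial grids, grids are quality
filtered (at least 60 genes, 300 transcripts, blank fraction below 3%), a
spatial KNN graph is built for the external spatial embedding model, and
clustering stability over a Leiden resolution sweep is quantified by pairwise
adjusted mutual information (AMI) and adjusted Rand index (ARI) across
bootstrap subsamples (default 80% of nodes, 25 times).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "GridMatrix",
    "aggregate_grid",
    "grid_qc",
    "knn_graph",
    "leiden_labels",
    "cluster_stability",
    "pca_embedding",
    "region_concordance",
]


@dataclass
class GridMatrix:
    """Grid-by-gene counts with per-grid blank tallies.

    ``counts`` is indexed by (ix, iy) bin indices over non-blank genes;
    ``blanks`` is aligned to the same index. ``centers()`` returns bin-center
    coordinates in micrometers.
    """

    counts: pd.DataFrame
    blanks: pd.Series
    bin_um: float
    origin: Tuple[float, float] = (0.0, 0.0)

    def centers(self) -> np.ndarray:
        idx = np.asarray(list(self.counts.index), dtype=float)
        return np.column_stack(
            [
                self.origin[0] + (idx[:, 0] + 0.5) * self.bin_um,
                self.origin[1] + (idx[:, 1] + 0.5) * self.bin_um,
            ]
        )


def aggregate_grid(spots: pd.DataFrame, bin_um: float = 30.0, origin=(0.0, 0.0)) -> GridMatrix:
    """Aggregate transcripts into half-open square bins from the section origin.

    Blanks are tallied separately per grid; the summed counts over all grids
    equal the number of non-blank transcripts.
    """
    if bin_um <= 0:
        raise ConfigurationError("bin_um must be positive")
    ix = np.floor((spots["x"].to_numpy(dtype=float) - origin[0]) / bin_um).astype(int)
    iy = np.floor((spots["y"].to_numpy(dtype=float) - origin[1]) / bin_um).astype(int)
    df = pd.DataFrame({"ix": ix, "iy": iy, "gene": spots["gene"].to_numpy(), "is_blank": spots["is_blank"].to_numpy()})
    counts = (
        df[~df["is_blank"]]
        .groupby(["ix", "iy", "gene"])
        .size()
        .unstack("gene", fill_value=0)
    )
    blanks = df[df["is_blank"]].groupby(["ix", "iy"]).size()
    all_bins = counts.index.union(blanks.index) if len(blanks) else counts.index
    counts = counts.reindex(all_bins, fill_value=0)
    blanks = blanks.reindex(all_bins, fill_value=0).astype(int)
    return GridMatrix(counts=counts, blanks=blanks, bin_um=float(bin_um), origin=tuple(origin))


def grid_qc(
    g: GridMatrix,
    min_genes: int = 60,
    min_transcripts: int = 300,
    max_blank_frac: float = 0.03,
) -> pd.Series:
    """Keep mask over grids: genes >= min, transcripts >= min, blank fraction < cap."""
    n_genes = (g.counts > 0).sum(axis=1)
    n_tx = g.counts.sum(axis=1)
    denom = n_tx + g.blanks
    blank_frac = np.divide(
        g.blanks.to_numpy(dtype=float),
        denom.to_numpy(dtype=float),
        out=np.zeros(len(denom)),
        where=denom.to_numpy() > 0,
    )
    keep = (n_genes >= min_genes) & (n_tx >= min_transcripts) & (blank_frac < max_blank_frac)
    return keep


def knn_graph(coords, k: int = 8) -> sp.csr_matrix:
    """Symmetric (union) k-nearest-neighbor graph with index tie-breaks.

    Each node links to its ``k`` nearest Euclidean neighbors; exact distance
    ties are broken toward the lower node index. With fewer than ``k+1``
    nodes a complete graph is returned with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n <= k:
        logger.warning("fewer nodes (%d) than k+1 (%d); returning complete graph", n, k + 1)
        adj = sp.csr_matrix(np.ones((n, n)) - np.eye(n))
        return adj
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    rows, cols = [], []
    order_idx = np.arange(n)
    for i in range(n):
        # stable lexicographic sort: distance first, node index second
        nb = np.lexsort((order_idx, d2[i]))[:k]
        rows.extend([i] * k)
        cols.extend(nb.tolist())
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    adj = ((adj + adj.T) > 0).astype(float)
    return adj.tocsr()


def _embedding_knn_graph(embedding: np.ndarray, k: int) -> "igraph.Graph":
    import igraph
    from sklearn.neighbors import NearestNeighbors

    n = len(embedding)
    kk = min(k + 1, n)
    nn = NearestNeighbors(n_neighbors=kk).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    edges = set()
    for i, row in enumerate(idx):
        for j in row:
            if i != j:
                edges.add((min(i, j), max(i, j)))
    g = igraph.Graph(n=n, edges=sorted(edges))
    return g


def leiden_labels(embedding: np.ndarray, resolution: float, k: int = 15, seed: int = 0) -> np.ndarray:
    """Leiden clustering on a k-nearest-neighbor graph of an embedding."""
    import leidenalg

    g = _embedding_knn_graph(np.asarray(embedding, dtype=float), k)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=float(resolution),
        seed=int(seed),
        n_iterations=2,
    )
    return np.asarray(part.membership)


def pca_embedding(counts: pd.DataFrame, n_components: int = 20, seed: int = 0) -> np.ndarray:
    """Built-in stand-in embedding: PCA of log-normalized grid counts.

    The production embedding comes from an external spatially-aware model;
    this keeps the stability analysis runnable end-to-end.
    """
    from sklearn.decomposition import PCA

    X = counts.to_numpy(dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    X = np.log1p(X / totals * np.median(totals))
    n_comp = min(n_components, X.shape[1], X.shape[0] - 1)
    return PCA(n_components=n_comp, random_state=seed).fit_transform(X)


def cluster_stability(
    embedding,
    resolutions: Sequence[float] = tuple(np.round(np.arange(0.2, 2.01, 0.1), 2)),
    n_boot: int = 25,
    frac: float = 0.8,
    seed: int = 0,
    k: int = 15,
) -> pd.DataFrame:
    """Bootstrap stability of Leiden clustering over a resolution sweep.

    ``n_boot`` subsamples of ``frac`` of the nodes are clustered at each
    resolution (k=15 neighbor graph on the embedding); all C(n_boot, 2)
    subsample pairs are scored by AMI and ARI on their shared nodes. Returns a
    tidy frame with columns resolution, pair, ami, ari, n_clusters (mean of
    the pair's cluster counts).
    """
    from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score

    embedding = np.asarray(embedding, dtype=float)
    resolutions = list(resolutions)
    if not resolutions:
        raise ConfigurationError("resolution sweep is empty")
    n = len(embedding)
    rng = np.random.default_rng(seed)
    size = max(int(round(frac * n)), 2)
    subsamples = [np.sort(rng.choice(n, size=size, replace=False)) for _ in range(n_boot)]
    rows = []
    for res in resolutions:
        labels = []
        for b, idx in enumerate(subsamples):
            lab = leiden_labels(embedding[idx], resolution=res, k=k, seed=seed + b)
            labels.append(dict(zip(idx.tolist(), lab.tolist())))
        for pair_index, (a, b) in enumerate(itertools.combinations(range(n_boot), 2)):
            shared = sorted(set(labels[a]) & set(labels[b]))
            la = [labels[a][i] for i in shared]
            lb = [labels[b][i] for i in shared]
            rows.append(
                {
                    "resolution": res,
                    "pair": pair_index,
                    "ami": adjusted_mutual_info_score(la, lb),
                    "ari": adjusted_rand_score(la, lb),
                    "n_clusters": 0.5 * (len(set(labels[a].values())) + len(set(labels[b].values()))),
                }
            )
    return pd.DataFrame(rows)


def region_concordance(
    domain_label: pd.Series,
    region_sets: Mapping[str, Set[str]],
    celltype: pd.Series,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Jaccard overlap between domain cell-type sets and region-specific sets.

    ``J(d, r) = |types(d) ∩ types(r)| / |types(d) ∪ types(r)|``. Returns the
    Jaccard matrix and the raw overlap counts (both domain × region). Empty
    domains give rows of zeros.
    """
    domains = sorted(pd.Series(domain_label).dropna().unique(), key=str)
    regions = sorted(region_sets)
    jac = pd.DataFrame(0.0, index=domains, columns=regions)
    overlap = pd.DataFrame(0, index=domains, columns=regions)
    ct = pd.Series(celltype)
    dl = pd.Series(domain_label)
    for d in domains:
        types_d = set(ct[dl == d].dropna().unique())
        for r in regions:
            types_r = set(region_sets[r])
            union = types_d | types_r
            inter = types_d & types_r
            overlap.loc[d, r] = len(inter)
            jac.loc[d, r] = len(inter) / len(union) if union else 0.0
    return jac, overlap
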