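"""Niche covariance representation and multiscale spectral similarity.

``covet_niche`` summarizes each cell's spatial niche (its k=8 nearest
neighbors) as a gene-gene shifted covariance matrix: deviations are taken
from the global dataset mean expression rather than the niche mean, which
makes matrices directly comparable across niches.

``mssi_score`` compares two spatial expression patterns (e.g. a measured gene
versus its imputed value) without requiring matched cells: each dataset gets
its own k=8 spatial kNN graph, which is coarsened and blurred four times by a
factor of two (greedy heavy-edge matching with mean pooling, analogous to
image downsampling). At each of the five scales, structural-similarity-style
luminance and contrast terms are combined with a distribution-based structure
term — the Pearson correlation of the two normalized expression histograms —
and the final score is the mean of the per-scale products.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import scipy.sparse as sp

__all__ = ["covet_niche", "knn_graph_weighted", "coarsen_graph", "mssi_score", "MssiResult"]

_EPS = 1e-12


def covet_niche(coords, expr, k: int = 8, exclude_self: bool = True) -> np.ndarray:
    """Shifted niche covariance matrix per cell.

    For each cell, with N its ``k`` nearest spatial neighbors (the cell itself
    excluded by default) and ``ē`` the global mean expression vector::

        C = mean over j in N of (e_j - ē)(e_j - ē)^T

    Returns an array of shape (n_cells, n_genes, n_genes); each matrix is
    symmetric positive semidefinite.
    """
    from scipy.spatial import cKDTree

    coords = np.asarray(coords, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if expr.ndim == 1:
        expr = expr[:, None]
    n = len(coords)
    if n < k + 1:
        raise ValueError(f"covet_niche needs at least k+1={k + 1} cells, got {n}")
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    centered = expr - expr.mean(axis=0)
    out = np.empty((n, expr.shape[1], expr.shape[1]))
    for i in range(n):
        nbrs = [j for j in idx[i] if j != i][:k] if exclude_self else idx[i][:k].tolist()
        D = centered[nbrs]
        out[i] = D.T @ D / len(nbrs)
    return out


def knn_graph_weighted(coords, k: int = 8) -> sp.csr_matrix:
    """Symmetric spatial kNN graph with inverse-distance edge weights."""
    from scipy.spatial import cKDTree

    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    kk = min(k, n - 1)
    tree = cKDTree(coords)
    d, idx = tree.query(coords, k=kk + 1)
    rows, cols, w = [], [], []
    for i in range(n):
        for dist, j in zip(d[i], idx[i]):
            if j == i:
                continue
            rows.append(i), cols.append(j), w.append(1.0 / (1.0 + dist))
    adj = sp.csr_matrix((w, (rows, cols)), shape=(n, n))
    adj = adj.maximum(adj.T)
    return adj.tocsr()


def coarsen_graph(
    adj: sp.spmatrix, values: np.ndarray, factor: int = 2
) -> Tuple[sp.csr_matrix, np.ndarray, sp.csr_matrix]:
    """One greedy heavy-edge-matching coarsening step.

    Edges are visited by decreasing weight (index tie-break); each node is
    matched with at most one neighbor and every matched pair becomes a
    supernode, unmatched nodes carry over as singletons, so the node count
    drops to ceil(n/2) on well-structured graphs. Pooled values are member
    means; supernodes inherit the union of member adjacency. Returns the
    coarsened graph, pooled values and the (n_super × n) mean-pooling
    operator. The ``factor`` is the nominal reduction per application.
    """
    adj = sp.csr_matrix(adj)
    n = adj.shape[0]
    values = np.asarray(values, dtype=float)
    if n == 0:
        return adj, values[:0], sp.csr_matrix((0, 0))
    coo = sp.triu(adj, k=1).tocoo()
    order = np.lexsort((coo.col, coo.row, -coo.data))
    matched = np.full(n, -1, dtype=int)
    groups: List[List[int]] = []
    for e in order:
        u, v = int(coo.row[e]), int(coo.col[e])
        if matched[u] < 0 and matched[v] < 0:
            matched[u] = matched[v] = len(groups)
            groups.append([u, v])
    for u in range(n):
        if matched[u] < 0:
            matched[u] = len(groups)
            groups.append([u])
    n_super = len(groups)
    rows, cols, w = [], [], []
    for gi, members in enumerate(groups):
        for m in members:
            rows.append(gi), cols.append(m), w.append(1.0 / len(members))
    P = sp.csr_matrix((w, (rows, cols)), shape=(n_super, n))
    pooled = P @ values
    Pb = sp.csr_matrix((np.ones(n), (matched, np.arange(n))), shape=(n_super, n))
    coarse = (Pb @ adj @ Pb.T).tolil()
    coarse.setdiag(0)
    return sp.csr_matrix(coarse), pooled, P


def _blur(adj: sp.spmatrix, values: np.ndarray) -> np.ndarray:
    """Graph blur: average a node's value with its neighborhood mean."""
    adj = sp.csr_matrix(adj)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    nbr_mean = np.zeros_like(values, dtype=float)
    nz = deg > 0
    nbr_sum = adj @ values
    nbr_mean[nz] = nbr_sum[nz] / deg[nz]
    out = values.astype(float).copy()
    out[nz] = 0.5 * values[nz] + 0.5 * nbr_mean[nz]
    return out


@dataclass
class MssiResult:
    score: float
    luminance: List[float] = field(default_factory=list)
    contrast: List[float] = field(default_factory=list)
    structure: List[float] = field(default_factory=list)
    per_scale: List[float] = field(default_factory=list)
    n_scales: int = 4
    coarsen_factor: int = 2


def _histogram(values: np.ndarray, lo: float, hi: float, bins: int) -> np.ndarray:
    if hi <= lo:
        hi = lo + 1.0
    h, _ = np.histogram(values, bins=bins, range=(lo, hi))
    total = h.sum()
    return h / total if total > 0 else h.astype(float)


def _structure(a: np.ndarray, b: np.ndarray, lo: float, hi: float, bins: int) -> float:
    ha = _histogram(a, lo, hi, bins)
    hb = _histogram(b, lo, hi, bins)
    if np.allclose(ha, hb):
        return 1.0
    sa, sb = ha.std(), hb.std()
    if sa < _EPS or sb < _EPS:
        return 0.0
    return float(np.corrcoef(ha, hb)[0, 1])


def mssi_score(
    ref_coords,
    ref_values,
    query_coords,
    query_values,
    k: int = 8,
    n_scales: int = 4,
    coarsen_factor: int = 2,
    bins: int = 64,
) -> MssiResult:
    """Multiscale spectral similarity between two spatial expression patterns.

    The datasets need not share coordinates or cell counts; each is coarsened
    by its own graph geometry. Stabilizing constants follow standard
    structural-similarity practice, C1=(0.01·L)² and C2=(0.03·L)² with L the
    pooled dynamic range of both inputs (pooled so the score is symmetric).
    """
    rv = np.asarray(ref_values, dtype=float).ravel()
    qv = np.asarray(query_values, dtype=float).ravel()
    ga = knn_graph_weighted(ref_coords, k=k)
    gb = knn_graph_weighted(query_coords, k=k)
    L = max(rv.max(initial=0) , qv.max(initial=0)) - min(rv.min(initial=0), qv.min(initial=0))
    C1 = max((0.01 * L) ** 2, _EPS)
    C2 = max((0.03 * L) ** 2, _EPS)
    result = MssiResult(score=0.0, n_scales=n_scales, coarsen_factor=coarsen_factor)
    a, b = rv, qv
    for scale in range(n_scales + 1):
        mu_a, mu_b = a.mean(), b.mean()
        sd_a, sd_b = a.std(), b.std()
        l = (2 * mu_a * mu_b + C1) / (mu_a**2 + mu_b**2 + C1)
        c = (2 * sd_a * sd_b + C2) / (sd_a**2 + sd_b**2 + C2)
        lo = min(a.min(initial=0), b.min(initial=0))
        hi = max(a.max(initial=0), b.max(initial=0))
        s = _structure(a, b, lo, hi, bins)
        result.luminance.append(float(l))
        result.contrast.append(float(c))
        result.structure.append(float(s))
        result.per_scale.append(float(l * c * s))
        if scale < n_scales:
            ga, a, _ = coarsen_graph(ga, a, factor=coarsen_factor)
            gb, b, _ = coarsen_graph(gb, b, factor=coarsen_factor)
            a = _blur(ga, a)
            b = _blur(gb, b)
    result.score = float(np.mean(result.per_scale))
    return result
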