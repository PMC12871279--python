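"""Doublet scoring and quantile-based thresholding.

A doublet is two adjacent cells segmented as one. The scorer assigns every
cell singlet/doublet probabilities; the built-in backend simulates artificial
doublets by summing random cell pairs' count profiles and classifies each
observed cell by a k-nearest-neighbor vote in a PCA-reduced log-count space
(the published scorer, a semi-supervised VAE, plugs in externally). Counts
are log-transformed but not depth-normalized: the doubled library size is
itself doublet evidence.

The threshold on ``dif = doublet_p - singlet_p`` is the spread of the dif
distribution among predicted doublets: ``q0.9(dif) - q0.1(dif)`` with
linear-interpolation quantiles; cells with dif strictly above the threshold
are flagged.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .core import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = ["score_doublets", "call_doublets"]


def _log_counts(X: np.ndarray) -> np.ndarray:
    # deliberately no library-size normalization: the doubled total count is
    # the strongest doublet signature and normalization would erase it
    return np.log1p(X)


def score_doublets(
    counts,
    backend: str = "builtin",
    seed: int = 0,
    n_simulated: Optional[int] = None,
    k: int = 25,
    n_pcs: int = 20,
) -> pd.DataFrame:
    """Singlet/doublet probabilities per cell.

    ``counts`` is a cell×gene array or AnnData. The builtin backend sums
    ``n_simulated`` (default ``2n``) random distinct cell pairs into
    artificial doublets, embeds observed + simulated profiles with PCA of
    log1p counts, and votes among the ``k`` nearest training profiles
    (observed = singlet evidence, simulated = doublet evidence); probabilities
    are the vote fractions. Deterministic given ``seed``.
    """
    if backend == "solo":
        raise ConfigurationError("solo backend is external; feed its scores into call_doublets")
    if backend != "builtin":
        raise ConfigurationError(f"unknown doublet backend {backend!r}")
    X = np.asarray(counts.X if hasattr(counts, "X") else counts, dtype=float)
    n = X.shape[0]
    if n < 50:
        raise ValueError(f"builtin doublet scorer needs >=50 cells, got {n}")
    rng = np.random.default_rng(seed)
    n_sim = 2 * n if n_simulated is None else int(n_simulated)
    i = rng.integers(0, n, size=n_sim)
    j = rng.integers(0, n - 1, size=n_sim)
    j = np.where(j >= i, j + 1, j)  # distinct pairs
    sim = X[i] + X[j]

    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    combined = _log_counts(np.vstack([X, sim]))
    n_comp = min(n_pcs, combined.shape[1], combined.shape[0] - 1)
    emb = PCA(n_components=n_comp, random_state=0).fit_transform(combined)
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(emb))).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    votes = []
    for row_i, row in enumerate(idx):
        nbrs = [v for v in row if v != row_i][:k]
        votes.append(np.mean([v >= n for v in nbrs]))
    doublet_p = np.asarray(votes)
    out = pd.DataFrame({"singlet_p": 1.0 - doublet_p, "doublet_p": doublet_p})
    out["dif"] = out["doublet_p"] - out["singlet_p"]
    if hasattr(counts, "obs"):
        out.index = counts.obs.index
    return out


def call_doublets(
    dif,
    predicted: Optional[np.ndarray] = None,
) -> Tuple[float, np.ndarray]:
    """Quantile-spread doublet threshold and flags.

    ``predicted`` marks the predicted-doublet cells whose dif values form the
    quantile distribution (default: ``dif > 0``, i.e. doublet probability
    exceeds singlet probability). Returns ``(threshold, flags)`` where
    ``threshold = q0.9 - q0.1`` of the predicted doublets' dif and ``flags``
    marks all cells with ``dif > threshold``. With no predicted doublets the
    threshold is NaN and nothing is flagged.
    """
    dif = np.asarray(dif, dtype=float)
    if isinstance(predicted, pd.Series):
        predicted = predicted.to_numpy()
    mask = (dif > 0) if predicted is None else np.asarray(predicted, dtype=bool)
    pool = dif[mask]
    if pool.size == 0:
        logger.warning("no predicted doublets; threshold undefined, zero flags")
        return float("nan"), np.zeros_like(dif, dtype=bool)
    q10, q90 = np.quantile(pool, [0.1, 0.9], method="linear")
    threshold = float(q90 - q10)
    return threshold, dif > threshold
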