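"""Adaptive filtering of label-transfer correlation scores.

Correlation-based label transfer assigns each cell a best-matching reference
cell type (here called a supertype) with an average correlation score. Score
distributions are skewed and differ between supertypes, so a fixed cutoff
over- or under-filters. The adaptive filter uses the DoubleMAD: separate
median absolute deviations below (MAD_low) and above (MAD_high) the median,
with removal below ``median - 3 * MAD_low``. Bimodal score distributions are
first split at the local KDE minimum between the two modes and the filter is
applied to the upper mode only, so a plausible lower subpopulation is not
penalized twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)

__all__ = [
    "DoubleMadParams",
    "BimodalityParams",
    "ThresholdReport",
    "double_mad",
    "detect_bimodality",
    "supertype_threshold",
    "filter_mapped_cells",
    "ann_distance",
]


@dataclass
class DoubleMadParams:
    k_mad: float = 3.0

    def __post_init__(self):
        if self.k_mad <= 0:
            raise ValueError("k_mad must be positive")


@dataclass
class BimodalityParams:
    """Criteria for calling a score distribution bimodal.

    A KDE (Gaussian kernel, Silverman bandwidth, 512-point grid) must show
    exactly two modes; the minor mode must carry at least ``min_minor_mass`` of
    the total density (mass split at the local minimum); the local minimum
    must lie within ``min_window`` of the median; and the normalized height
    difference between the two peaks must be below ``max_peak_gap``.
    """

    min_minor_mass: float = 0.10
    min_window: float = 0.05
    max_peak_gap: float = 0.05
    grid_size: int = 512


@dataclass
class ThresholdReport:
    supertype: str
    median: float
    mad_low: float
    mad_high: float
    threshold: float
    bimodal: bool
    local_min: Optional[float]
    n_kept: int
    n_removed: int
    note: str = ""


def double_mad(values) -> Tuple[float, float, float]:
    """(median, MAD_low, MAD_high) with the median included on both sides.

    MAD_low is the median absolute deviation of values at or below the
    median, MAD_high of values at or above it; both are 0 for a constant
    sample.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("double_mad needs at least 3 values")
    med = float(np.median(x))
    low = float(np.median(np.abs(x[x <= med] - med)))
    high = float(np.median(np.abs(x[x >= med] - med)))
    return med, low, high


def detect_bimodality(values, p: BimodalityParams | None = None) -> Tuple[bool, Optional[float]]:
    """KDE-based bimodality verdict and the local minimum between the modes."""
    p = p or BimodalityParams()
    x = np.asarray(values, dtype=float)
    if x.size < 50 or np.ptp(x) == 0:
        return False, None
    try:
        kde = gaussian_kde(x, bw_method="silverman")
    except Exception:
        return False, None
    grid = np.linspace(x.min(), x.max(), p.grid_size)
    y = kde(grid)
    interior = np.arange(1, len(grid) - 1)
    maxima = interior[(y[interior] > y[interior - 1]) & (y[interior] >= y[interior + 1])]
    if len(maxima) != 2:
        return False, None
    m1, m2 = maxima
    between = np.arange(m1, m2 + 1)
    min_idx = between[np.argmin(y[between])]
    local_min = float(grid[min_idx])
    med = float(np.median(x))
    if not (med - p.min_window <= local_min <= med + p.min_window):
        return False, local_min
    lower_mass = float(kde.integrate_box_1d(-np.inf, local_min))
    minor = min(lower_mass, 1.0 - lower_mass)
    if minor < p.min_minor_mass:
        return False, local_min
    peak_gap = abs(y[m1] - y[m2]) / max(y[m1], y[m2])
    if peak_gap >= p.max_peak_gap:
        return False, local_min
    return True, local_min


def supertype_threshold(
    values,
    dm: DoubleMadParams | None = None,
    bp: BimodalityParams | None = None,
    supertype: str = "",
) -> Tuple[ThresholdReport, np.ndarray]:
    """DoubleMAD removal threshold for one supertype's score distribution.

    Returns the report and a boolean keep mask aligned with ``values``. For a
    bimodal distribution the median and MAD_low are recomputed on the values
    above the local minimum before thresholding; if that subset is degenerate
    the full distribution is used with a warning.
    """
    dm = dm or DoubleMadParams()
    bp = bp or BimodalityParams()
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("supertype_threshold needs at least 3 values")
    bimodal, local_min = detect_bimodality(x, bp) if x.size >= 50 else (False, None)
    note = ""
    subset = x
    if bimodal:
        upper = x[x > local_min]
        if upper.size < 3:
            logger.warning("upper mode has <3 values; falling back to full distribution")
            note = "upper-mode fallback"
            bimodal_used = False
        else:
            subset = upper
            bimodal_used = True
    else:
        bimodal_used = False
    med, mad_low, mad_high = double_mad(subset)
    threshold = med - dm.k_mad * mad_low
    # keep cells at or above the cutoff; the tolerance only absorbs rounding
    # in the median/MAD arithmetic, not a real margin in correlation units
    keep = x >= threshold - 1e-9 * max(1.0, abs(threshold))
    report = ThresholdReport(
        supertype=supertype,
        median=med,
        mad_low=mad_low,
        mad_high=mad_high,
        threshold=float(threshold),
        bimodal=bimodal_used,
        local_min=local_min if bimodal_used else None,
        n_kept=int(keep.sum()),
        n_removed=int((~keep).sum()),
        note=note,
    )
    return report, keep


def filter_mapped_cells(
    scores: pd.DataFrame,
    dm: DoubleMadParams | None = None,
    bp: BimodalityParams | None = None,
    supertype_col: str = "supertype",
    score_col: str = "avg_correlation",
) -> Tuple[pd.Series, List[ThresholdReport]]:
    """Per-supertype adaptive filtering of mapping scores.

    ``scores`` has one row per cell with the supertype label and the average
    correlation. Supertypes with fewer than 3 cells are kept unfiltered and
    flagged in their report. Returns a keep mask aligned with the input rows
    and one report per supertype.
    """
    keep = pd.Series(True, index=scores.index)
    reports: List[ThresholdReport] = []
    for st, group in scores.groupby(supertype_col, sort=True):
        vals = group[score_col].to_numpy(dtype=float)
        if len(vals) < 3:
            reports.append(
                ThresholdReport(
                    supertype=str(st), median=float(np.median(vals)), mad_low=np.nan,
                    mad_high=np.nan, threshold=-np.inf, bimodal=False, local_min=None,
                    n_kept=len(vals), n_removed=0, note="too few cells; kept unfiltered",
                )
            )
            continue
        report, mask = supertype_threshold(vals, dm, bp, supertype=str(st))
        reports.append(report)
        keep.loc[group.index] = mask
    return keep, reports


def ann_distance(positions, group) -> pd.Series:
    """Mean nearest-neighbor distance within each group.

    For every cell, the Euclidean distance to the nearest other cell of the
    same group; the group value is the mean. Singleton groups get NaN.
    """
    from scipy.spatial import cKDTree

    positions = np.asarray(positions, dtype=float)
    group = pd.Series(group).reset_index(drop=True)
    out = {}
    for g, idx in group.groupby(group).groups.items():
        pts = positions[np.asarray(idx)]
        if len(pts) < 2:
            out[g] = np.nan
            continue
        tree = cKDTree(pts)
        d, _ = tree.query(pts, k=2)
        out[g] = float(np.mean(d[:, 1]))
    return pd.Series(out, name="ann_distance")
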