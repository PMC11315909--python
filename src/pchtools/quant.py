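"""Per-repeat and per-group signal summaries with hierarchical ordering.

The analysis unit is the repeat instance: for each group the distribution
of per-repeat mean signals is the boxplot surface, and group means of those
per-repeat means fill the heatmap matrix.  Heatmap rows/columns are ordered
by agglomerative clustering with euclidean distance and complete linkage,
matching pheatmap's defaults as used for the repeat-class heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist

from .genome import GenomicInterval
from .tracks import BASE_WEIGHTED, SignalTrack, quantify

logger = logging.getLogger(__name__)


@dataclass
class GroupDistribution:
    """Per-repeat mean signal values for one repeat group."""

    group: str
    values: np.ndarray

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def median(self) -> float:
        return float(np.median(self.values)) if self.n else float("nan")


def group_distributions(
    track: SignalTrack,
    groups: dict[str, list[GenomicInterval]],
    mode: str = BASE_WEIGHTED,
) -> list[GroupDistribution]:
    """One distribution of per-repeat means per group.

    Missing values (possible in ``overlap_unweighted`` mode) are dropped
    with a logged count; empty groups yield empty distributions.
    """
    if not groups:
        raise ValueError("groups must be non-empty")
    out = []
    for group, intervals in groups.items():
        if not intervals:
            logger.warning("group %r has no intervals", group)
            out.append(GroupDistribution(group, np.empty(0)))
            continue
        vals = quantify(track, intervals, mode=mode)
        n_missing = int(np.isnan(vals).sum())
        if n_missing:
            logger.info("group %r: dropped %d missing values", group, n_missing)
            vals = vals[~np.isnan(vals)]
        out.append(GroupDistribution(group, vals))
    return out


def group_mean_matrix(
    tracks: dict[str, SignalTrack],
    groups: dict[str, list[GenomicInterval]],
    mode: str = BASE_WEIGHTED,
) -> pd.DataFrame:
    """Group-by-sample matrix of means of per-repeat means."""
    if not tracks:
        raise ValueError("need at least one sample track")
    cols = {}
    for sample, track in tracks.items():
        dists = group_distributions(track, groups, mode=mode)
        cols[sample] = {
            d.group: (float(d.values.mean()) if d.n else np.nan) for d in dists
        }
    return pd.DataFrame(cols).loc[list(groups)]


def hierarchical_order(
    matrix: pd.DataFrame | np.ndarray,
    axis: int = 0,
    metric: str = "euclidean",
    method: str = "complete",
) -> tuple[list[int], np.ndarray]:
    """Dendrogram leaf order and merge heights for one axis of a matrix.

    Complete-linkage agglomeration on euclidean distances by default; rows
    containing missing values are dropped (logged) before clustering.
    Returns (leaf order as indices into the clustered axis, merge heights).
    """
    values = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    if axis == 1:
        values = values.T
    n_before = values.shape[0]
    keep = ~np.isnan(values).any(axis=1)
    values = values[keep]
    if values.shape[0] < n_before:
        logger.warning(
            "dropped %d rows with missing values before clustering",
            n_before - values.shape[0],
        )
    if values.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    link = sch.linkage(pdist(values, metric=metric), method=method)
    order = list(sch.leaves_list(link))
    return order, link[:, 2].copy()


def linkage_to_newick(
    matrix: pd.DataFrame,
    axis: int = 0,
    metric: str = "euclidean",
    method: str = "complete",
) -> str:
    """Newick export of the dendrogram (branch lengths from merge heights)."""
    labels = list(matrix.index if axis == 0 else matrix.columns)
    values = matrix.to_numpy()
    if axis == 1:
        values = values.T
    link = sch.linkage(pdist(values, metric=metric), method=method)
    n = values.shape[0]
    heights = {i: 0.0 for i in range(n)}

    def build(node: int) -> str:
        if node < n:
            return labels[node]
        li, ri, h, _ = link[node - n]
        left, right = int(li), int(ri)
        bl = h - heights[left]
        br = h - heights[right]
        return f"({build(left)}:{bl / 2:g},{build(right)}:{br / 2:g})"

    for i, row in enumerate(link):
        heights[n + i] = row[2]
    return build(2 * n - 2) + ";"


def sample_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between sample columns (QC surface).

    Zero-variance columns produce NaN entries with a warning.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ValueError("need >= 2 samples and >= 2 rows")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=0)
    if np.any(sd == 0):
        logger.warning(
            "zero-variance samples: %s",
            [c for c, s in zip(matrix.columns, sd) if s == 0],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    return pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)


def distributions_to_frame(dists: Sequence[GroupDistribution]) -> pd.DataFrame:
    """Long-format table (group, value) for export/plotting."""
    return pd.DataFrame(
        [(d.group, v) for d in dists for v in d.values],
        columns=["group", "value"],
    )
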