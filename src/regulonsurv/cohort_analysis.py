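"""Downstream cohort associations: activity clustering and stage ANOVA.

Hierarchical clustering of the z-scored activity matrix (rows = regulators,
columns = samples) reproduces the usual expression-heatmap view of regulator
programs; one-way ANOVA relates the risk score to ordinal clinical stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import f_oneway

log = logging.getLogger("regulonsurv")

__all__ = ["ClusterLayout", "cluster_activity", "anova_by_stage"]


@dataclass
class ClusterLayout:
    """Leaf orders and merge records from clustering rows and columns."""

    row_order: list[int]
    col_order: list[int]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def ordered_rows(self) -> list[str]:
        return [self.row_labels[i] for i in self.row_order]

    def ordered_cols(self) -> list[str]:
        return [self.col_labels[i] for i in self.col_order]


def _linkage_for(data: np.ndarray, distance: str, method: str) -> np.ndarray:
    if distance == "euclidean":
        d = pdist(data, metric="euclidean")
    elif distance == "one_minus_pearson":
        d = pdist(data, metric="correlation")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    if method not in ("average", "complete", "ward"):
        raise ValueError(f"unknown linkage {method!r}")
    if method == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    return linkage(d, method=method)


def cluster_activity(
    z: pd.DataFrame,
    distance: str = "one_minus_pearson",
    method: str = "average",
) -> ClusterLayout:
    """Agglomerative clustering of rows and columns of a z-scored matrix.

    The default (one-minus-Pearson distance, average linkage) is the common
    choice for expression heatmaps.  Missing values are rejected; filter
    regulons/samples first.
    """
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    values = z.to_numpy(float)
    if not np.all(np.isfinite(values)):
        raise ValueError(
            "activity matrix contains missing values; apply the gene-presence "
            "filter / drop unscored samples before clustering"
        )
    row_link = _linkage_for(values, distance, method)
    col_link = _linkage_for(values.T, distance, method)
    return ClusterLayout(
        row_order=[int(i) for i in leaves_list(row_link)],
        col_order=[int(i) for i in leaves_list(col_link)],
        row_linkage=row_link,
        col_linkage=col_link,
        row_labels=list(z.index),
        col_labels=list(z.columns),
    )


def anova_by_stage(
    scores: pd.Series | np.ndarray,
    stage: np.ndarray,
) -> tuple[float, float, dict[str, float]]:
    """Classical one-way fixed-effects ANOVA of risk score across stages.

    Stages are treated as unordered groups (no trend test).  Samples with a
    missing stage are dropped and counted.  Returns (F, p, per-stage means).
    """
    values = scores.to_numpy(float) if isinstance(scores, pd.Series) else np.asarray(scores, float)
    stage = np.asarray(stage, dtype=object)
    if len(values) != len(stage):
        raise ValueError("scores and stage labels differ in length")
    present = np.array([s is not None and s == s for s in stage])  # drops None/NaN
    n_dropped = int((~present).sum())
    if n_dropped:
        log.info("ANOVA: dropped %d samples with missing stage", n_dropped)
    values, stage = values[present], stage[present]
    labels = sorted({str(s) for s in stage})
    groups = [values[stage.astype(str) == lab] for lab in labels]
    if len(groups) < 2:
        raise ValueError("need at least 2 stages for ANOVA")
    small = [lab for lab, g in zip(labels, groups) if len(g) < 2]
    if small:
        raise ValueError(f"stages with fewer than 2 samples: {small}")
    f_stat, p = f_oneway(*groups)
    means = {lab: float(g.mean()) for lab, g in zip(labels, groups)}
    return float(f_stat), float(p), means
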