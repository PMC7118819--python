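"""Per-sample regulator activity as recovery-curve AUC over expression ranks.

For one sample, genes are ranked by expression (highest first).  Scanning
down the ranking, the recovery curve ``y(x)`` counts how many regulon genes
appear within the top ``x`` ranks.  The activity score is the area under this
curve up to a rank cutoff ``x_max = ceil(cutoff_fraction * N)``, normalized
by the maximum achievable area for a regulon of the same size, so a perfect
front-loading of the regulon scores 1 and a regulon entirely below the cutoff
scores 0.  Because only ranks enter, the score is invariant to any strictly
increasing per-sample transform of the expression values — the property that
lets one model trained on RNA-seq be applied to microarray cohorts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix
from .regulon_builder import Regulon

log = logging.getLogger("regulonsurv")

__all__ = [
    "SampleRanking",
    "ActivityMatrix",
    "rank_genes",
    "recovery_auc",
    "score_activity_matrix",
    "standardize_activities",
    "write_activity_matrix",
    "read_activity_matrix",
]

DEFAULT_CUTOFF = 0.2
MIN_PRESENT_FRACTION = 0.8


@dataclass
class SampleRanking:
    """One sample's genes ordered by expression, highest first.

    Ties are broken by gene symbol ascending, so the ranking (and everything
    downstream) is bitwise reproducible.
    """

    sample_id: str
    ordered_genes: list[str]

    def positions(self) -> dict[str, int]:
        """1-based rank per gene (rank 1 = highest expression)."""
        return {g: i + 1 for i, g in enumerate(self.ordered_genes)}

    def __len__(self) -> int:
        return len(self.ordered_genes)


@dataclass
class ActivityMatrix:
    """Regulators x samples recovery-curve AUC scores in [0, 1].

    Unscorable entries (no regulon gene present for a sample) are NaN and
    excluded from downstream risk scoring.
    """

    regulators: list[str]
    sample_ids: list[str]
    scores: np.ndarray
    cutoff_fraction: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.regulators), len(self.sample_ids)):
            raise ValueError("score matrix shape does not match id lists")
        finite = self.scores[np.isfinite(self.scores)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("activity scores must lie in [0, 1]")
        if not 0.0 < self.cutoff_fraction < 1.0:
            raise ValueError("cutoff_fraction must be in (0, 1)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.regulators, columns=self.sample_ids)

    def row(self, regulator: str) -> np.ndarray:
        return self.scores[self.regulators.index(regulator)]


# ---------------------------------------------------------------------------
# ranking and AUC
# ---------------------------------------------------------------------------


def _rank_matrix(expr: ExpressionMatrix) -> np.ndarray:
    """1-based rank (descending expression, symbol tie-break) per gene/sample."""
    sym_order = np.argsort(np.array(expr.gene_ids))  # symbols ascending
    n_genes, n_samples = expr.values.shape
    ranks = np.empty((n_genes, n_samples), dtype=np.int64)
    positions = np.arange(1, n_genes + 1)
    for s in range(n_samples):
        vals = expr.values[sym_order, s]
        order = np.argsort(-vals, kind="stable")  # stable: ties stay in symbol order
        ranks[sym_order[order], s] = positions
    return ranks


def rank_genes(
    expr: ExpressionMatrix,
    sample_id: str,
    tie_break: str = "symbol",
    seed: int | None = None,
) -> SampleRanking:
    """Rank one sample's genes by expression descending.

    Ties are broken by gene symbol ascending (the default, bitwise
    reproducible) or, with ``tie_break="random"``, by a seeded random
    permutation for comparison runs.
    """
    try:
        s = expr.sample_index()[sample_id]
    except KeyError:
        raise KeyError(f"sample {sample_id!r} not in expression matrix") from None
    if tie_break == "symbol":
        keys = expr.gene_ids
    elif tie_break == "random":
        rng = np.random.default_rng(seed)
        keys = rng.permutation(expr.n_genes).tolist()
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    order = sorted(range(expr.n_genes), key=lambda i: (-expr.values[i, s], keys[i]))
    return SampleRanking(sample_id, [expr.gene_ids[i] for i in order])


def recovery_auc(
    ranking: SampleRanking,
    regulon: Regulon,
    cutoff_fraction: float = DEFAULT_CUTOFF,
) -> float:
    """Area under one regulon's recovery curve, normalized to [0, 1].

    With ``N`` ranked genes, ``x_max = ceil(cutoff_fraction * N)`` and ``m``
    regulon genes present, the raw area is ``sum_{x=1..x_max} y(x)`` where
    ``y(x)`` counts regulon genes at rank <= x, and the score is the raw area
    divided by its maximum ``sum_{x=1..x_max} min(x, m)``.  Returns NaN (and
    logs) when no regulon gene is present in the ranking.
    """
    N = len(ranking)
    x_max = math.ceil(cutoff_fraction * N)
    pos = ranking.positions()
    target_ranks = np.array([pos[g] for g in regulon.targets if g in pos])
    m = len(target_ranks)
    if m == 0:
        log.warning(
            "regulon %s has no genes in sample %s ranking; score is missing",
            regulon.regulator, ranking.sample_id,
        )
        return float("nan")
    raw = int(np.clip(x_max - target_ranks + 1, 0, None).sum())
    x = np.arange(1, x_max + 1)
    max_raw = int(np.minimum(x, m).sum())
    return raw / max_raw


def score_activity_matrix(
    expr: ExpressionMatrix,
    regulons: list[Regulon],
    cutoff_fraction: float = DEFAULT_CUTOFF,
    min_present_fraction: float = MIN_PRESENT_FRACTION,
) -> ActivityMatrix:
    """Score every regulon in every sample.

    Regulons with fewer than ``min_present_fraction`` of their genes present
    in the matrix are dropped with a warning rather than silently rescored —
    losing many genes to a platform's gene set changes what the score means.
    One ranking is computed per sample and reused across regulons.
    """
    if not 0.0 < cutoff_fraction < 1.0:
        raise ValueError("cutoff_fraction must be in (0, 1)")
    gene_index = expr.gene_index()
    kept: list[Regulon] = []
    for regulon in regulons:
        present = [g for g in regulon.targets if g in gene_index]
        frac = len(present) / len(regulon.targets)
        if frac < min_present_fraction:
            log.warning(
                "regulon %s dropped: only %.0f%% of %d genes present (< %.0f%%)",
                regulon.regulator, 100 * frac, len(regulon.targets),
                100 * min_present_fraction,
            )
            continue
        kept.append(regulon)
    if not kept:
        raise ValueError("no regulon passes the gene-presence filter")

    ranks = _rank_matrix(expr)  # genes x samples, 1-based
    N = expr.n_genes
    x_max = math.ceil(cutoff_fraction * N)
    scores = np.empty((len(kept), expr.n_samples))
    for i, regulon in enumerate(kept):
        idx = [gene_index[g] for g in regulon.targets if g in gene_index]
        m = len(idx)
        x = np.arange(1, x_max + 1)
        max_raw = np.minimum(x, m).sum()
        # a gene at rank k <= x_max contributes (x_max - k + 1) to the area
        raw = np.clip(x_max - ranks[idx] + 1, 0, None).sum(axis=0)
        scores[i] = raw / max_raw
    return ActivityMatrix([r.regulator for r in kept], list(expr.sample_ids), scores, cutoff_fraction)


def standardize_activities(act: ActivityMatrix) -> pd.DataFrame:
    """Z-score each regulator row across samples (population SD).

    Zero-variance rows are dropped with a warning; NaN entries are ignored in
    the statistics and propagate.
    """
    frame = act.to_frame()
    means = frame.mean(axis=1)
    sds = frame.std(axis=1, ddof=0)
    keep = sds > 0
    for reg in frame.index[~keep]:
        log.warning("regulator %s has zero activity variance; dropped from z-scores", reg)
    if not keep.any():
        raise ValueError("all regulator rows have zero variance")
    frame = frame.loc[keep]
    return frame.sub(means[keep], axis=0).div(sds[keep], axis=0)


def write_activity_matrix(act: ActivityMatrix, path: str | Path) -> None:
    frame = act.to_frame()
    frame.index.name = "regulator"
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_activity_matrix(path: str | Path, cutoff_fraction: float = DEFAULT_CUTOFF) -> ActivityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ActivityMatrix(
        list(frame.index), list(frame.columns), frame.to_numpy(float), cutoff_fraction
    )
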