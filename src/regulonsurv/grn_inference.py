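"""Nonlinear co-expression scoring of regulator -> gene pairs.

For every gene, a stochastic gradient-boosted regression of the gene's
(z-scored) expression on all regulator expressions is fitted and the total
split gain attributed to each regulator over the ensemble becomes the
importance of the (regulator, gene) pair.  The importances are used purely as
a ranking to keep the top fraction of pairs, so the responses are
standardized before fitting to make gains comparable across genes and exactly
invariant to per-gene affine rescaling of the input.

A fast mode scoring pairs by absolute Spearman correlation is provided for
small machines and smoke tests; it is not the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExpressionMatrix, normalize_symbol

log = logging.getLogger("regulonsurv")

__all__ = [
    "BoostingParams",
    "ImportanceTable",
    "infer_importances",
    "write_importances",
    "read_importances",
]

MIN_SAMPLES = 20


@dataclass
class BoostingParams:
    """Hyperparameters of the per-gene boosted regression.

    The source method publishes no settings; these follow common
    gradient-boosting GRN practice (many shallow trees, small learning rate,
    row subsampling, sqrt-of-p feature sampling per split) and are all
    exposed through the pipeline config.
    """

    n_rounds: int = 500
    learning_rate: float = 0.01
    subsample: float = 0.9
    feature_fraction: str | float = "sqrt"
    max_depth: int = 3
    min_child_samples: int = 20

    def resolved_feature_fraction(self, n_features: int) -> float:
        if self.feature_fraction == "sqrt":
            return min(1.0, max(1, int(np.sqrt(n_features))) / n_features)
        return float(self.feature_fraction)


@dataclass
class ImportanceTable:
    """Scored (regulator, gene, importance) records, one per candidate pair."""

    records: pd.DataFrame  # columns: regulator, gene, importance

    def __post_init__(self) -> None:
        required = {"regulator", "gene", "importance"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"importance table needs columns {sorted(required)}")
        rec = self.records
        if (rec["regulator"] == rec["gene"]).any():
            raise ValueError("importance table contains self pairs")
        if rec.duplicated(["regulator", "gene"]).any():
            raise ValueError("importance table contains repeated pairs")
        imp = rec["importance"].to_numpy(float)
        if not np.all(np.isfinite(imp)) or np.any(imp < 0):
            raise ValueError("importances must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.records)

    def sorted(self) -> pd.DataFrame:
        return self.records.sort_values(
            ["importance", "regulator", "gene"], ascending=[False, True, True]
        ).reset_index(drop=True)


def infer_importances(
    expr: ExpressionMatrix,
    regulators: list[str],
    params: BoostingParams | None = None,
    seed: int = 0,
    mode: str = "boosting",
    min_samples: int = MIN_SAMPLES,
) -> ImportanceTable:
    """Score every (regulator, candidate gene) pair on the training matrix.

    Candidate genes are all genes in the matrix; a regulator is never a
    predictor of itself.  Zero-variance genes are skipped (their importances
    recorded as 0 and the skip logged).  Deterministic given ``seed``.
    """
    params = params or BoostingParams()
    regulators = [normalize_symbol(r) for r in regulators]
    gene_index = expr.gene_index()
    missing = [r for r in regulators if r not in gene_index]
    if missing:
        raise KeyError(f"regulators absent from expression matrix: {missing}")
    if expr.n_samples < min_samples:
        raise ValueError(
            f"need at least {min_samples} samples for co-expression inference, "
            f"have {expr.n_samples}"
        )
    if mode not in ("boosting", "spearman"):
        raise ValueError(f"unknown inference mode {mode!r}")

    reg_idx = np.array([gene_index[r] for r in regulators])
    X = expr.values[reg_idx].T  # samples x regulators
    reg_set = set(regulators)
    log.info(
        "co-expression inference: %d regulators x %d genes, mode=%s, params=%s",
        len(regulators), expr.n_genes, mode, asdict(params),
    )

    gene_sd = expr.values.std(axis=1)
    n_skipped = int((gene_sd == 0.0).sum())
    if n_skipped:
        log.info("skipping %d zero-variance genes (importances set to 0)", n_skipped)

    if mode == "spearman":
        imp_matrix = np.abs(_rank_correlations(expr.values[reg_idx], expr.values))
    else:
        imp_matrix = np.zeros((len(regulators), expr.n_genes))
        seeds = np.random.SeedSequence(seed).generate_state(expr.n_genes) % (2**31)
        for gi, gene in enumerate(expr.gene_ids):
            if gene_sd[gi] == 0.0:
                continue
            y = expr.values[gi]
            cols = [j for j, r in enumerate(regulators) if r != gene]
            gains = _boosted_gain(X[:, cols], (y - y.mean()) / gene_sd[gi], params, int(seeds[gi]))
            imp_matrix[cols, gi] = gains

    rows_reg: list[str] = []
    rows_gene: list[str] = []
    rows_imp: list[float] = []
    for gi, gene in enumerate(expr.gene_ids):
        for rj, reg in enumerate(regulators):
            if reg == gene:
                continue
            rows_reg.append(reg)
            rows_gene.append(gene)
            rows_imp.append(float(imp_matrix[rj, gi]) if gene_sd[gi] > 0 else 0.0)

    table = pd.DataFrame({"regulator": rows_reg, "gene": rows_gene, "importance": rows_imp})
    return ImportanceTable(table)


def _rank_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Spearman correlation of every row of A against every row of B."""

    def _standardized_ranks(M: np.ndarray) -> np.ndarray:
        ranks = np.apply_along_axis(rankdata, 1, M)
        ranks -= ranks.mean(axis=1, keepdims=True)
        sd = ranks.std(axis=1, keepdims=True)
        sd[sd == 0] = np.inf  # constant rows get correlation 0
        return ranks / sd

    ra, rb = _standardized_ranks(A), _standardized_ranks(B)
    return ra @ rb.T / A.shape[1]


def _boosted_gain(X: np.ndarray, y: np.ndarray, params: BoostingParams, seed: int) -> np.ndarray:
    """Total split gain per feature from one LightGBM regression ensemble."""
    import lightgbm as lgb

    model = lgb.LGBMRegressor(
        n_estimators=params.n_rounds,
        learning_rate=params.learning_rate,
        subsample=params.subsample,
        subsample_freq=1 if params.subsample < 1.0 else 0,
        colsample_bynode=params.resolved_feature_fraction(X.shape[1]),
        max_depth=params.max_depth,
        num_leaves=2**params.max_depth,
        min_child_samples=params.min_child_samples,
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
        importance_type="gain",
    )
    model.fit(X, y)
    return np.asarray(model.feature_importances_, dtype=float)


def write_importances(table: ImportanceTable, path: str | Path) -> None:
    """Write the table as 3-column TSV sorted by importance desc, regulator, gene."""
    table.sorted().to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_importances(path: str | Path) -> ImportanceTable:
    frame = pd.read_csv(path, sep="\t", dtype={"regulator": str, "gene": str})
    return ImportanceTable(frame)
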