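"""Refine ChIP-derived candidate targets into cohort-specific regulons.

The top fraction (default 5%) of all scored regulator-gene pairs is
intersected with each regulator's ChIP-derived candidate targets; the
intersection is the regulon used for activity scoring.  Regulons smaller than
a minimum size are dropped, since an activity estimated from a handful of
genes loses the averaging that makes the score robust.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .grn_inference import ImportanceTable
from .io_formats import RegulatorTargetMap

log = logging.getLogger("regulonsurv")

__all__ = ["Regulon", "select_top_pairs", "build_regulons"]


@dataclass
class Regulon:
    """A regulator with its refined target set and provenance counts."""

    regulator: str
    targets: set[str]
    n_chip_targets: int = 0
    n_top_pairs_for_regulator: int = 0
    n_intersection: int = 0

    def __post_init__(self) -> None:
        if self.regulator in self.targets:
            raise ValueError(f"regulon {self.regulator} contains itself")

    def __len__(self) -> int:
        return len(self.targets)


def select_top_pairs(
    importances: ImportanceTable,
    top_fraction: float = 0.05,
    scope: str = "global",
) -> set[tuple[str, str]]:
    """Keep the highest-scoring fraction of regulator-gene pairs.

    ``scope="global"`` cuts the top ``floor(top_fraction * n_pairs)`` over all
    pairs (the default reading of a single top-5% cut); ``"per_regulator"``
    applies the same rule within each regulator's pairs.  Ties at the boundary
    are broken by (importance desc, regulator asc, gene asc) so the kept count
    is exact and deterministic.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    if len(importances) == 0:
        raise ValueError("importance table is empty")
    ordered = importances.sorted()
    if scope == "global":
        k = math.floor(top_fraction * len(ordered))
        if k == 0:
            raise ValueError(
                f"top_fraction={top_fraction} keeps zero of {len(ordered)} pairs; "
                "increase the fraction"
            )
        kept = ordered.head(k)
    elif scope == "per_regulator":
        grouped = ordered.groupby("regulator", sort=False)
        quota = np.maximum(1, np.floor(top_fraction * grouped["gene"].transform("size")))
        kept = ordered[grouped.cumcount() < quota]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return set(zip(kept["regulator"], kept["gene"]))


def build_regulons(
    pairs: set[tuple[str, str]],
    target_map: RegulatorTargetMap,
    min_size: int = 10,
) -> list[Regulon]:
    """Intersect top co-expression pairs with ChIP candidate targets.

    Regulators absent from the target map are skipped with a warning;
    regulons below ``min_size`` are dropped with a logged reason.  Purely
    set-algebraic: deterministic given its inputs.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    by_regulator: dict[str, set[str]] = {}
    for reg, gene in pairs:
        by_regulator.setdefault(reg, set()).add(gene)

    regulons: list[Regulon] = []
    for reg in sorted(by_regulator):
        if reg not in target_map:
            log.warning("regulator %s has top pairs but no ChIP targets; skipped", reg)
            continue
        chip = target_map[reg]
        top = by_regulator[reg]
        intersection = (top & chip) - {reg}
        if len(intersection) < min_size:
            log.info(
                "regulon %s dropped: intersection %d < min_size %d",
                reg, len(intersection), min_size,
            )
            continue
        regulons.append(
            Regulon(
                regulator=reg,
                targets=intersection,
                n_chip_targets=len(chip),
                n_top_pairs_for_regulator=len(top),
                n_intersection=len(intersection),
            )
        )
    return regulons
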