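"""Readers and writers for expression matrices, regulator target maps, regulons
and clinical tables.

All gene and regulator symbols are uppercased and stripped of surrounding
whitespace on load, so joins between expression matrices and target maps are
case-insensitive by construction.  Expression files are tab-separated with
genes in rows (first column ``gene``) and samples in columns; target maps are
either two-column (regulator, target) TSV or GMT; clinical tables are TSV with
at least ``sample``, ``time_days`` (or ``time``) and ``event`` columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("regulonsurv")

__all__ = [
    "ExpressionMatrix",
    "RegulatorTargetMap",
    "SurvivalTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_target_map",
    "write_target_map",
    "read_survival_table",
    "write_survival_table",
    "write_regulons_gmt",
]


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene/regulator symbol."""
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of (log-scale) expression values.

    Gene symbols are unique and uppercase; sample identifiers are unique;
    every value is finite.  This is the ranking substrate for activity
    scoring, so only the within-sample ordering of values carries meaning
    downstream.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [normalize_symbol(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValueError(f"duplicate gene symbols: {sorted(dupes)[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValueError(f"duplicate sample ids: {sorted(dupes)[:5]}")
        if self.values.size == 0:
            raise ValueError("empty expression matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        keep = [idx[normalize_symbol(g)] for g in genes]
        return ExpressionMatrix(
            [self.gene_ids[i] for i in keep], list(self.sample_ids), self.values[keep]
        )


@dataclass
class RegulatorTargetMap:
    """Candidate (e.g. ChIP-derived) target genes per transcription regulator."""

    entries: dict[str, set[str]]

    def __post_init__(self) -> None:
        cleaned: dict[str, set[str]] = {}
        for reg, targets in self.entries.items():
            reg_n = normalize_symbol(reg)
            tset = {normalize_symbol(t) for t in targets}
            tset.discard(reg_n)
            if not tset:
                log.warning("regulator %s has no targets after cleanup; dropped", reg_n)
                continue
            if reg_n in cleaned:
                raise ValueError(f"duplicate regulator symbol {reg_n}")
            cleaned[reg_n] = tset
        self.entries = cleaned

    @property
    def regulators(self) -> list[str]:
        return sorted(self.entries)

    def __getitem__(self, regulator: str) -> set[str]:
        return self.entries[normalize_symbol(regulator)]

    def __contains__(self, regulator: str) -> bool:
        return normalize_symbol(regulator) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class SurvivalTable:
    """Per-sample overall-survival time (days), event indicator and optional
    clinical labels (stage, subtype, ER/PR/HER2 receptor status)."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    stage: np.ndarray | None = None
    subtype: np.ndarray | None = None
    receptor_status: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError(f"duplicate sample ids: {sorted(_duplicates(self.sample_ids))[:5]}")
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length does not match sample ids")
        if np.any(self.time < 0):
            bad = self.sample_ids[int(np.argmax(self.time < 0))]
            raise ValueError(f"negative survival time for sample {bad}")
        bad_event = ~np.isin(self.event, [0, 1])
        if np.any(bad_event):
            bad = self.sample_ids[int(np.argmax(bad_event))]
            raise ValueError(f"event indicator outside {{0,1}} for sample {bad}")
        self.event = self.event.astype(int)
        if self.stage is not None:
            self.stage = np.asarray(self.stage, dtype=object)
        if self.subtype is not None:
            self.subtype = np.asarray(self.subtype, dtype=object)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def align(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        """Subset/reorder to the given samples (all must be present)."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples absent from survival table: {missing[:5]}")
        order = [idx[s] for s in sample_ids]
        return SurvivalTable(
            [self.sample_ids[i] for i in order],
            self.time[order],
            self.event[order],
            None if self.stage is None else self.stage[order],
            None if self.subtype is None else self.subtype[order],
            {k: v[order] for k, v in self.receptor_status.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray | list] = {
            "sample": self.sample_ids,
            "time_days": self.time,
            "event": self.event,
        }
        if self.stage is not None:
            data["stage"] = self.stage
        if self.subtype is not None:
            data["subtype"] = self.subtype
        for key, vals in self.receptor_status.items():
            data[key] = vals
        return pd.DataFrame(data)


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def read_expression_matrix(
    path: str | Path, probe_map: Mapping[str, str] | None = None
) -> ExpressionMatrix:
    """Read a tab-separated genes x samples matrix.

    First column holds gene (or probe) identifiers, header row holds sample
    ids.  When ``probe_map`` is given, probe ids are mapped to gene symbols
    (unmapped probes dropped) and probes annotated to the same gene are merged
    by the arithmetic mean of their values per sample — values are assumed to
    already be on a log scale, so no re-exponentiation is performed.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = [h.strip() for h in header[1:]]
    dupes = _duplicates(sample_ids)
    if dupes:
        raise ValueError(f"duplicate sample ids in header: {sorted(dupes)}")
    if not sample_ids:
        raise ValueError(f"no sample columns in {path}")

    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, skiprows=1, header=None)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty expression matrix in {path}") from None
    raw.columns = sample_ids
    if raw.empty:
        raise ValueError(f"empty expression matrix in {path}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {raw.iat[r, c]!r} at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing value at row {raw.index[r]!r}, column {raw.columns[c]!r}")

    if probe_map is not None:
        mapping = {str(k).strip(): normalize_symbol(v) for k, v in probe_map.items()}
        probes = pd.Series(numeric.index.astype(str).str.strip(), index=numeric.index)
        genes = probes.map(mapping)
        mapped = genes.notna().to_numpy()
        n_unmapped = int((~mapped).sum())
        if n_unmapped:
            log.info("dropping %d probes without a gene mapping", n_unmapped)
        numeric = numeric.loc[mapped]
        numeric.index = pd.Index(genes.to_numpy()[mapped])
    else:
        numeric.index = numeric.index.astype(str).str.strip().str.upper()

    # merge any duplicate symbols (multiple probes, or case-collisions) by mean
    if numeric.index.has_duplicates:
        numeric = numeric.groupby(level=0, sort=True).mean()
    else:
        numeric = numeric.sort_index()
    return ExpressionMatrix.from_frame(numeric)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    frame = expr.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# target maps and regulons
# ---------------------------------------------------------------------------


def read_target_map(path: str | Path, format: str = "tsv2col") -> RegulatorTargetMap:
    """Read a regulator -> target-genes map from 2-column TSV or GMT.

    Targets are deduplicated per regulator and a regulator listed among its
    own targets is removed (handled by :class:`RegulatorTargetMap`).
    """
    path = Path(path)
    entries: dict[str, set[str]] = {}
    if format == "tsv2col":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                    raise ValueError(f"{path}:{lineno}: expected 'regulator<TAB>target', got {line!r}")
                entries.setdefault(normalize_symbol(parts[0]), set()).add(normalize_symbol(parts[1]))
    elif format == "gmt":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(parts)}")
                name = normalize_symbol(parts[0])
                if name in entries:
                    raise ValueError(f"{path}:{lineno}: duplicate set name {name}")
                entries[name] = {normalize_symbol(g) for g in parts[2:] if g.strip()}
    else:
        raise ValueError(f"unknown target map format {format!r}")
    return RegulatorTargetMap(entries)


def write_target_map(target_map: RegulatorTargetMap, path: str | Path) -> None:
    """Write a target map as two-column (regulator, target) TSV."""
    with open(path, "w") as fh:
        for reg in target_map.regulators:
            for target in sorted(target_map.entries[reg]):
                fh.write(f"{reg}\t{target}\n")


def write_regulons_gmt(regulons: Sequence, path: str | Path) -> None:
    """Write refined regulons as GMT (name, 'refined_regulon', members).

    Round-trips losslessly through ``read_target_map(format='gmt')``.
    """
    if not regulons:
        raise ValueError("no regulons to write")
    with open(path, "w") as fh:
        for regulon in regulons:
            members = "\t".join(sorted(regulon.targets))
            fh.write(f"{regulon.regulator}\trefined_regulon\t{members}\n")


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

_RECEPTOR_COLUMNS = ("er", "pr", "her2")


def read_survival_table(path: str | Path) -> SurvivalTable:
    """Read a clinical TSV with sample, time_days (or time), event columns.

    Rows with missing time or event are dropped (count logged); optional
    stage/subtype/receptor columns are kept when present.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str})
    cols = {c.lower(): c for c in frame.columns}
    if "sample" not in cols:
        raise ValueError(f"{path}: missing required column 'sample'")
    time_col = cols.get("time_days") or cols.get("time")
    if time_col is None:
        raise ValueError(f"{path}: missing required column 'time_days'")
    if "event" not in cols:
        raise ValueError(f"{path}: missing required column 'event'")

    time = pd.to_numeric(frame[time_col], errors="coerce")
    event = pd.to_numeric(frame[cols["event"]], errors="coerce")
    complete = time.notna() & event.notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("dropped %d rows with missing time or event from %s", n_dropped, path)
    frame = frame.loc[complete]
    time = time[complete]
    event = event[complete]

    bad_event = ~event.isin([0, 1])
    if bad_event.any():
        sample = frame[cols["sample"]][bad_event].iloc[0]
        raise ValueError(f"{path}: event value outside {{0,1}} for sample {sample!r}")
    if (time < 0).any():
        sample = frame[cols["sample"]][time < 0].iloc[0]
        raise ValueError(f"{path}: negative time for sample {sample!r}")

    def _optional(name: str) -> np.ndarray | None:
        if name not in cols:
            return None
        vals = frame[cols[name]]
        return np.where(vals.isna(), None, vals.astype(object))

    receptor = {}
    for rc in _RECEPTOR_COLUMNS:
        vals = _optional(rc)
        if vals is not None:
            receptor[rc] = vals
    return SurvivalTable(
        list(frame[cols["sample"]].astype(str)),
        time.to_numpy(),
        event.to_numpy(int),
        stage=_optional("stage"),
        subtype=_optional("subtype"),
        receptor_status=receptor,
    )


def write_survival_table(table: SurvivalTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
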