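"""miRNA target tables, the read-count >= 10 "true target" filter, and
procedure-by-timepoint presence/exclusivity patterns.

The biology being encoded: a miRNA-target interaction only matters in a
tissue where the target mRNA is actually expressed, so target records are
kept only when the target gene reaches a minimum read count in at least
one sample.  The same detection threshold defines *presence* of a miRNA
(precursor) in a (procedure, timepoint) cell — any replicate over
threshold — from which procedure-exclusive miRNAs and earlier-appearance
orderings are derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError, DuplicateKeyError, FormatError

__all__ = [
    "read_target_table",
    "write_target_table",
    "filter_true_targets",
    "presence_patterns",
    "ExclusivityReport",
    "exclusive_mirnas",
]

logger = logging.getLogger(__name__)

TARGET_COLUMNS = ("mirna_id", "target_gene", "evidence")

#: Detection threshold: a gene/miRNA counts as present with >= 10 reads.
DEFAULT_MIN_READS = 10


def read_target_table(path) -> pd.DataFrame:
    """Read a miRNA->target TSV (mirna_id, target_gene, evidence)."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in TARGET_COLUMNS[:2] if c not in table.columns]
    if missing:
        raise FormatError(f"target table {path} lacks columns {missing}")
    if "evidence" not in table.columns:
        table["evidence"] = ""
    _check_no_duplicate_pairs(table)
    return table[list(TARGET_COLUMNS)]


def write_target_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def _check_no_duplicate_pairs(table: pd.DataFrame) -> None:
    dup = table.duplicated(subset=["mirna_id", "target_gene"])
    if dup.any():
        pair = table.loc[dup, ["mirna_id", "target_gene"]].iloc[0].tolist()
        raise DuplicateKeyError(f"duplicate (mirna, target) pair {pair}")


def filter_true_targets(
    targets: pd.DataFrame, expr: pd.DataFrame, min_reads: int = DEFAULT_MIN_READS
) -> pd.DataFrame:
    """Keep target records whose gene reaches >= min_reads in >= 1 sample.

    ``expr`` must be raw counts.  The boundary is inclusive (exactly 10
    reads keeps a record).  Idempotent, and monotone in ``min_reads``:
    a larger threshold always yields a subset.
    """
    _check_no_duplicate_pairs(targets)
    detected = set(expr.index[(expr >= min_reads).any(axis=1)])
    keep = targets["target_gene"].isin(detected)
    removed = int((~keep).sum())
    if removed:
        logger.info(
            "filter_true_targets removed %d records below %d reads",
            removed,
            min_reads,
        )
    return targets.loc[keep].reset_index(drop=True)


def presence_patterns(
    mirna_expr: pd.DataFrame,
    design: pd.DataFrame,
    threshold: int = DEFAULT_MIN_READS,
    include_reference: bool = False,
) -> pd.DataFrame:
    """Boolean presence grid: miRNA x (procedure, timepoint_h).

    Presence in a cell means any replicate of that (procedure, timepoint)
    reaches >= threshold counts.  A design cell with no samples is marked
    absent with a warning.
    """
    rows = design if include_reference else design[~design["is_reference"].astype(bool)]
    cells: dict[tuple[str, float], list[str]] = {}
    for sample, row in rows.iterrows():
        cells.setdefault(
            (row["procedure"], float(row["timepoint_h"])), []
        ).append(sample)
    ordered = sorted(cells)
    data = {}
    for cell in ordered:
        samples = [s for s in cells[cell] if s in mirna_expr.columns]
        if not samples:
            logger.warning("design cell %s has no expression samples", cell)
            data[cell] = pd.Series(False, index=mirna_expr.index)
        else:
            data[cell] = (mirna_expr[samples] >= threshold).any(axis=1)
    grid = pd.DataFrame(data)
    grid.columns = pd.MultiIndex.from_tuples(ordered, names=["procedure", "timepoint_h"])
    return grid


@dataclass
class ExclusivityReport:
    """Exclusive miRNAs of one procedure plus cross-procedure first appearances.

    ``exclusive`` maps each miRNA present in the named procedure and absent
    from every timepoint of every other procedure to its earliest presence
    timepoint.  ``first_seen`` (miRNA x procedure, NaN = never detected)
    supports earlier-appearance statements for shared miRNAs.
    """

    procedure: str
    exclusive: dict[str, float]
    first_seen: pd.DataFrame


def exclusive_mirnas(patterns: pd.DataFrame, procedure: str) -> ExclusivityReport:
    """Procedure-exclusive miRNAs and the first-appearance table."""
    procedures = patterns.columns.get_level_values("procedure").unique().tolist()
    if procedure not in procedures:
        raise DesignError(f"procedure {procedure!r} not in pattern grid")
    if len(procedures) < 2:
        raise DesignError("exclusivity needs patterns over >= 2 procedures")
    first_seen = pd.DataFrame(np.nan, index=patterns.index, columns=procedures)
    for proc in procedures:
        block = patterns[proc]  # miRNA x timepoints
        tps = np.asarray(block.columns, dtype=float)
        present = block.to_numpy(dtype=bool)
        has_any = present.any(axis=1)
        first_idx = present.argmax(axis=1)
        first_seen.loc[has_any, proc] = tps[first_idx[has_any]]
    in_proc = first_seen[procedure].notna()
    others = [p for p in procedures if p != procedure]
    absent_elsewhere = first_seen[others].isna().all(axis=1)
    exclusive = {
        mirna: float(first_seen.at[mirna, procedure])
        for mirna in patterns.index[in_proc & absent_elsewhere]
    }
    return ExclusivityReport(procedure, exclusive, first_seen)
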