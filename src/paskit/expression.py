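"""Count-matrix and sample-design I/O, normalization, expression filtering.

Expression matrices are plain :class:`pandas.DataFrame` objects, genes as
rows (index named ``gene_id``) and samples as columns, all values >= 0.
Sample designs are DataFrames indexed by ``sample_id`` with columns
``procedure`` (surgical procedure label), ``timepoint_h`` (hours
post-surgery), ``replicate`` and ``is_reference`` (0/1 flag marking the
normal/reference group every case sample is scored against).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    DesignError,
    DuplicateKeyError,
    FormatError,
    ParameterError,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "validate_design",
    "reference_samples",
    "normalize",
    "filter_expressed",
]

logger = logging.getLogger(__name__)

#: HTSeq-count appends summary rows ("__no_feature", "__ambiguous", ...)
#: below the per-gene counts; they are not genes and are dropped on read.
HTSEQ_SUMMARY_PREFIX = "__"

DESIGN_COLUMNS = ("procedure", "timepoint_h", "replicate", "is_reference")


def read_counts(path) -> pd.DataFrame:
    """Read an HTSeq-count style TSV (first column gene id, header = samples).

    Summary rows whose id begins with ``__`` are dropped and counted in a
    log message.  Negative values and duplicate gene ids are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    summary = df.index.astype(str).str.startswith(HTSEQ_SUMMARY_PREFIX)
    if summary.any():
        logger.info("dropped %d HTSeq summary rows from %s", summary.sum(), path)
        df = df.loc[~summary]
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DuplicateKeyError(f"duplicate gene ids in {path}: {dupes[:5]}")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"negative expression values in {path}")
    return df


def write_counts(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_design(path) -> pd.DataFrame:
    """Read a sample design TSV (sample_id, procedure, timepoint_h, replicate, is_reference)."""
    design = pd.read_csv(path, sep="\t", index_col="sample_id")
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise FormatError(f"design {path} lacks columns {missing}")
    return design


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index_label="sample_id")


def validate_design(design: pd.DataFrame, matrix: pd.DataFrame | None = None) -> None:
    """Check design invariants, optionally against an expression matrix.

    Every sample must have exactly one design row and the reference group
    must contain at least 2 samples (a tolerance interval needs a spread).
    """
    if design.index.duplicated().any():
        raise DuplicateKeyError("duplicate sample ids in design")
    if int(design["is_reference"].astype(bool).sum()) < 2:
        raise DesignError("design must flag at least 2 reference samples")
    if matrix is not None:
        missing = [s for s in matrix.columns if s not in design.index]
        if missing:
            raise DesignError(f"samples without design rows: {missing[:5]}")


def reference_samples(design: pd.DataFrame) -> list[str]:
    """Sample ids of the normal/reference group, in design order."""
    refs = design.index[design["is_reference"].astype(bool)].tolist()
    if len(refs) < 2:
        raise DesignError(
            f"reference group has {len(refs)} samples; at least 2 required"
        )
    return refs


def normalize(matrix: pd.DataFrame, method: str = "cpm") -> pd.DataFrame:
    """Library-size normalization.

    ``cpm`` rescales each column to sum to 10^6; ``median_ratio`` scales each
    column by the median of per-gene ratios to the geometric-mean reference
    profile (computed over genes positive in every sample); ``none`` is the
    identity.  CPM is the default because the downstream activation score
    depends only on case-to-reference ratios, which any per-column scaling
    preserves.
    """
    if method == "none":
        return matrix.copy()
    if method == "cpm":
        sums = matrix.sum(axis=0)
        if (sums <= 0).any():
            bad = sums.index[sums <= 0].tolist()
            raise DegenerateInputError(f"all-zero columns: {bad[:5]}")
        return matrix / sums * 1e6
    if method == "median_ratio":
        values = matrix.to_numpy(dtype=float)
        positive = (values > 0).all(axis=1)
        if not positive.any():
            raise DegenerateInputError(
                "median_ratio needs at least one gene positive in every sample"
            )
        logs = np.log(values[positive])
        log_ref = logs.mean(axis=1, keepdims=True)  # geometric-mean profile
        factors = np.exp(np.median(logs - log_ref, axis=0))
        return matrix / factors
    raise ParameterError(f"unknown normalization method {method!r}")


def filter_expressed(
    matrix: pd.DataFrame, min_count: float = 10, min_samples: int = 1
) -> pd.DataFrame:
    """Keep genes with >= ``min_count`` in >= ``min_samples`` samples.

    Gene order is preserved; the operation is idempotent.  The defaults
    borrow the read-count >= 10 detection convention used elsewhere in the
    pipeline for miRNA targets.
    """
    if min_count < 0:
        raise ParameterError("min_count must be >= 0")
    if min_samples < 1:
        raise ParameterError("min_samples must be >= 1")
    if min_samples > matrix.shape[1]:
        raise ParameterError(
            f"min_samples={min_samples} exceeds sample count {matrix.shape[1]}"
        )
    keep = (matrix >= min_count).sum(axis=1) >= min_samples
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_expressed dropped %d genes", dropped)
    return matrix.loc[keep]
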