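"""Single-sample, rank-based gene-set enrichment scores.

Used for cell-cycle phase signatures (e.g. a G1/S transition gene set):
each sample gets one score per signature, so the kinetics of cell-cycle
engagement can be compared across surgical procedures sample by sample.

The scorer is a Kolmogorov-Smirnov-like running sum on the sample's gene
ranks: genes are walked in decreasing-abundance order, stepping up by
1/|signature genes present| on set members and down by 1/|non-members|
otherwise; the score is the maximum deviation of this walk, signed by its
direction, and lies in [-1, 1].  Being rank-based, the score is invariant
under any strictly monotone transform of the abundance vector.  This is a
deliberately simple single-sample statistic: the kernel-density variant
used by some established tools is not reproduced, because the questions
asked of these scores (which condition's score rises first) are
rank-ordering properties robust to the exact scorer.

Ties in abundance are broken lexicographically by gene id, making every
score deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

__all__ = [
    "GeneSignature",
    "read_gmt",
    "sample_enrichment_score",
    "enrichment_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set (signature) with unique members."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("signature name must be non-empty")
        if not self.genes:
            raise FormatError(f"signature {self.name!r} has no genes")


def read_gmt(path) -> list[GeneSignature]:
    """Read standard GMT: name, description, then member genes, tab-separated."""
    signatures = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"line {lineno}: GMT record needs name, description and "
                    f">= 1 gene"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            signatures.append(GeneSignature(name, frozenset(genes), description))
    return signatures


def sample_enrichment_score(values: pd.Series, signature: GeneSignature) -> float:
    """Running-sum enrichment score of one signature in one sample.

    ``values`` maps gene id -> abundance for a single sample.  Returns NaN
    (missing-signature sentinel) when no signature gene is present.
    """
    if len(values) < 10:
        raise ParameterError("expression vector must contain >= 10 genes")
    genes = values.index.to_numpy(dtype=object)
    abundances = values.to_numpy(dtype=float)
    # decreasing abundance, ties broken lexicographically by gene id
    order = np.lexsort((genes, -abundances))
    member = np.isin(genes[order], list(signature.genes))
    n_in = int(member.sum())
    n_out = member.size - n_in
    if n_in == 0:
        return float("nan")
    if n_out == 0:
        return 1.0  # degenerate: every gene is in the set
    steps = np.where(member, 1.0 / n_in, -1.0 / n_out)
    walk = np.cumsum(steps)
    peak = int(np.argmax(np.abs(walk)))  # first maximal deviation
    return float(walk[peak])


def enrichment_matrix(
    expr: pd.DataFrame, signatures: list[GeneSignature]
) -> pd.DataFrame:
    """Signature x sample matrix of single-sample enrichment scores.

    Missing-signature sentinels (NaN) propagate per cell.
    """
    names = [sig.name for sig in signatures]
    out = pd.DataFrame(
        np.nan, index=pd.Index(names, name="signature"), columns=expr.columns
    )
    for sig in signatures:
        for sample in expr.columns:
            out.at[sig.name, sample] = sample_enrichment_score(expr[sample], sig)
    return out
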