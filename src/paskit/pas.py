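"""Pathway activation strength: CNR, BTIF and the PAS score.

The model scores each pathway *p* in each sample *s* as

    PAS(p, s) = sum_n ARR(n, p) * BTIF(n, s) * log10(CNR(n, s))

over the pathway's member genes *n*, where

* CNR (case-to-normal ratio) is the sample's expression of a gene divided
  by the mean expression of that gene over the reference ("normal") group,
* BTIF (beyond-tolerance-interval flag) is 1 only for genes whose
  perturbation is both large (CNR outside the [fold_low, fold_high] band,
  defaults 0.66 / 1.5, inclusive) and significant (two-sided Gaussian tail
  probability of the sample's log2 abundance under the reference
  distribution below ``alpha``), and
* ARR is the discrete activator/repressor role weight from the pathway
  database.

A positive PAS therefore means the pathway's activators are up and/or its
repressors are down relative to normal.  ``lg`` is the decimal logarithm;
a different base would only rescale every PAS by a constant.

Reference samples are scored leave-self-in: their CNR uses the whole
reference set (themselves included) as the denominator, which is how the
reference PAS distribution used by :mod:`paskit.stats` is built.

Numerical policy: a pseudocount (default 1.0 on the normalized scale) is
added symmetrically to case and reference so CNR is finite and positive
even for zero counts, and the reference log2 standard deviation is floored
at ``sd_floor`` (default 0.1 log2 units) so tiny reference groups and
zero-variance genes do not produce spurious flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .errors import DegenerateInputError, ParameterError
from .expression import reference_samples
from .pathway_db import PathwayCollection

__all__ = [
    "compute_cnr",
    "compute_btif",
    "compute_pas",
    "score_pathways",
    "PASResult",
    "write_pas",
    "read_pas",
]

logger = logging.getLogger(__name__)


def compute_cnr(
    matrix: pd.DataFrame, design: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Case-to-normal ratio per gene and sample.

    ``(matrix + pseudocount) / mean over reference samples of
    (matrix + pseudocount)``.  With ``pseudocount > 0`` every entry is
    finite and positive; a gene that is zero everywhere gets CNR exactly 1.
    """
    if pseudocount < 0:
        raise ParameterError("pseudocount must be >= 0")
    refs = reference_samples(design)
    shifted = matrix + pseudocount
    ref_mean = shifted[refs].mean(axis=1)
    zero_ref = ref_mean == 0
    if zero_ref.any():
        nonzero_rows = shifted.loc[zero_ref].to_numpy().any(axis=1)
        if nonzero_rows.any():
            raise DegenerateInputError(
                "reference mean is 0 for genes with nonzero case counts; "
                "use a positive pseudocount"
            )
        # all-zero gene with pseudocount 0: define CNR = 1 (no change)
        ref_mean = ref_mean.mask(zero_ref, 1.0)
        shifted = shifted.mask(
            pd.DataFrame(
                np.broadcast_to(zero_ref.to_numpy()[:, None], shifted.shape),
                index=shifted.index,
                columns=shifted.columns,
            ),
            1.0,
        )
    return shifted.div(ref_mean, axis=0)


def compute_btif(
    matrix: pd.DataFrame,
    cnr: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
    fold_low: float = 0.66,
    fold_high: float = 1.5,
    pseudocount: float = 1.0,
    sd_floor: float = 0.1,
) -> pd.DataFrame:
    """Beyond-tolerance-interval flag per gene and sample (0/1 integers).

    Flag = 1 iff CNR <= fold_low or CNR >= fold_high (inclusive), AND the
    two-sided Gaussian tail probability of log2(value + pseudocount) under
    the reference group's log2 mean/sd (sd floored at ``sd_floor``) is
    below ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if not 0 < fold_low < 1 <= fold_high:
        raise ParameterError(
            f"fold band must satisfy 0 < fold_low < 1 <= fold_high, "
            f"got ({fold_low}, {fold_high})"
        )
    refs = reference_samples(design)
    with np.errstate(divide="ignore"):
        log2v = np.log2(matrix.to_numpy(dtype=float) + pseudocount)
    log2df = pd.DataFrame(log2v, index=matrix.index, columns=matrix.columns)
    ref_mean = log2df[refs].mean(axis=1)
    ref_sd = log2df[refs].std(axis=1, ddof=1).clip(lower=sd_floor)
    z = log2df.sub(ref_mean, axis=0).div(ref_sd, axis=0)
    pvals = 2.0 * sps.norm.sf(np.abs(z.to_numpy()))
    fold_flag = (cnr <= fold_low) | (cnr >= fold_high)
    flag = fold_flag.to_numpy() & (pvals < alpha)
    return pd.DataFrame(
        flag.astype(np.int8), index=matrix.index, columns=matrix.columns
    )


def compute_pas(
    cnr: pd.DataFrame,
    btif: pd.DataFrame,
    db: PathwayCollection,
    size_normalize: bool = False,
) -> pd.DataFrame:
    """PAS score per pathway (rows, display names) and sample (columns).

    Pathway genes absent from the matrix are skipped (counted in a log
    message); a pathway with no gene present gets NaN — a missing-pathway
    sentinel, deliberately distinct from a true 0.  ``size_normalize``
    divides by the pathway's total gene count (off by default; the score as
    defined has no size normalization).
    """
    if cnr.shape != btif.shape:
        raise ParameterError("cnr and btif must share shape")
    signal = btif.to_numpy(dtype=float) * np.log10(cnr.to_numpy(dtype=float))
    index = cnr.index
    out = np.full((len(db), cnr.shape[1]), np.nan)
    n_skipped = 0
    for i, pw in enumerate(db):
        genes = [r.gene for r in pw.roles]
        pos = index.get_indexer(genes)
        present = pos >= 0
        n_skipped += int((~present).sum())
        if not present.any():
            continue
        arr = np.array([r.arr for r in pw.roles])[present]
        pas = arr @ signal[pos[present]]
        if size_normalize:
            pas = pas / len(pw.roles)
        out[i] = pas
    if n_skipped:
        logger.info(
            "compute_pas skipped %d pathway-gene memberships absent from the "
            "expression matrix",
            n_skipped,
        )
    return pd.DataFrame(out, index=pd.Index(db.names, name="pathway"),
                        columns=cnr.columns)


@dataclass
class PASResult:
    """PAS matrix together with the intermediates and parameters that made it."""

    pas: pd.DataFrame
    cnr: pd.DataFrame
    btif: pd.DataFrame
    params: dict = field(default_factory=dict)


def score_pathways(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    db: PathwayCollection,
    normalization: str = "cpm",
    pseudocount: float = 1.0,
    alpha: float = 0.05,
    fold_low: float = 0.66,
    fold_high: float = 1.5,
    sd_floor: float = 0.1,
    size_normalize: bool = False,
) -> PASResult:
    """Convenience pipeline: normalize -> CNR -> BTIF -> PAS."""
    from .expression import normalize  # local import avoids cycle at module load

    norm = normalize(matrix, normalization)
    cnr = compute_cnr(norm, design, pseudocount)
    btif = compute_btif(
        norm, cnr, design, alpha, fold_low, fold_high, pseudocount, sd_floor
    )
    pas = compute_pas(cnr, btif, db, size_normalize)
    params = {
        "reference_samples": reference_samples(design),
        "normalization": normalization,
        "pseudocount": pseudocount,
        "alpha": alpha,
        "fold_low": fold_low,
        "fold_high": fold_high,
        "sd_floor": sd_floor,
        "size_normalize": size_normalize,
    }
    return PASResult(pas=pas, cnr=cnr, btif=btif, params=params)


def write_pas(pas: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a PAS matrix as TSV (missing pathways as ``NA``) + YAML sidecar."""
    pas.to_csv(path, sep="\t", na_rep="NA", index_label="pathway")
    if params is not None:
        sidecar = str(path) + ".yaml" if not str(path).endswith(".tsv") else str(
            path
        )[: -len(".tsv")] + ".yaml"
        with open(sidecar, "w", encoding="utf-8") as handle:
            yaml.safe_dump(params, handle, sort_keys=True)


def read_pas(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="pathway", na_values=["NA"])
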