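"""Significance machinery for pathway activation scores.

Two layers, mirroring how the score is used:

* per-sample: each case sample's PAS is compared against the Gaussian fit
  (mean, sd) of the reference samples' PAS values for the same pathway —
  reference PAS values exist because reference samples are scored
  leave-self-in (see :mod:`paskit.pas`);
* per-group: a two-sided Wilcoxon rank-sum test between case and control
  PAS values, exact by enumeration for combined n <= 12 and a
  tie-corrected normal approximation above.

Selection ("significant ISPs") is group p < alpha; the stringent variant
additionally requires |group PAS| >= min_pas (default 0.1).  The absolute
value matters: repressed pathways carry negative PAS and survive the
stringency filter on magnitude.  P-values are reported raw by default; an
optional Benjamini-Hochberg switch is provided for reuse across hundreds
of pathways.
"""

from __future__ import annotations

import logging
import warnings
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, ParameterError

__all__ = [
    "gaussian_sample_pvalues",
    "wilcoxon_group_test",
    "ranksum_pvalues",
    "significance_table",
    "select_significant",
]

logger = logging.getLogger(__name__)

#: Largest combined group size for which the rank-sum null distribution is
#: enumerated exactly (C(12, 6) = 924 assignments at worst).
EXACT_LIMIT = 12


def gaussian_sample_pvalues(
    pas: pd.DataFrame, reference_samples: list[str], sd_floor: float = 0.1
) -> pd.DataFrame:
    """Two-sided Gaussian tail p-value of each sample's PAS per pathway.

    For each pathway, mean and sd (ddof=1, floored at ``sd_floor``) are
    fitted over the reference samples' PAS values; every column of ``pas``
    is then scored against that fit.  Invariant under any affine rescaling
    applied jointly to case and reference values (as long as the floor
    does not engage).
    """
    refs = [s for s in reference_samples if s in pas.columns]
    if len(refs) < 2:
        raise DesignError("need >= 2 reference samples with PAS values")
    mu = pas[refs].mean(axis=1)
    sd = pas[refs].std(axis=1, ddof=1).clip(lower=sd_floor)
    z = pas.sub(mu, axis=0).div(sd, axis=0)
    pvals = 2.0 * sps.norm.sf(np.abs(z.to_numpy()))
    return pd.DataFrame(pvals, index=pas.index, columns=pas.columns)


@lru_cache(maxsize=64)
def _combo_index(n_total: int, n_case: int) -> np.ndarray:
    return np.array(list(combinations(range(n_total), n_case)))


def wilcoxon_group_test(case, control) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two value groups.

    Exact by enumeration of all case/control rank assignments (mid-ranks,
    so ties are handled) when the combined size is <= 12; tie-corrected
    normal approximation otherwise.  All values tied across both groups
    degenerates to p = 1 with a warning.
    """
    x = np.asarray(case, dtype=float)
    y = np.asarray(control, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both groups must be non-empty")
    p = ranksum_pvalues(x[None, :], y[None, :])[0]
    return float(p)


def ranksum_pvalues(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Vectorized rank-sum test: one p-value per row of (case, control).

    ``case`` is (m, n1) and ``control`` (m, n2); rows with NaN yield NaN.
    Same method switch as :func:`wilcoxon_group_test`.
    """
    case = np.atleast_2d(np.asarray(case, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    n1, n2 = case.shape[1], control.shape[1]
    n_total = n1 + n2
    pooled = np.hstack([case, control])
    out = np.full(pooled.shape[0], np.nan)
    valid = ~np.isnan(pooled).any(axis=1)
    if not valid.any():
        return out
    ranks = sps.rankdata(pooled[valid], axis=1)
    w = ranks[:, :n1].sum(axis=1)
    expected = n1 * (n_total + 1) / 2.0
    dev = np.abs(w - expected)
    degenerate = np.ptp(pooled[valid], axis=1) == 0
    if degenerate.any():
        warnings.warn(
            "all values tied across both groups; rank-sum p set to 1",
            stacklevel=2,
        )
    if n_total <= EXACT_LIMIT:
        combos = _combo_index(n_total, n1)
        # all possible case rank-sums, per row: (rows, n_combos)
        ws = ranks[:, combos].sum(axis=2)
        pv = (np.abs(ws - expected) >= dev[:, None] - 1e-12).mean(axis=1)
    else:
        # tie correction: sum(t^3 - t) over tie groups, per row
        tie_term = np.empty(ranks.shape[0])
        for i, row in enumerate(pooled[valid]):
            _, counts = np.unique(row, return_counts=True)
            tie_term[i] = float((counts**3 - counts).sum())
        var = (
            n1 * n2 / 12.0
            * ((n_total + 1) - tie_term / (n_total * (n_total - 1)))
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (w - expected) / np.sqrt(var)
        pv = 2.0 * sps.norm.sf(np.abs(z))
        pv = np.where(var <= 0, 1.0, np.minimum(pv, 1.0))
    pv = np.where(degenerate, 1.0, pv)
    out[valid] = pv
    return out


def significance_table(
    pas: pd.DataFrame,
    case_samples: list[str],
    control_samples: list[str],
    alpha: float = 0.05,
    min_pas: float = 0.1,
    sd_floor: float = 0.1,
    multiple_testing: str | None = None,
) -> pd.DataFrame:
    """Per-pathway significance summary for one case-vs-control contrast.

    Columns: ``group_pas`` (mean PAS over case samples, signed),
    ``p_wilcoxon`` (two-sided group test against control PAS values,
    BH-adjusted if ``multiple_testing='bh'``), ``p_min_sample`` (smallest
    per-sample Gaussian p over the case samples, fitted on the control
    group), ``passes_alpha`` and ``passes_stringency``.
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    if min_pas < 0:
        raise ParameterError("min_pas must be >= 0")
    missing = [s for s in [*case_samples, *control_samples] if s not in pas.columns]
    if missing:
        raise DesignError(f"samples absent from PAS matrix: {missing[:5]}")
    group_pas = pas[case_samples].mean(axis=1)
    p_wilcoxon = pd.Series(
        ranksum_pvalues(
            pas[case_samples].to_numpy(), pas[control_samples].to_numpy()
        ),
        index=pas.index,
    )
    if multiple_testing == "bh":
        ok = p_wilcoxon.notna()
        adj = p_wilcoxon.copy()
        adj[ok] = sps.false_discovery_control(p_wilcoxon[ok], method="bh")
        p_wilcoxon = adj
    elif multiple_testing is not None:
        raise ParameterError(f"unknown multiple_testing {multiple_testing!r}")
    sample_p = gaussian_sample_pvalues(pas, control_samples, sd_floor)
    p_min_sample = sample_p[case_samples].min(axis=1)
    passes_alpha = p_wilcoxon < alpha
    passes_stringency = passes_alpha & (group_pas.abs() >= min_pas)
    return pd.DataFrame(
        {
            "group_pas": group_pas,
            "p_wilcoxon": p_wilcoxon,
            "p_min_sample": p_min_sample,
            "passes_alpha": passes_alpha,
            "passes_stringency": passes_stringency,
        }
    )


def select_significant(
    table: pd.DataFrame, alpha: float = 0.05, min_pas: float = 0.0
) -> list[str]:
    """Pathways with group p < alpha and |group PAS| >= min_pas.

    ``min_pas=0`` reproduces the plain significance sets; ``min_pas=0.1``
    the stringent ones.  Monotone: raising ``min_pas`` or lowering
    ``alpha`` never adds a pathway.  NaN rows (missing pathways) never
    select.
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    if min_pas < 0:
        raise ParameterError("min_pas must be >= 0")
    mask = (table["p_wilcoxon"] < alpha) & (table["group_pas"].abs() >= min_pas)
    return table.index[mask.fillna(False)].tolist()
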