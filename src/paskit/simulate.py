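"""Synthetic study generator: pathway databases, surgical-design count
matrices with planted pathway activations, and recovery scoring.

The generator emulates the statistical structure the analysis assumes: a
multi-procedure mouse liver time course (sham, transection, PVL, LLLx,
ALPPS and 68% hepatectomy by default) sampled at 0.5-12 h post-surgery
with n = 3 replicates per cell and a sham time-0 reference group, bulk
RNA-seq counts drawn from a negative binomial with moderate dispersion
(default 0.05, tight, pooled-sample-like), log-normal library sizes
(sd 0.2 in log space) to exercise normalization, and log-normal per-gene
baseline means spanning tens to thousands of reads.

A planted activation acts multiplicatively on means and respects the
activator/repressor role signs: in an "activated" pathway, activator
genes' means are multiplied by the fold and repressor genes' by its
inverse (vice versa for "repressed"), so planted "activated" pathways
have positive true PAS by construction — this defines the recovery
target unambiguously.  Identical seed + spec gives byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import ParameterError
from .pathway_db import ALLOWED_ARR, GeneRole, PathwayCollection, PathwayDef

__all__ = [
    "PROCEDURES",
    "TIMEPOINTS_H",
    "TruthEntry",
    "TruthSpec",
    "generate_pathway_db",
    "make_design",
    "simulate_counts",
    "recovery_auroc",
]

#: The study's surgical procedures (sham is also the reference procedure).
PROCEDURES = ("sham", "transection", "PVL", "LLLx", "ALPPS", "hx68")

#: Hours post-surgery at which tissue is sampled.
TIMEPOINTS_H = (0.5, 1.0, 4.0, 8.0, 12.0)


@dataclass(frozen=True)
class TruthEntry:
    """One planted effect: a pathway activated/repressed in one design cell."""

    procedure: str
    timepoint_h: float
    pathway: str  # pathway display name
    direction: str  # "activated" or "repressed"
    fold: float

    def __post_init__(self) -> None:
        if self.direction not in ("activated", "repressed"):
            raise ParameterError(f"direction {self.direction!r} invalid")
        if not self.fold > 1:
            raise ParameterError(f"fold must be > 1, got {self.fold}")


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth and noise model for one simulated dataset."""

    entries: tuple[TruthEntry, ...] = ()
    dispersion: float = 0.05
    baseline_log_mean: float = math.log(200.0)
    baseline_log_sd: float = 1.0
    library_size_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")

    def planted_pathways(self) -> set[str]:
        return {e.pathway for e in self.entries}


def generate_pathway_db(
    n_pathways: int = 378,
    size_range: tuple[int, int] = (10, 60),
    overlap_fraction: float = 0.1,
    seed: int = 0,
    activator_fraction: float = 0.6,
    zero_fraction: float = 0.05,
) -> PathwayCollection:
    """Random pathway collection with mixed roles and controlled overlap.

    Each pathway draws ``round(size * overlap_fraction)`` genes from the
    pool of genes already used by earlier pathways and the rest fresh, so
    ``overlap_fraction=0`` gives pairwise-disjoint pathways (Jaccard 0).
    Role weights are sampled so ~``activator_fraction`` of members are
    activators (split 3:1 between +1 and +0.5), a small ``zero_fraction``
    are neutral, and the remainder repressors (split 7:3 between -1 and
    -0.5).
    """
    if n_pathways < 1:
        raise ParameterError("n_pathways must be >= 1")
    lo, hi = size_range
    if not 1 <= lo <= hi:
        raise ParameterError(f"invalid size_range {size_range}")
    if not 0 <= overlap_fraction < 1:
        raise ParameterError("overlap_fraction must be in [0, 1)")
    if not 0 <= activator_fraction + zero_fraction <= 1:
        raise ParameterError("activator_fraction + zero_fraction must be <= 1")
    rng = np.random.default_rng(seed)
    rep_fraction = 1.0 - activator_fraction - zero_fraction
    arr_probs = np.array(
        [
            0.7 * rep_fraction,  # -1
            0.3 * rep_fraction,  # -0.5
            zero_fraction,  # 0
            0.25 * activator_fraction,  # +0.5
            0.75 * activator_fraction,  # +1
        ]
    )
    arr_values = np.array(sorted(ALLOWED_ARR))
    pool: list[str] = []
    next_gene = 0
    pathways = []
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        n_shared = min(round(size * overlap_fraction), len(pool))
        shared = (
            list(rng.choice(pool, size=n_shared, replace=False))
            if n_shared
            else []
        )
        fresh = [f"G{j:05d}" for j in range(next_gene, next_gene + size - n_shared)]
        next_gene += size - n_shared
        genes = shared + fresh
        arrs = rng.choice(arr_values, size=len(genes), p=arr_probs)
        roles = tuple(GeneRole(g, float(a)) for g, a in zip(genes, arrs))
        pathways.append(PathwayDef(f"Synthetic pathway {i + 1:03d}", "main", roles))
        pool.extend(fresh)
    return PathwayCollection(pathways)


def make_design(
    procedures: tuple[str, ...] = tuple(p for p in PROCEDURES if p != "sham"),
    timepoints: tuple[float, ...] = TIMEPOINTS_H,
    n_replicates: int = 3,
    reference_procedure: str = "sham",
    reference_timepoint: float = 0.0,
    n_reference: int = 3,
) -> pd.DataFrame:
    """Design grid: reference cell first, then procedure x timepoint x replicate."""
    if n_replicates < 1 or n_reference < 2:
        raise ParameterError("need n_replicates >= 1 and n_reference >= 2")
    rows = []
    for rep in range(1, n_reference + 1):
        rows.append(
            (
                f"{reference_procedure}_{reference_timepoint:g}h_r{rep}",
                reference_procedure,
                reference_timepoint,
                rep,
                1,
            )
        )
    for proc in procedures:
        for tp in timepoints:
            for rep in range(1, n_replicates + 1):
                rows.append((f"{proc}_{tp:g}h_r{rep}", proc, float(tp), rep, 0))
    design = pd.DataFrame(
        rows,
        columns=["sample_id", "procedure", "timepoint_h", "replicate", "is_reference"],
    ).set_index("sample_id")
    return design


def simulate_counts(
    db: PathwayCollection,
    truth: TruthSpec,
    design: pd.DataFrame,
    seed: int = 0,
    n_background_genes: int = 0,
) -> pd.DataFrame:
    """Negative-binomial count matrix for the given design and ground truth.

    Reference samples are never perturbed.  Genes are the pathway
    collection's universe (sorted) plus optional pathway-free background
    genes.  Returns genes x samples integer counts.
    """
    for entry in truth.entries:
        if entry.pathway not in db:
            raise ParameterError(f"planted pathway {entry.pathway!r} not in collection")
    rng = np.random.default_rng(seed)
    genes = sorted(db.universe) + [f"BG{j:05d}" for j in range(n_background_genes)]
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes, n_samples = len(genes), design.shape[0]
    baseline = rng.lognormal(truth.baseline_log_mean, truth.baseline_log_sd, n_genes)
    lib = rng.lognormal(0.0, truth.library_size_sd, n_samples)
    effect = np.ones((n_genes, n_samples))
    is_ref = design["is_reference"].astype(bool).to_numpy()
    for entry in truth.entries:
        cell = (
            (design["procedure"] == entry.procedure)
            & (design["timepoint_h"].astype(float) == float(entry.timepoint_h))
            & ~design["is_reference"].astype(bool)
        ).to_numpy()
        if not cell.any():
            raise ParameterError(
                f"no design samples in cell ({entry.procedure}, {entry.timepoint_h})"
            )
        sign = 1.0 if entry.direction == "activated" else -1.0
        for role in db[entry.pathway].roles:
            if role.arr == 0:
                continue
            gene_fold = entry.fold ** (sign * np.sign(role.arr))
            effect[gene_pos[role.gene], cell] *= gene_fold
    effect[:, is_ref] = 1.0  # reference samples stay unperturbed
    mu = baseline[:, None] * lib[None, :] * effect
    if truth.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / truth.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                        columns=design.index)


def recovery_auroc(group_pas: pd.Series, planted: set[str]) -> float:
    """AUROC for recovering planted pathways by ranking |group PAS|.

    Missing pathways (NaN) rank lowest.  Requires at least one planted and
    one unplanted pathway.
    """
    labels = np.array([name in planted for name in group_pas.index], dtype=int)
    if labels.all() or not labels.any():
        raise ParameterError("need both planted and unplanted pathways")
    scores = group_pas.abs().fillna(-1.0).to_numpy()
    return float(roc_auc_score(labels, scores))
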