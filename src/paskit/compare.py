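"""Cross-condition structure: Venn partitions, PAS ratios, time profiles,
hierarchical clustering, PCA and correlation matrices.

These operations consume pathway-by-sample (or pathway-by-group) PAS
matrices and the significant-pathway sets produced by :mod:`paskit.stats`,
and expose the set-algebra and ordination views used to contrast surgical
procedures: which pathways are exclusive to one procedure, how much
stronger a pathway responds under one procedure than another, and how
samples group in pathway-activation space.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from itertools import combinations as iter_combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateInputError, DesignError, ParameterError

__all__ = [
    "VennPartition",
    "venn_partition",
    "pas_ratio",
    "time_profiles",
    "ClusterResult",
    "hierarchical_cluster",
    "PCAResult",
    "pca_transform",
    "correlation_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class VennPartition:
    """Disjoint region decomposition of 2-4 named sets.

    ``regions`` maps a tuple of labels (the combination of input sets a
    member belongs to, in input-label order) to the members exclusive to
    exactly that combination.  Regions are pairwise disjoint and their
    union is the union of the inputs.
    """

    labels: tuple[str, ...]
    regions: dict[tuple[str, ...], frozenset]

    @property
    def counts(self) -> dict[tuple[str, ...], int]:
        return {combo: len(members) for combo, members in self.regions.items()}

    def exclusive(self, label: str) -> frozenset:
        """Members found only in ``label``'s set."""
        return self.regions[(label,)]

    def to_json(self) -> str:
        payload = {
            "sets": list(self.labels),
            "regions": {
                "∩".join(combo): sorted(members)
                for combo, members in self.regions.items()
            },
            "counts": {
                "∩".join(combo): len(members)
                for combo, members in self.regions.items()
            },
        }
        return json.dumps(payload, ensure_ascii=False, indent=2)


def venn_partition(sets: Mapping[str, Iterable] | list[tuple[str, Iterable]]) -> VennPartition:
    """Exact region memberships and counts for 2-4 named sets."""
    if isinstance(sets, Mapping):
        items = list(sets.items())
    else:
        items = [(label, members) for label, members in sets]
    labels = [label for label, _ in items]
    if len(set(labels)) != len(labels):
        raise ParameterError(f"duplicate set labels in {labels}")
    if not 2 <= len(labels) <= 4:
        raise ParameterError(f"need 2-4 sets, got {len(labels)}")
    as_sets = {label: frozenset(members) for label, members in items}
    regions: dict[tuple[str, ...], frozenset] = {}
    for r in range(1, len(labels) + 1):
        for combo in iter_combinations(labels, r):
            inside = frozenset.intersection(*(as_sets[l] for l in combo))
            outside = frozenset.union(
                frozenset(), *(as_sets[l] for l in labels if l not in combo)
            )
            regions[combo] = inside - outside
    return VennPartition(tuple(labels), regions)


def pas_ratio(table: pd.DataFrame, pathway: str, numerator: str, denominator: str) -> float:
    """Signed ratio of one pathway's PAS between two conditions.

    ``table`` is pathways x conditions; returns
    ``table.loc[pathway, numerator] / table.loc[pathway, denominator]``.
    A zero denominator yields NaN (undefined-ratio sentinel) with a
    warning rather than an exception, so tabulated ratios stay usable.
    """
    a = float(table.loc[pathway, numerator])
    b = float(table.loc[pathway, denominator])
    if b == 0:
        warnings.warn(f"zero denominator PAS for {pathway!r}", stacklevel=2)
        return float("nan")
    return a / b


def time_profiles(
    pas: pd.DataFrame, design: pd.DataFrame, include_reference: bool = False
) -> pd.DataFrame:
    """Group-mean PAS per pathway over the (procedure, timepoint) grid.

    Columns are a MultiIndex (procedure, timepoint_h) with timepoints
    strictly increasing within each procedure.
    """
    rows = design if include_reference else design[~design["is_reference"].astype(bool)]
    cells: dict[tuple[str, float], list[str]] = {}
    for sample, row in rows.iterrows():
        if sample not in pas.columns:
            raise DesignError(f"design sample {sample!r} absent from PAS matrix")
        cells.setdefault((row["procedure"], float(row["timepoint_h"])), []).append(sample)
    ordered = sorted(cells)  # procedure alphabetical, then timepoint ascending
    data = {cell: pas[cells[cell]].mean(axis=1) for cell in ordered}
    profile = pd.DataFrame(data)
    profile.columns = pd.MultiIndex.from_tuples(ordered, names=["procedure", "timepoint_h"])
    return profile


@dataclass
class ClusterResult:
    """Average-linkage merge tree over columns plus its leaf ordering."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix (merge tree)
    leaf_order: list[str]


def _pearson_distance(values: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns; constant columns get the
    maximal distance 2 against everything (0 against themselves)."""
    constant = values.std(axis=0) == 0
    if constant.any():
        logger.warning(
            "%d constant columns assigned maximal Pearson distance",
            int(constant.sum()),
        )
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 2.0
    np.fill_diagonal(dist, 0.0)
    # guard tiny negative round-off
    return np.clip(dist, 0.0, None)


def hierarchical_cluster(
    matrix: pd.DataFrame, metric: str = "pearson", method: str = "average"
) -> ClusterResult:
    """Agglomerative clustering of the matrix's columns.

    ``pearson`` distance is 1 - Pearson correlation; ``euclidean`` is the
    usual L2 metric.  Linkage defaults to average (UPGMA).  Rows with NaN
    are dropped first (missing pathways).
    """
    if matrix.shape[1] < 2:
        raise DegenerateInputError("clustering needs >= 2 columns")
    clean = matrix.dropna(axis=0)
    values = clean.to_numpy(dtype=float)
    if metric == "pearson":
        condensed = squareform(_pearson_distance(values), checks=False)
    elif metric == "euclidean":
        condensed = pdist(values.T, metric="euclidean")
    else:
        raise ParameterError(f"unknown metric {metric!r}")
    linkage = hierarchy.linkage(condensed, method=method)
    order = hierarchy.leaves_list(linkage)
    labels = list(matrix.columns)
    return ClusterResult(labels, linkage, [labels[i] for i in order])


@dataclass
class PCAResult:
    """Column-centered PCA of samples in pathway space."""

    coordinates: pd.DataFrame  # samples x components
    variance_explained: np.ndarray  # fractions, non-increasing
    components: pd.DataFrame  # components x features (loadings)
    mean: pd.Series


def pca_transform(matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of samples (columns of ``matrix``) in pathway/feature space.

    Features are the matrix rows; NaN rows are dropped.  Each component's
    loading vector is oriented so that its largest-magnitude entry is
    positive, making the output deterministic.
    """
    clean = matrix.dropna(axis=0)
    X = clean.to_numpy(dtype=float).T  # samples x features
    n_samples, n_features = X.shape
    if n_samples < 2:
        raise DegenerateInputError("PCA needs >= 2 samples")
    if not 1 <= n_components <= min(n_samples, n_features):
        raise ParameterError(
            f"n_components={n_components} outside [1, {min(n_samples, n_features)}]"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((s**2).sum())
    for k in range(n_components):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    coords = U[:, :n_components] * s[:n_components]
    frac = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    comp_labels = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=matrix.columns, columns=comp_labels),
        variance_explained=frac,
        components=pd.DataFrame(Vt[:n_components], index=comp_labels, columns=clean.index),
        mean=pd.Series(mean, index=clean.index),
    )


def correlation_matrix(
    matrix: pd.DataFrame,
    method: str = "pearson",
    cluster_order: bool = True,
) -> pd.DataFrame:
    """Column-by-column correlation matrix, optionally sorted by clustering.

    ``method`` is ``pearson`` (product-moment, default) or ``kendall``
    (rank tau).  Constant columns get correlation 0 against everything
    (diagonal stays 1) with a warning.  With ``cluster_order`` the rows
    and columns follow the average-linkage Pearson-distance leaf order.
    """
    if method not in ("pearson", "kendall"):
        raise ParameterError(f"unknown correlation method {method!r}")
    if matrix.shape[0] < 2:
        raise DegenerateInputError("correlation needs >= 2 observations per vector")
    clean = matrix.dropna(axis=0)
    corr = clean.corr(method=method)
    constant = clean.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant columns set to correlation 0",
            stacklevel=2,
        )
        corr.loc[constant, :] = 0.0
        corr.loc[:, constant] = 0.0
    values = corr.to_numpy(dtype=float, copy=True)
    np.fill_diagonal(values, 1.0)
    corr = pd.DataFrame(values, index=clean.columns, columns=clean.columns)
    if cluster_order and matrix.shape[1] >= 2:
        order = hierarchical_cluster(clean, metric="pearson").leaf_order
        corr = corr.loc[order, order]
    return corr
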