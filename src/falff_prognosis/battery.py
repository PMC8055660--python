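"""Multicollinearity structure of the behavioral assessment battery.

Aphasia batteries are strongly multicollinear: most measures probe
overlapping language ability. This module quantifies that structure the
way the prognostic analysis reports it: pairwise Kendall tau-b rank
correlations computed within each impairment group on pairwise-complete
observations (no imputation), averaged across groups to balance unequal
group sizes, then converted to a correlation distance (1 - tau, or
1 - |tau|) and clustered with UPGMA (average-linkage agglomerative
clustering). The signed distance follows the analysis text; the published
dendrogram caption describes the absolute variant, so both are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "AssociationMatrix",
    "Dendrogram",
    "kendall_tau_b",
    "groupwise_average_tau",
    "correlation_distance",
    "upgma",
]

MIN_COMPLETE_PAIRS = 3


def kendall_tau_b(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall tau-b of two measures over pairwise-complete observations.

    Rows where either value is missing are dropped; fewer than 3 complete
    pairs (or a variable left constant after dropping) yields NaN, which
    callers treat as "no valid correlation" and exclude from averaging.
    Tie correction follows the standard tau-b definition
    ``(C - D) / sqrt((n0 - n1)(n0 - n2))``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    if keep.sum() < MIN_COMPLETE_PAIRS:
        return float("nan")
    res = stats.kendalltau(x[keep], y[keep], variant="b")
    return float(res.statistic)


@dataclass
class AssociationMatrix:
    """Pairwise tau-b across measures, with effective pair counts."""

    measures: list[str]
    tau: np.ndarray  # (p, p), symmetric, unit diagonal, NaN where invalid
    n_effective: np.ndarray  # (p, p) pairwise-complete counts summed over groups

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tau, index=self.measures, columns=self.measures)


def _group_tau(table: pd.DataFrame, measures: list[str]) -> tuple[np.ndarray, np.ndarray]:
    p = len(measures)
    tau = np.full((p, p), np.nan)
    counts = np.zeros((p, p), dtype=int)
    cols = [table[m].to_numpy(float) for m in measures]
    for i in range(p):
        tau[i, i] = 1.0
        counts[i, i] = int(np.isfinite(cols[i]).sum())
        for j in range(i + 1, p):
            complete = int((~(np.isnan(cols[i]) | np.isnan(cols[j]))).sum())
            if complete >= MIN_COMPLETE_PAIRS:
                t = kendall_tau_b(cols[i], cols[j])
                tau[i, j] = tau[j, i] = t
                counts[i, j] = counts[j, i] = complete
    return tau, counts


def groupwise_average_tau(
    tables: dict[str, pd.DataFrame] | list[pd.DataFrame],
    measures: list[str] | None = None,
) -> AssociationMatrix:
    """Tau-b per impairment group, averaged cell-wise across groups.

    Each table is one group's subjects x measures frame (NaN = missing).
    Correlations are computed within groups first, then the unweighted mean
    over groups with a valid value is taken per cell — balancing groups of
    unequal size. A cell with no valid group stays NaN.
    """
    if isinstance(tables, dict):
        tables = list(tables.values())
    if not tables:
        raise ValueError("need at least one group table")
    if measures is None:
        measures = [c for c in tables[0].columns if c != "subject_id"]
    p = len(measures)
    stack = np.full((len(tables), p, p), np.nan)
    counts = np.zeros((p, p), dtype=int)
    for g, table in enumerate(tables):
        tau_g, n_g = _group_tau(table, measures)
        stack[g] = tau_g
        counts += n_g
    with np.errstate(invalid="ignore"):
        mean_tau = np.nanmean(stack, axis=0)
    return AssociationMatrix(measures=list(measures), tau=mean_tau, n_effective=counts)


def correlation_distance(matrix: AssociationMatrix, absolute: bool = False) -> np.ndarray:
    """Distance between measures: ``1 - tau`` (default) or ``1 - |tau|``.

    Missing cells are an error; complete the matrix (e.g. pool groups or
    drop sparse measures) before clustering.
    """
    tau = matrix.tau
    if np.isnan(tau).any():
        bad = [
            (matrix.measures[i], matrix.measures[j])
            for i, j in zip(*np.where(np.isnan(tau)))
            if i < j
        ]
        raise ValueError(
            f"tau matrix has {len(bad)} incomplete cell(s), e.g. {bad[:3]}; "
            "drop or pool measures with too few complete pairs before clustering"
        )
    dist = 1.0 - (np.abs(tau) if absolute else tau)
    np.fill_diagonal(dist, 0.0)
    return (dist + dist.T) / 2


@dataclass
class Dendrogram:
    """UPGMA merge tree over measures.

    ``merges`` lists p-1 pairs of cluster ids (ids < p are leaves, p + i is
    the cluster created by merge i), ``heights`` the nondecreasing merge
    distances.
    """

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    merges: list[tuple[int, int]]
    heights: np.ndarray
    leaf_order: list[int]

    def cophenetic(self) -> np.ndarray:
        """Square matrix of cophenetic distances (merge height joining two leaves)."""
        return squareform(hierarchy.cophenet(self.linkage))

    def to_newick(self) -> str:
        """Newick serialization with merge heights as node depths."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree)


def upgma(distances: np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) hierarchical clustering of a distance matrix.

    Repeatedly merges the closest pair of clusters, with inter-cluster
    distance the size-weighted mean of member pairwise distances. Merge
    heights are nondecreasing. Input must be square, symmetric,
    nonnegative, zero-diagonal.
    """
    D = np.asarray(distances, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distances must be nonnegative")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    p = D.shape[0]
    if labels is None:
        labels = [f"m{i}" for i in range(p)]
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    merges = [(int(a), int(b)) for a, b in Z[:, :2]]
    return Dendrogram(
        labels=list(labels),
        linkage=Z,
        merges=merges,
        heights=Z[:, 2].copy(),
        leaf_order=[int(i) for i in hierarchy.leaves_list(Z)],
    )
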