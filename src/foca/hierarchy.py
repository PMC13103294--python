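"""Hierarchical organization of the FOCA matrix.

Networks are clustered on their FOCA coupling profiles with average linkage
and a correlation distance (1 minus Pearson's r).  Flat cuts give clusters and
hyper-clusters; summaries average the intra- and inter-cluster couplings.  A
reference solution (e.g. adult-derived) can be projected onto another cohort's
matrix for direct developmental comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .topography import FocaMatrix, matrix_similarity

__all__ = [
    "ClusterSolution",
    "profile_distance_matrix",
    "cluster_foca",
    "cluster_summary",
    "project_reference_clusters",
]


@dataclass(frozen=True)
class ClusterSolution:
    """An agglomerative clustering of networks with two flat cuts."""

    merge_tree: np.ndarray  # scipy linkage matrix, (K-1, 4)
    flat_labels: np.ndarray  # network -> cluster id (1-based)
    n_clusters: int
    hyper_labels: np.ndarray | None = None  # network -> hyper-cluster id
    cluster_to_hyper: dict[int, int] = field(default_factory=dict)
    foca_values: np.ndarray | None = None  # matrix the solution was fit on

    def __post_init__(self) -> None:
        heights = self.merge_tree[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("merge heights must be non-decreasing")
        if len(np.unique(self.flat_labels)) != self.n_clusters:
            raise ValueError("flat labels must form exactly n_clusters groups")


def _masked_profile_corr(values: np.ndarray, i: int, j: int) -> float:
    """Correlation of rows i and j over entries excluding both self-terms."""
    k = values.shape[0]
    keep = np.ones(k, dtype=bool)
    keep[[i, j]] = False
    a, b = values[i, keep], values[j, keep]
    if a.std() < 1e-12 or b.std() < 1e-12:
        raise ValueError(f"constant coupling profile for network {i + 1} or {j + 1}")
    return float(np.corrcoef(a, b)[0, 1])


def profile_distance_matrix(foca: FocaMatrix) -> np.ndarray:
    """1 - r distances between network coupling profiles (diagonal masked)."""
    k = foca.k
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = 1.0 - _masked_profile_corr(foca.values, i, j)
    return d


def cluster_foca(
    group_foca: FocaMatrix, n_clusters: int = 6, n_hyper: int = 3
) -> ClusterSolution:
    """Average-linkage clustering of FOCA coupling profiles.

    Features are the networks' FOCA rows with self-entries masked; the
    distance is 1 minus their Pearson correlation.  Cuts at ``n_clusters``
    and ``n_hyper`` give nested flat labellings.
    """
    k = group_foca.k
    if not (2 <= n_hyper <= n_clusters <= k):
        raise ValueError("need 2 <= n_hyper <= n_clusters <= K")
    d = profile_distance_matrix(group_foca)
    iu = np.triu_indices(k, 1)
    tree = linkage(d[iu], method="average")
    flat = fcluster(tree, t=n_clusters, criterion="maxclust")
    hyper = fcluster(tree, t=n_hyper, criterion="maxclust")
    c2h = {}
    for c in np.unique(flat):
        hs = np.unique(hyper[flat == c])
        c2h[int(c)] = int(hs[0])
    return ClusterSolution(
        merge_tree=tree,
        flat_labels=flat,
        n_clusters=int(len(np.unique(flat))),
        hyper_labels=hyper,
        cluster_to_hyper=c2h,
        foca_values=group_foca.values.copy(),
    )


def cluster_summary(foca: FocaMatrix, solution: ClusterSolution) -> dict:
    """Average intra- and inter-cluster couplings (strict upper triangle).

    Intra means for singleton clusters are reported as NaN.
    """
    labels = solution.flat_labels
    if len(labels) != foca.k:
        raise ValueError("cluster labelling does not match matrix size")
    vals = foca.values
    clusters = np.unique(labels)
    intra: dict[int, float] = {}
    for c in clusters:
        idx = np.where(labels == c)[0]
        if len(idx) < 2:
            intra[int(c)] = float("nan")
            continue
        block = vals[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), 1)
        intra[int(c)] = float(block[iu].mean())
    inter: dict[tuple[int, int], float] = {}
    for a_i, a in enumerate(clusters):
        for b in clusters[a_i + 1 :]:
            ia = np.where(labels == a)[0]
            ib = np.where(labels == b)[0]
            inter[(int(a), int(b))] = float(vals[np.ix_(ia, ib)].mean())
    return {"intra": intra, "inter": inter}


def project_reference_clusters(
    foca_other: FocaMatrix, reference_solution: ClusterSolution
) -> dict:
    """Summarize a new matrix under a reference clustering.

    Applies the reference flat labels directly (same K and network ordering
    required) and reports the upper-triangle correlation between the two
    matrices alongside the summary.
    """
    if len(reference_solution.flat_labels) != foca_other.k:
        raise ValueError("network ordering/size mismatch with reference solution")
    summary = cluster_summary(foca_other, reference_solution)
    sim = None
    if reference_solution.foca_values is not None:
        sim = matrix_similarity(foca_other.values, reference_solution.foca_values)
    return {**summary, "similarity_to_reference": sim}
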