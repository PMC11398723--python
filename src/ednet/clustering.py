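"""Limbic subnetwork clustering: eta-squared profile similarity + Ward.

Each limbic parcel is characterised by its whole-brain connectivity profile
(its row of the subject RSFC matrix).  Profile similarity between two
parcels uses the eta-squared statistic standard in connectivity-based
parcellation: with ``m_p`` the pairwise mean at position p and ``M`` the
grand mean over both profiles,

    eta^2 = 1 - sum_p [(a_p - m_p)^2 + (b_p - m_p)^2]
                / sum_p [(a_p - M)^2 + (b_p - M)^2]

which lies in [0, 1] (the pairwise mean minimises each numerator term) and
equals 1 iff the profiles are identical.  Per-subject similarity matrices
are averaged and the group matrix is clustered with Ward's agglomerative
algorithm — the feature vector of a parcel being its row of the similarity
matrix — which at each step merges the pair of clusters minimising the
increase in error sum of squares (ESS; squared deviations from cluster
centroids).  No automatic cluster-count selection is applied: the cut level
k is explicit, with merge-height gaps reported to support choosing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .connectivity import RSFCMatrix


@dataclass
class SimilarityMatrix:
    """L x L eta-squared similarity over the limbic parcel subset."""

    eta2: np.ndarray
    parcel_ids: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.eta2 = np.asarray(self.eta2, dtype=float)
        n = self.eta2.shape[0]
        if self.eta2.shape != (n, n) or np.asarray(self.parcel_ids).size != n:
            raise ValueError("eta2 must be square and match parcel_ids")
        if np.any(self.eta2 < -1e-9) or np.any(self.eta2 > 1 + 1e-9):
            raise ValueError("eta-squared values must lie in [0, 1]")
        if not np.allclose(self.eta2, self.eta2.T):
            raise ValueError("similarity matrix must be symmetric")


@dataclass
class ClusterSolution:
    """Ward merge tree over the similarity rows.

    ``merges`` lists (cluster_a, cluster_b, height) with height the ESS
    increase of the merge (nondecreasing); ``linkage_matrix`` is the
    underlying scipy encoding used for cuts.
    """

    merges: list[tuple[int, int, float]]
    linkage_matrix: np.ndarray
    parcel_ids: np.ndarray
    chosen_k: Optional[int] = None
    labels_at_k: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_items(self) -> int:
        return len(self.parcel_ids)


def eta_squared(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Eta-squared similarity of two profiles (see module docstring)."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("profiles must be equal-length 1-D, length >= 2")
    grand = (a.mean() + b.mean()) / 2.0
    denom = np.sum((a - grand) ** 2 + (b - grand) ** 2)
    if denom == 0:
        raise ValueError("both profiles constant: eta-squared undefined")
    pair_mean = (a + b) / 2.0
    num = np.sum((a - pair_mean) ** 2 + (b - pair_mean) ** 2)
    return float(1.0 - num / denom)


def similarity_matrix(rsfc: RSFCMatrix, limbic_parcels: Sequence) -> SimilarityMatrix:
    """Pairwise eta-squared over the limbic rows of a subject matrix.

    Profiles are the full-brain rows (self-similarity columns retained).
    """
    limbic_parcels = np.asarray(limbic_parcels)
    if limbic_parcels.size == 0:
        raise ValueError("limbic parcel subset is empty")
    rows = np.stack([rsfc.row(pid) for pid in limbic_parcels])
    n = limbic_parcels.size
    eta = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            eta[i, j] = eta[j, i] = eta_squared(rows[i], rows[j])
    return SimilarityMatrix(eta2=eta, parcel_ids=limbic_parcels,
                            subject_id=rsfc.subject_id)


def group_similarity(matrices: Sequence[RSFCMatrix],
                     limbic_parcels: Sequence) -> SimilarityMatrix:
    """Average per-subject similarity matrices into the group matrix."""
    sims = [similarity_matrix(m, limbic_parcels) for m in matrices]
    if not sims:
        raise ValueError("no subject matrices given")
    return SimilarityMatrix(
        eta2=np.mean([s.eta2 for s in sims], axis=0),
        parcel_ids=np.asarray(limbic_parcels), subject_id="group")


def ward_cluster(sim: SimilarityMatrix) -> ClusterSolution:
    """Ward agglomeration of the similarity rows.

    Rows of the similarity matrix are the feature vectors.  Merge heights
    are reported as ESS increases (scipy's Ward distances squared, halved)
    and are nondecreasing.
    """
    x = sim.eta2
    if np.any(~np.isfinite(x)):
        raise ValueError("NaN in similarity matrix")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 parcels to cluster")
    lk = linkage(x, method="ward")
    merges = [(int(a), int(b), float(d) ** 2 / 2.0) for a, b, d, _ in lk]
    return ClusterSolution(merges=merges, linkage_matrix=lk,
                           parcel_ids=np.asarray(sim.parcel_ids))


def cut_dendrogram(solution: ClusterSolution, k: int) -> np.ndarray:
    """Labels (1..k, by first occurrence) from the merge tree at k clusters."""
    n = solution.n_items
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    if k == n:
        labels = np.arange(1, n + 1)
    else:
        raw = fcluster(solution.linkage_matrix, t=k, criterion="maxclust")
        labels = _first_occurrence_relabel(raw)
    solution.labels_at_k[k] = labels
    solution.chosen_k = k
    return labels


def _first_occurrence_relabel(raw: np.ndarray) -> np.ndarray:
    seen: dict = {}
    out = np.empty(raw.size, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in seen:
            seen[lab] = len(seen) + 1
        out[i] = seen[lab]
    return out


def height_gaps(solution: ClusterSolution) -> dict[int, float]:
    """Merge-height gap supporting each cluster count k.

    gap(k) = height of the merge that destroys the k-cluster solution minus
    the height of the merge that created it; a large gap marks a persistent
    k.  Defined for 2 <= k <= n-1.
    """
    heights = [h for _, _, h in solution.merges]
    n = solution.n_items
    gaps = {}
    for k in range(2, n):
        gaps[k] = heights[n - k] - heights[n - k - 1]
    return gaps


def cluster_mean_maps(matrices: Sequence[RSFCMatrix], labels: np.ndarray,
                      limbic_parcels: Sequence) -> np.ndarray:
    """Per-subject mean whole-brain profile of each cluster.

    Returns (n_subjects, n_clusters, n_parcels): for each subject, the mean
    z row over the cluster's member parcels.  Order of members is
    irrelevant; empty clusters are an error.
    """
    labels = np.asarray(labels)
    limbic_parcels = np.asarray(limbic_parcels)
    if labels.size != limbic_parcels.size:
        raise ValueError("labels must cover the limbic subset")
    clusters = np.unique(labels)
    out = np.empty((len(matrices), clusters.size, matrices[0].n_parcels))
    for s, mat in enumerate(matrices):
        rows = np.stack([mat.row(pid) for pid in limbic_parcels])
        for ci, c in enumerate(clusters):
            members = labels == c
            if not members.any():
                raise ValueError(f"cluster {c} is empty")
            out[s, ci] = rows[members].mean(axis=0)
    return out
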