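"""Hierarchical clustering of genomes on binary functional profiles.

Before clustering, uninformative features are removed: a feature present in
a single genome or in every genome says nothing about how genomes differ, so
the default filter keeps features carried by between 2 and n-1 genomes.

Distances are computed on 0/1 rows — ``euclidean_binary`` (the square root
of the symmetric-difference size, the default of the generic heatmap routine
this reproduces) or ``jaccard`` — and agglomerated with complete or average
linkage via scipy. Genomes are sorted by id before the merge tree is built,
so the result is invariant to input row order even when merge heights tie.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform

from .annotation import PresenceMatrix

__all__ = [
    "ClusteringResult",
    "cluster_profiles",
    "filter_informative",
    "partition_agreement",
]

DISTANCES = ("euclidean_binary", "jaccard")
LINKAGES = ("complete", "average")


def filter_informative(
    matrix: PresenceMatrix,
    min_genomes: int = 2,
    max_genomes: int | None = None,
) -> PresenceMatrix:
    """Retain features carried by between ``min_genomes`` and ``max_genomes``.

    ``max_genomes`` defaults to n-1 (drop the universally shared features
    along with the singletons). Removing every column is an error naming the
    bounds. Idempotent.
    """
    n = matrix.frame.shape[0]
    if max_genomes is None:
        max_genomes = n - 1
    if not 1 <= min_genomes <= max_genomes <= n:
        raise ValueError(
            f"require 1 <= min_genomes <= max_genomes <= {n}, got [{min_genomes}, {max_genomes}]"
        )
    counts = matrix.column_counts()
    keep = counts.index[(counts >= min_genomes) & (counts <= max_genomes)]
    if len(keep) == 0:
        raise ValueError(
            f"informative filter [{min_genomes}, {max_genomes}] removed every feature"
        )
    return PresenceMatrix(matrix.frame[list(keep)])


@dataclass(frozen=True)
class ClusteringResult:
    """Merge tree over genomes plus helpers to cut it.

    ``genome_ids`` is the leaf labelling of ``merges`` (scipy linkage
    encoding: row i merges clusters Z[i,0] and Z[i,1] at height Z[i,2]).
    """

    genome_ids: tuple[str, ...]
    merges: np.ndarray
    distance: str
    linkage_method: str

    def cut(self, k: int) -> dict[str, int]:
        """Assign genomes to ``k`` flat clusters (ids 1..k)."""
        if not 1 <= k <= len(self.genome_ids):
            raise ValueError(f"k must be in [1, {len(self.genome_ids)}], got {k}")
        labels = fcluster(self.merges, t=k, criterion="maxclust")
        return dict(zip(self.genome_ids, (int(c) for c in labels)))

    def to_newick(self) -> str:
        """Serialize the merge tree as Newick with heights as node depths.

        Branch lengths are parent height minus child height (leaves sit at
        height 0), so root-to-leaf path lengths equal merge heights.
        """
        n = len(self.genome_ids)

        def node(i: int) -> tuple[str, float]:
            if i < n:
                # escape Newick-reserved characters in genome ids
                safe = self.genome_ids[i].replace(" ", "_").replace("(", "").replace(")", "").replace(",", "")
                return safe, 0.0
            a, b, h = int(self.merges[i - n, 0]), int(self.merges[i - n, 1]), float(self.merges[i - n, 2])
            sa, ha = node(a)
            sb, hb = node(b)
            return f"({sa}:{h - ha:g},{sb}:{h - hb:g})", h

        return node(2 * n - 2)[0] + ";"


def _pairwise(matrix: PresenceMatrix, distance: str) -> np.ndarray:
    data = matrix.frame.to_numpy(dtype=float)
    if distance == "euclidean_binary":
        return pdist(data, metric="euclidean")
    # scipy's jaccard defines the distance between two all-zero profiles as 0
    return pdist(data.astype(bool), metric="jaccard")


def cluster_profiles(
    matrix: PresenceMatrix,
    distance: str = "euclidean_binary",
    linkage_method: str = "complete",
) -> ClusteringResult:
    """Agglomerate genomes on their binary feature profiles.

    Rows are sorted by genome id before distances are computed, making the
    merge tree a function of the profile set alone (column order never
    matters; row order only relabels leaves).
    """
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}, got {distance!r}")
    if linkage_method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage_method!r}")
    if matrix.frame.shape[0] < 2:
        raise ValueError("clustering needs at least two genomes")
    if matrix.frame.shape[1] < 1:
        raise ValueError("clustering needs at least one feature")
    ordered = PresenceMatrix(matrix.frame.sort_index())
    condensed = _pairwise(ordered, distance)
    merges = linkage(condensed, method=linkage_method)
    return ClusteringResult(
        genome_ids=tuple(ordered.genome_ids),
        merges=merges,
        distance=distance,
        linkage_method=linkage_method,
    )


def pairwise_distance_matrix(matrix: PresenceMatrix, distance: str = "euclidean_binary") -> np.ndarray:
    """Square symmetric distance matrix in the matrix's own genome order."""
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}, got {distance!r}")
    return squareform(_pairwise(matrix, distance))


def partition_agreement(assignments: dict[str, int], labels: dict[str, int | str]) -> float:
    """Best-match overlap between two labelings of the same genomes, in [0, 1].

    Cluster ids are matched to label values by maximum-weight bipartite
    matching on the contingency table (for two balanced clusters this is the
    better of the two possible matchings); the score is the matched fraction.
    """
    if set(assignments) != set(labels):
        raise ValueError("partition_agreement requires identical genome sets")
    if not assignments:
        raise ValueError("empty partitions")
    a_ids = sorted(set(assignments.values()))
    b_ids = sorted(set(labels.values()), key=str)
    table = np.zeros((len(a_ids), len(b_ids)), dtype=int)
    a_index = {c: i for i, c in enumerate(a_ids)}
    b_index = {c: i for i, c in enumerate(b_ids)}
    for genome, cluster in assignments.items():
        table[a_index[cluster], b_index[labels[genome]]] += 1
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum()) / len(assignments)
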