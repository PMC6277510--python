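"""Phyletic-pattern clustering of informational-gene repertoires.

Genomes are compared by the Pearson correlation distance between their
binary presence/absence profiles over informational COGs (or any other
feature set) and grouped by agglomerative hierarchical clustering.  A
four-way cut of the dendrogram checks whether the archaea / bacteria /
eukaryota / megavirales groups come out as the four main branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .matrix import MatrixError, PresenceAbsenceMatrix

LINKAGES = ("average", "complete", "single")


@dataclass
class Dendrogram:
    """Agglomerative clustering result over a fixed taxon set.

    ``merges`` is the scipy linkage matrix: row i merges clusters
    ``merges[i, 0]`` and ``merges[i, 1]`` at height ``merges[i, 2]``
    (clusters >= n are earlier merges).  ``leaf_order`` is the dendrogram
    leaf ordering.
    """

    taxa: list[str]
    merges: np.ndarray
    linkage: str

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.merges)
        return [self.taxa[i] for i in order]

    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Assign each taxon a cluster id (1..n_clusters) at the given cut."""
        labels = hierarchy.fcluster(self.merges, t=n_clusters, criterion="maxclust")
        return {t: int(c) for t, c in zip(self.taxa, labels)}

    def newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.merges)

        def fmt(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                name = self.taxa[node.id].replace(" ", "_")
                return f"{name}:{length:.6f}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6f}"

        return fmt(tree, tree.dist) + ";"


def pearson_distance(m: PresenceAbsenceMatrix) -> np.ndarray:
    """Pearson correlation distance between taxon profiles: d = 1 - r.

    Profiles are the raw binary rows, centered as usual by the Pearson
    formula, so d lies in [0, 2]: 0 for identical profiles, 2 for perfectly
    complementary ones.

    Raises
    ------
    MatrixError
        If any taxon has a constant profile (correlation undefined),
        naming the offending taxa.
    """
    x = m.data.astype(float)
    std = x.std(axis=1)
    constant = [t for t, s in zip(m.taxa, std) if s == 0.0]
    if constant:
        raise MatrixError(
            f"constant presence/absence profile (correlation undefined) "
            f"for taxa: {constant[:10]}"
        )
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    # symmetrize and clamp away float round-off
    d = 0.5 * (d + d.T)
    return d.clip(min=0.0)


def hierarchical_cluster(
    distances: np.ndarray, taxa: list[str], linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of a precomputed distance matrix.

    Scipy's deterministic agglomeration order is used; for the monotone
    linkages offered here merge heights are non-decreasing.

    Raises
    ------
    MatrixError
        For a non-square matrix or unknown linkage.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise MatrixError(f"distance matrix must be square, got {d.shape}")
    if linkage not in LINKAGES:
        raise MatrixError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if len(taxa) != d.shape[0]:
        raise MatrixError("taxa length must match distance matrix")
    condensed = squareform(d, checks=True)
    merges = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(list(taxa), merges, linkage)


def cluster_phyletic(
    m: PresenceAbsenceMatrix, linkage: str = "average"
) -> Dendrogram:
    """Pearson-distance hierarchical clustering of a phyletic matrix."""
    return hierarchical_cluster(pearson_distance(m), m.taxa, linkage)


@dataclass
class FourBranchReport:
    """Group composition of the dendrogram cut into four clusters."""

    cluster_majority: dict[int, str]
    cluster_sizes: dict[int, int]
    purity: float
    assignments: dict[str, int]


def four_branch_check(
    dendrogram: Dendrogram, group_labels: dict[str, str]
) -> FourBranchReport:
    """Cut the dendrogram into 4 clusters and score group purity.

    Purity is the fraction of taxa belonging to their cluster's majority
    group; 1.0 means the four clusters coincide exactly with the four
    microbial groups (majority ties broken by lexicographic group name).
    """
    assignments = dendrogram.cut(4)
    clusters: dict[int, list[str]] = {}
    for taxon, c in assignments.items():
        clusters.setdefault(c, []).append(taxon)
    majority: dict[int, str] = {}
    sizes: dict[int, int] = {}
    correct = 0
    for c, members in sorted(clusters.items()):
        counts: dict[str, int] = {}
        for t in members:
            counts[group_labels[t]] = counts.get(group_labels[t], 0) + 1
        top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        majority[c] = top[0]
        sizes[c] = len(members)
        correct += top[1]
    return FourBranchReport(
        cluster_majority=majority,
        cluster_sizes=sizes,
        purity=correct / len(assignments),
        assignments=assignments,
    )
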