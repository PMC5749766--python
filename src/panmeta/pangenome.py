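"""Pangenome partitioning, Jaccard similarity and bi-clustering.

Clusters are classified by strain occupancy: *core* when every strain is
present, *strain-specific* when exactly one strain is present (paralogs from
a single strain count once — presence/absence semantics), *dispensable*
otherwise.  Strain-vs-strain similarity on dispensable clusters uses the
Jaccard index; the resulting matrix is bi-clustered with average linkage on
Euclidean distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import pdist

from panmeta.clustering import ClusterSet
from panmeta.seqio import ProfileMatrix

logger = logging.getLogger(__name__)

CORE = "core"
DISPENSABLE = "dispensable"
STRAIN_SPECIFIC = "strain_specific"

__all__ = [
    "PangenomePartition",
    "classify_clusters",
    "jaccard_matrix",
    "biclust_order",
    "BiclustResult",
]


@dataclass
class PangenomePartition:
    """Cluster classes plus the strain x cluster presence/absence matrix."""

    classes: dict[int, str]          # cluster index -> class label
    presence: ProfileMatrix          # strains x clusters, 0/1
    strain_list: list[str]

    def class_counts(self) -> dict[str, int]:
        counts = {CORE: 0, DISPENSABLE: 0, STRAIN_SPECIFIC: 0}
        for label in self.classes.values():
            counts[label] += 1
        return counts

    def clusters_of_class(self, label: str) -> list[int]:
        return [idx for idx, cls in self.classes.items() if cls == label]

    def dispensable_sets(self) -> dict[str, set[int]]:
        """strain -> set of dispensable cluster indices containing it."""
        disp = set(self.clusters_of_class(DISPENSABLE))
        out: dict[str, set[int]] = {}
        for i, strain in enumerate(self.presence.row_labels):
            present = np.nonzero(self.presence.values[i] > 0)[0]
            out[strain] = {int(c) for c in present if int(c) in disp}
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("cluster_id\tclass\toccupancy\n")
            for idx in sorted(self.classes):
                bits = "".join(
                    str(int(v)) for v in self.presence.values[:, idx]
                )
                fh.write(f"{idx}\t{self.classes[idx]}\t{bits}\n")


def classify_clusters(
    cluster_set: ClusterSet,
    gene_source_map: dict[str, str],
    strain_list: list[str],
) -> PangenomePartition:
    """Assign each cluster to {core, dispensable, strain_specific}.

    ``gene_source_map`` maps every gene id to its strain; a gene with an
    unknown source raises.  With a single strain every cluster is both
    "all strains" and "one strain"; the documented precedence resolves it
    as core, with a warning.
    """
    strain_index = {s: i for i, s in enumerate(strain_list)}
    n_strains = len(strain_list)
    if n_strains == 0:
        raise ValueError("strain_list must be nonempty")
    if n_strains == 1:
        logger.warning(
            "classify_clusters: single strain — every cluster classified as "
            "core by documented precedence"
        )

    presence = np.zeros((n_strains, len(cluster_set)), dtype=float)
    for idx, cluster in enumerate(cluster_set.clusters):
        for member in cluster.members:
            source = gene_source_map.get(member.gene_id)
            if source is None:
                raise ValueError(
                    f"gene {member.gene_id!r} has no source strain"
                )
            if source not in strain_index:
                raise ValueError(
                    f"gene {member.gene_id!r} has unknown source {source!r}"
                )
            presence[strain_index[source], idx] = 1.0

    classes: dict[int, str] = {}
    occupancy = presence.sum(axis=0)
    for idx in range(len(cluster_set)):
        occ = int(occupancy[idx])
        if occ == n_strains:
            classes[idx] = CORE
        elif occ == 1:
            classes[idx] = STRAIN_SPECIFIC
        else:
            classes[idx] = DISPENSABLE

    matrix = ProfileMatrix(
        row_labels=strain_list,
        col_labels=[str(i) for i in range(len(cluster_set))],
        values=presence,
    )
    return PangenomePartition(classes=classes, presence=matrix, strain_list=list(strain_list))


def jaccard_matrix(partition: PangenomePartition) -> ProfileMatrix:
    """Strain x strain Jaccard similarity on dispensable-cluster membership.

    ``J(s, t) = |D_s ∩ D_t| / |D_s ∪ D_t|`` with ``D_x`` the set of
    dispensable clusters containing strain ``x``.  The 0/0 case is defined
    as 1 on the diagonal and 0 off-diagonal (logged).
    """
    strains = partition.strain_list
    if len(strains) < 2:
        raise ValueError("jaccard_matrix requires at least 2 strains")
    disp = partition.dispensable_sets()
    for strain, ds in disp.items():
        if not ds:
            logger.warning(
                "jaccard_matrix: strain %s has no dispensable clusters "
                "(0/0 treated as 1 on the diagonal, 0 off-diagonal)",
                strain,
            )
    n = len(strains)
    values = np.zeros((n, n))
    for i, s in enumerate(strains):
        for j, t in enumerate(strains):
            if j < i:
                continue
            union = disp[s] | disp[t]
            if not union:
                val = 1.0 if i == j else 0.0
            else:
                val = len(disp[s] & disp[t]) / len(union)
            values[i, j] = values[j, i] = val
    return ProfileMatrix(strains, strains, values)


@dataclass
class BiclustResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]
    row_newick: str
    col_newick: str


def _linkage_to_newick(merge: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string.

    Branch lengths are differences of merge heights (leaves sit at height
    zero).
    """
    root = to_tree(merge)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.12g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.12g}"

    left = render(root.left, root.dist)
    right = render(root.right, root.dist)
    return f"({left},{right});"


def biclust_order(matrix: ProfileMatrix) -> BiclustResult:
    """Bi-cluster a labeled matrix: average linkage, Euclidean distances.

    Rows and columns are clustered independently.  Labels are pre-sorted so
    merge tie-breaking (scipy's index order) is deterministic under input
    permutation; leaf orders come from the dendrograms.
    """
    if len(matrix.row_labels) < 2:
        raise ValueError("biclust_order requires at least 2 rows")

    def one_axis(values: np.ndarray, labels: list[str]) -> tuple[np.ndarray, list[str], str]:
        order = sorted(range(len(labels)), key=lambda i: labels[i])
        values = values[order]
        labels = [labels[i] for i in order]
        merge = linkage(pdist(values, metric="euclidean"), method="average")
        leaf_order = [labels[i] for i in leaves_list(merge)]
        return merge, leaf_order, _linkage_to_newick(merge, labels)

    row_merge, row_order, row_newick = one_axis(
        matrix.values, list(matrix.row_labels)
    )
    col_merge, col_order, col_newick = one_axis(
        matrix.values.T, list(matrix.col_labels)
    )
    return BiclustResult(
        row_linkage=row_merge,
        col_linkage=col_merge,
        row_order=row_order,
        col_order=col_order,
        row_newick=row_newick,
        col_newick=col_newick,
    )
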