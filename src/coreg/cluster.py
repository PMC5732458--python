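"""Hierarchical clustering of the dissimilarity matrix and tree cutting.

The tree is always built with complete linkage.  Two cutting strategies
are provided: the adaptive hybrid dynamic cut (default, see
:mod:`coreg._treecut`) and a fixed-height static cut.  Both relabel
clusters to contiguous positive integers in decreasing-size order and
report genes outside any qualifying cluster as module 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from coreg._treecut import cutree_hybrid
from coreg.similarity import DissimilarityMatrix

DEEP_SPLIT_VALUES = (0, 1, 2, 3, 4)


@dataclass
class ClusterTree:
    """Complete-linkage merge tree over the genes of a dissimilarity matrix."""

    genes: list[str]
    linkage: np.ndarray  # scipy linkage matrix, (n-1) x 4
    linkage_name: str = "complete"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class ModulePartition:
    """Gene -> module id mapping; id 0 means unassigned."""

    assignment: dict[str, int]
    params: dict = field(default_factory=dict)

    @property
    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for mod in self.assignment.values():
            if mod > 0:
                sizes[mod] = sizes.get(mod, 0) + 1
        return sizes

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def members(self, module_id: int) -> list[str]:
        return [g for g, m in self.assignment.items() if m == module_id]


def _labels_to_partition(
    genes: list[str],
    labels: np.ndarray,
    min_cluster_size: int,
    params: dict,
) -> ModulePartition:
    """Drop undersized clusters, relabel survivors by decreasing size."""
    labels = np.asarray(labels, dtype=int).copy()
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    for mod, size in zip(ids, counts):
        if size < min_cluster_size:
            labels[labels == mod] = 0
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    order = np.lexsort((ids, -counts))
    remap = {int(ids[pos]): new for new, pos in enumerate(order, start=1)}
    assignment = {g: remap.get(int(lab), 0) for g, lab in zip(genes, labels)}
    return ModulePartition(assignment, params=params)


def hierarchical_cluster(d: DissimilarityMatrix) -> ClusterTree:
    """Complete-linkage agglomeration on a dissimilarity matrix.

    SciPy's nearest-neighbor-chain agglomeration is deterministic for a
    fixed input ordering, which the pipeline guarantees.
    """
    if len(d.genes) < 2:
        raise ValueError("clustering needs at least 2 genes")
    condensed = squareform(np.asarray(d.values, dtype=float), checks=False)
    return ClusterTree(list(d.genes), linkage(condensed, method="complete"))


def dynamic_tree_cut(
    tree: ClusterTree,
    d: DissimilarityMatrix,
    deep_split: int = 1,
    min_cluster_size: int = 2,
    max_height: float = 1.0,
) -> ModulePartition:
    """Hybrid adaptive cut of the dendrogram.

    ``deep_split`` (0..4) controls how aggressively branches are split;
    ``max_height`` caps the merge height considered (1.0, the upper
    bound of the normalized dissimilarity, by default).  Every reported
    module has at least ``min_cluster_size`` genes.
    """
    if deep_split not in DEEP_SPLIT_VALUES:
        raise ValueError(f"deep_split must be one of {DEEP_SPLIT_VALUES}, got {deep_split}")
    if tree.genes != d.genes:
        raise ValueError("tree and dissimilarity matrix cover different genes")
    labels = cutree_hybrid(
        tree.linkage,
        np.asarray(d.values, dtype=float),
        deep_split=deep_split,
        min_cluster_size=min_cluster_size,
        cut_height=max_height,
    )
    params = {
        "method": "dynamic",
        "deep_split": deep_split,
        "min_cluster_size": min_cluster_size,
        "max_height": max_height,
        "linkage": tree.linkage_name,
    }
    return _labels_to_partition(tree.genes, labels, min_cluster_size, params)


def static_tree_cut(
    tree: ClusterTree,
    height: float,
    min_cluster_size: int = 2,
) -> ModulePartition:
    """Cut every branch at a fixed height; undersized clusters become 0."""
    if not 0.0 <= height <= 1.0:
        raise ValueError(f"height must be in [0, 1], got {height}")
    labels = fcluster(tree.linkage, t=height, criterion="distance")
    params = {
        "method": "static",
        "height": height,
        "min_cluster_size": min_cluster_size,
        "linkage": tree.linkage_name,
    }
    return _labels_to_partition(tree.genes, labels, min_cluster_size, params)
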