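"""Scoring module-finding output against ground truth.

Metrics: normalized mutual information between partitions, the
size-weighted rewiring recall score over (original, duplicate) pairs,
ROC/AUC over ranked co-regulator pairs, the printed random-walk
similarity baseline, the directed-to-bipartite transformation, and the
static-versus-dynamic tree cut comparison harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.linalg import matrix_power
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from coreg.cluster import (
    DEEP_SPLIT_VALUES,
    ModulePartition,
    dynamic_tree_cut,
    hierarchical_cluster,
    static_tree_cut,
)
from coreg.netio import DirectedNetwork
from coreg.similarity import DissimilarityMatrix, SimilarityMatrix

STATIC_HEIGHTS = tuple(round(0.1 * i, 1) for i in range(11))  # 0.0 .. 1.0


@dataclass
class EvaluationReport:
    metric: str
    value: float
    params: dict = field(default_factory=dict)
    per_run: list[float] = field(default_factory=list)


@dataclass
class BipartiteNetwork:
    """Undirected two-sided view of a directed network.

    Head copies exist for nodes with out-degree > 0, tail copies for
    nodes with in-degree > 0; each directed edge u -> v becomes the
    undirected edge (u_h, v_t).  Copies are named by suffixing the
    original identifier.
    """

    head_nodes: list[str]
    tail_nodes: list[str]
    edges: list[tuple[str, str]]  # (head copy, tail copy)

    @staticmethod
    def head_name(gene: str) -> str:
        return gene + "_h"

    @staticmethod
    def tail_name(gene: str) -> str:
        return gene + "_t"

    def merge_copy_modules(self, copy_assignment: dict[str, int]) -> dict[str, set[int]]:
        """Back-map module labels from copies to original nodes (union rule)."""
        merged: dict[str, set[int]] = {}
        for gene in {g[:-2] for g in copy_assignment}:
            mods: set[int] = set()
            for copy in (self.head_name(gene), self.tail_name(gene)):
                if copy in copy_assignment:
                    mods.add(copy_assignment[copy])
            merged[gene] = mods
        return merged


def _entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi(
    partition_a: ModulePartition | dict[str, int],
    partition_b: ModulePartition | dict[str, int],
    restrict_to: set[str] | None = None,
) -> float:
    """Normalized mutual information, 2*I / (H_a + H_b).

    Genes with module 0 (unassigned) are treated as singleton clusters:
    unassignment is absence of a claim, not a shared module.  If exactly
    one partition is a single cluster the score is 0; if both are, 1.
    """
    a = getattr(partition_a, "assignment", partition_a)
    b = getattr(partition_b, "assignment", partition_b)
    genes = sorted(set(a) & set(b))
    if restrict_to is not None:
        genes = sorted(set(genes) & set(restrict_to))
    if not genes:
        raise ValueError("partitions share no genes on the requested set")

    def labels(assignment: dict[str, int]) -> np.ndarray:
        out = np.empty(len(genes), dtype=int)
        next_singleton = -1
        for i, g in enumerate(genes):
            mod = assignment[g]
            if mod == 0:
                out[i] = next_singleton
                next_singleton -= 1
            else:
                out[i] = mod
        return out

    la, lb = labels(a), labels(b)
    _, ia = np.unique(la, return_inverse=True)
    _, ib = np.unique(lb, return_inverse=True)
    n_a, n_b = ia.max() + 1, ib.max() + 1
    contingency = np.zeros((n_a, n_b))
    np.add.at(contingency, (ia, ib), 1.0)
    n = contingency.sum()
    h_a = _entropy(contingency.sum(axis=1))
    h_b = _entropy(contingency.sum(axis=0))
    if h_a == 0.0 or h_b == 0.0:
        return 1.0 if (h_a == 0.0 and h_b == 0.0) else 0.0
    p = contingency / n
    outer = np.outer(contingency.sum(axis=1), contingency.sum(axis=0)) / n**2
    nz = p > 0
    mi = float((p[nz] * np.log(p[nz] / outer[nz])).sum())
    return float(np.clip(2.0 * mi / (h_a + h_b), 0.0, 1.0))


def rewiring_recall_score(
    partition: ModulePartition | dict[str, int],
    pairs: list[tuple[str, str]],
    total_nodes: int,
) -> float:
    """Size-weighted recall of true co-regulator pairs landing together.

    ``score = sum_i s_i * w_i / (|V| * |U| / 2)`` with ``s_i = 1`` iff
    the pair shares a nonzero module and ``w_i = |V| / m_i`` where
    ``m_i`` is that module's size.  Equals 1 exactly when every pair
    sits alone in its own two-node module.
    """
    if total_nodes <= 0:
        raise ValueError("total_nodes must be positive")
    if not pairs:
        raise ValueError("no pairs to score")
    assignment = getattr(partition, "assignment", partition)
    sizes: dict[int, int] = {}
    for mod in assignment.values():
        if mod > 0:
            sizes[mod] = sizes.get(mod, 0) + 1
    numerator = 0.0
    for u, u_dup in pairs:
        mod_u = assignment.get(u, 0)
        mod_d = assignment.get(u_dup, 0)
        if mod_u > 0 and mod_u == mod_d:
            numerator += total_nodes / sizes[mod_u]
    return numerator / (total_nodes * len(pairs) / 2.0)


def bipartite_transform(net: DirectedNetwork) -> BipartiteNetwork:
    """Split each node into head/tail copies; edges become undirected."""
    head_nodes = [
        BipartiteNetwork.head_name(g) for g in net.nodes if net.out_degree(g) > 0
    ]
    tail_nodes = [
        BipartiteNetwork.tail_name(g) for g in net.nodes if net.in_degree(g) > 0
    ]
    edges = [
        (BipartiteNetwork.head_name(u), BipartiteNetwork.tail_name(v))
        for u, v in net.edges
    ]
    return BipartiteNetwork(head_nodes, tail_nodes, edges)


def wt_similarity(
    net: DirectedNetwork,
    steps: int = 4,
    per_step_degree: bool = False,
) -> SimilarityMatrix:
    """Random-walk similarity baseline, 1 - D on ``P = T^steps``.

    The adjacency gets a unit diagonal (self-loops guarantee positive
    row sums), T is the row-normalized transition matrix, and

        D(i, j) = sqrt( sum_k (P_ik - P_jk)^2 / d(i) )

    with d the total degree on the self-loop-augmented adjacency.  Note
    the divisor indexes the *row* node, making D (and S) asymmetric;
    ``per_step_degree=True`` switches to the variant that divides each
    term by d(k) instead, which is symmetric.
    """
    if steps < 1:
        raise ValueError("steps must be a positive integer")
    index = {g: i for i, g in enumerate(net.nodes)}
    n = len(net.nodes)
    adj = np.zeros((n, n))
    for u, v in net.edges:
        adj[index[u], index[v]] = 1.0
    np.fill_diagonal(adj, 1.0)
    t = adj / adj.sum(axis=1, keepdims=True)
    p = matrix_power(t, steps)
    degree = adj.sum(axis=1) + adj.sum(axis=0)
    # ||P_i - P_j||^2 (optionally d(k)-weighted) via the Gram identity
    if per_step_degree:
        gram = (p / degree[None, :]) @ p.T
    else:
        gram = p @ p.T
    sq = np.diag(gram)
    sq_norm = np.clip(sq[:, None] + sq[None, :] - 2.0 * gram, 0.0, None)
    dist = np.sqrt(sq_norm if per_step_degree else sq_norm / degree[:, None])
    values = 1.0 - dist
    np.fill_diagonal(values, 0.0)
    return SimilarityMatrix(list(net.nodes), values, "walktrap", "combined")


def roc_auc(
    positive_scores: list[float], negative_scores: list[float]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (fpr, tpr) and trapezoidal AUC for two score samples."""
    if len(positive_scores) == 0 or len(negative_scores) == 0:
        raise ValueError("both score lists must be nonempty")
    y_true = np.concatenate(
        [np.ones(len(positive_scores)), np.zeros(len(negative_scores))]
    )
    y_score = np.concatenate([positive_scores, negative_scores])
    fpr, tpr, _ = _sk_roc_curve(y_true, y_score)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


def pair_scores(
    sim: SimilarityMatrix, pairs: list[tuple[str, str]], symmetrize: bool = True
) -> list[float]:
    """Similarity score per gene pair (averaged over orientation by default)."""
    index = {g: i for i, g in enumerate(sim.genes)}
    values = np.asarray(sim.values)
    out = []
    for u, v in pairs:
        i, j = index[u], index[v]
        s = 0.5 * (values[i, j] + values[j, i]) if symmetrize else values[i, j]
        out.append(float(s))
    return out


def compare_tree_cuts(
    d: DissimilarityMatrix,
    rewired,
    min_cluster_size: int = 2,
    deep_split_values: tuple[int, ...] = DEEP_SPLIT_VALUES,
) -> dict[str, EvaluationReport]:
    """Grid-search static vs dynamic cutting by rewiring recall score.

    The static cut is evaluated at 11 heights (0.0 to 1.0 in steps of
    0.1); the dynamic cut over the grid of the same 11 max-heights times
    the deepSplit values.  Returns the best RRS of each strategy with
    the winning parameters; which strategy wins is reported, not
    asserted.
    """
    tree = hierarchical_cluster(d)
    total_nodes = rewired.network.n_nodes
    pairs = rewired.pairs

    static_scores: list[float] = []
    best_static = (-1.0, None)
    for h in STATIC_HEIGHTS:
        part = static_tree_cut(tree, h, min_cluster_size)
        score = rewiring_recall_score(part, pairs, total_nodes)
        static_scores.append(score)
        if score > best_static[0]:
            best_static = (score, h)

    dynamic_scores: list[float] = []
    best_dynamic = (-1.0, None, None)
    for h in STATIC_HEIGHTS:
        for ds in deep_split_values:
            if h == 0.0:
                score = 0.0  # no merges below height 0: nothing is clustered
            else:
                part = dynamic_tree_cut(
                    tree, d, deep_split=ds, min_cluster_size=min_cluster_size, max_height=h
                )
                score = rewiring_recall_score(part, pairs, total_nodes)
            dynamic_scores.append(score)
            if score > best_dynamic[0]:
                best_dynamic = (score, h, ds)

    return {
        "static": EvaluationReport(
            "rrs",
            best_static[0],
            params={"height": best_static[1], "grid_size": len(STATIC_HEIGHTS)},
            per_run=static_scores,
        ),
        "dynamic": EvaluationReport(
            "rrs",
            best_dynamic[0],
            params={
                "max_height": best_dynamic[1],
                "deep_split": best_dynamic[2],
                "grid_size": len(STATIC_HEIGHTS) * len(deep_split_values),
            },
            per_run=dynamic_scores,
        ),
    }
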