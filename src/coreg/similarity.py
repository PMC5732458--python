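"""Pairwise neighbor-overlap similarity and dissimilarity matrices.

Three indices are supported, each computed separately over in-neighbors
and out-neighbors and then combined as a weighted sum
``S = w1 * S_in + w2 * S_out`` (defaults w1 = w2 = 1):

* ``jaccard``       -- |common| / |union| of neighbor sets (0 when both
  sets are empty);
* ``geometric``     -- |common|^2 / (|N(i)| * |N(j)|) (0 when either set
  is empty);
* ``invlogweighted`` -- sum over common neighbors c of 1/log(d(c)),
  where d(c) is the total (in + out) degree of c, natural log.  For
  weighted networks d(c) is the summed weight of edges incident to c.

The dissimilarity transform is ``S' = (max(S) - S) / max(S)`` with the
maximum taken over off-diagonal entries; the diagonal is fixed at 0 and
never enters the normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from coreg.netio import DirectedNetwork, NetworkError

VALID_INDICES = ("jaccard", "geometric", "invlogweighted")


@dataclass
class SimilarityMatrix:
    genes: list[str]
    values: np.ndarray
    index_name: str
    direction: str  # "in", "out" or "combined"
    weights: tuple[float, float] | None = None

    def value(self, gene_a: str, gene_b: str) -> float:
        i = self.genes.index(gene_a)
        j = self.genes.index(gene_b)
        return float(self.values[i, j])

    def to_tsv(self, path) -> None:
        _write_labeled_matrix(self.genes, self.values, path)


@dataclass
class DissimilarityMatrix:
    genes: list[str]
    values: np.ndarray
    source_max: float

    def to_tsv(self, path) -> None:
        _write_labeled_matrix(self.genes, self.values, path)


def _write_labeled_matrix(genes, values, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(genes) + "\n")
        for g, row in zip(genes, np.asarray(values)):
            fh.write(g + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def _neighbor_matrix(net: DirectedNetwork, direction: str) -> sp.csr_matrix:
    """Boolean node x node matrix; row i holds the chosen neighbor set of node i."""
    if direction not in ("in", "out"):
        raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")
    index = {g: i for i, g in enumerate(net.nodes)}
    n = len(net.nodes)
    rows = np.fromiter((index[u] for u, _ in net.edges), dtype=np.int64, count=len(net.edges))
    cols = np.fromiter((index[v] for _, v in net.edges), dtype=np.int64, count=len(net.edges))
    data = np.ones(len(net.edges), dtype=np.float64)
    adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    adj.data[:] = 1.0  # collapse any duplicates defensively
    return adj if direction == "out" else adj.T.tocsr()


def _zero_diagonal(values: np.ndarray) -> np.ndarray:
    np.fill_diagonal(values, 0.0)
    return values


def jaccard_similarity(net: DirectedNetwork, direction: str) -> SimilarityMatrix:
    """Jaccard overlap of in- or out-neighbor sets for every node pair."""
    nbr = _neighbor_matrix(net, direction)
    common = np.asarray((nbr @ nbr.T).todense())
    sizes = np.asarray(nbr.sum(axis=1)).ravel()
    union = sizes[:, None] + sizes[None, :] - common
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(union > 0, common / np.where(union > 0, union, 1.0), 0.0)
    return SimilarityMatrix(list(net.nodes), _zero_diagonal(values), "jaccard", direction)


def geometric_similarity(net: DirectedNetwork, direction: str) -> SimilarityMatrix:
    """Squared common-neighbor count over the product of neighbor counts."""
    nbr = _neighbor_matrix(net, direction)
    common = np.asarray((nbr @ nbr.T).todense())
    sizes = np.asarray(nbr.sum(axis=1)).ravel()
    prod = sizes[:, None] * sizes[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(prod > 0, common**2 / np.where(prod > 0, prod, 1.0), 0.0)
    return SimilarityMatrix(list(net.nodes), _zero_diagonal(values), "geometric", direction)


def _total_degrees(net: DirectedNetwork, use_weights: bool) -> np.ndarray:
    index = {g: i for i, g in enumerate(net.nodes)}
    d = np.zeros(len(net.nodes))
    for u, v in net.edges:
        w = 1.0
        if use_weights:
            if net.weights is None or (u, v) not in net.weights:
                raise NetworkError("use_weights=True but the network has no edge weights")
            w = net.weights[(u, v)]
            if w <= 0:
                raise NetworkError("all edge weights must be > 0 for the weighted index")
        d[index[u]] += w
        d[index[v]] += w
    return d


def invlogweighted_similarity(
    net: DirectedNetwork, direction: str, use_weights: bool = False
) -> SimilarityMatrix:
    """Inverse log-weighted count of common neighbors.

    Each common neighbor c contributes ``1 / log(d(c))`` with d(c) the
    total degree of c (or its summed edge weight when ``use_weights``).
    A common neighbor with d(c) <= 1 would make the term undefined; this
    cannot happen in a clean unweighted network but can with weights, in
    which case an error instructs the caller to rescale weights.
    """
    nbr = _neighbor_matrix(net, direction)
    d = _total_degrees(net, use_weights)
    # nodes that can appear as a common neighbor have >= 2 incident edges
    # in the opposite direction of `direction`
    candidate = np.asarray(nbr.sum(axis=0)).ravel() >= 2
    if np.any(candidate & (d <= 1.0)):
        raise NetworkError(
            "a potential common neighbor has (weighted) degree <= 1; "
            "rescale edge weights so every summed weight exceeds 1"
        )
    inv_log = np.zeros_like(d)
    ok = d > 1.0
    inv_log[ok] = 1.0 / np.log(d[ok])
    weighted = nbr.multiply(inv_log[None, :]).tocsr()
    values = np.asarray((weighted @ nbr.T).todense())
    return SimilarityMatrix(
        list(net.nodes), _zero_diagonal(values), "invlogweighted", direction
    )


_INDEX_FUNCS = {
    "jaccard": jaccard_similarity,
    "geometric": geometric_similarity,
    "invlogweighted": invlogweighted_similarity,
}


def combine_similarity(
    s_in: SimilarityMatrix,
    s_out: SimilarityMatrix,
    w1: float = 1.0,
    w2: float = 1.0,
) -> SimilarityMatrix:
    """Weighted elementwise sum ``w1 * S_in + w2 * S_out``."""
    if s_in.genes != s_out.genes:
        raise ValueError("gene orderings of the two matrices differ")
    if s_in.index_name != s_out.index_name:
        raise ValueError("cannot combine matrices built with different indices")
    if w1 < 0 or w2 < 0 or (w1 == 0 and w2 == 0):
        raise ValueError("weights must be non-negative and not both zero")
    values = w1 * s_in.values + w2 * s_out.values
    return SimilarityMatrix(
        list(s_in.genes), values, s_in.index_name, "combined", weights=(w1, w2)
    )


def similarity_matrix(
    net: DirectedNetwork,
    index: str = "jaccard",
    w1: float = 1.0,
    w2: float = 1.0,
    use_weights: bool = False,
) -> SimilarityMatrix:
    """Convenience: combined in + out similarity under the chosen index."""
    if index not in _INDEX_FUNCS:
        raise ValueError(f"unknown similarity index {index!r}; choose from {VALID_INDICES}")
    if index == "invlogweighted":
        s_in = invlogweighted_similarity(net, "in", use_weights=use_weights)
        s_out = invlogweighted_similarity(net, "out", use_weights=use_weights)
    else:
        func = _INDEX_FUNCS[index]
        s_in = func(net, "in")
        s_out = func(net, "out")
    return combine_similarity(s_in, s_out, w1, w2)


def to_dissimilarity(s: SimilarityMatrix) -> DissimilarityMatrix:
    """Normalize to ``S' = (max(S) - S) / max(S)`` over off-diagonal entries.

    The diagonal is set to 0 (self-distance) and excluded from max(S).
    An all-zero similarity matrix carries no co-regulation signal and is
    rejected.
    """
    values = np.array(s.values, dtype=float, copy=True)
    n = values.shape[0]
    off_diag = ~np.eye(n, dtype=bool)
    source_max = float(values[off_diag].max()) if n > 1 else 0.0
    if not source_max > 0:
        raise NetworkError(
            "no co-regulation signal: every off-diagonal similarity is zero"
        )
    out = (source_max - values) / source_max
    np.fill_diagonal(out, 0.0)
    out = np.clip(out, 0.0, 1.0)
    return DissimilarityMatrix(list(s.genes), out, source_max)
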