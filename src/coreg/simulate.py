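"""Planted co-regulatory network simulation and duplication--rewiring.

Two ground-truth generators:

* :func:`generate_simulated_network` plants co-regulatory modules.  It
  creates ``mSize x mNum`` regulator nodes split evenly into modules,
  ``auxNum`` auxiliary target-only nodes, a pool of ``targetNum``
  candidate targets per module, and gives every regulator exactly
  ``targetNum`` distinct targets -- each drawn from its module's pool
  with probability ``prob`` and from outside the pool otherwise.

* :func:`duplicate_and_rewire` copies the neighborhoods of randomly
  chosen nodes onto fresh duplicate nodes, making each (original,
  duplicate) pair a known true co-regulator pair, then perturbs the
  duplicates by swapping edge targets between duplicates with a given
  probability.  Swaps change neither the edge count nor any node degree,
  and the subgraph on the original nodes is untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from coreg.netio import DirectedNetwork, NetworkError

logger = logging.getLogger(__name__)

DUPLICATE_SUFFIX = "__dup"


@dataclass(frozen=True)
class SimulationParams:
    """Five-parameter planted-module generator settings."""

    mSize: int  # regulators per module
    mNum: int  # number of modules
    targetNum: int  # targets per regulator == pool size per module
    auxNum: int  # auxiliary (target-only) nodes
    prob: float  # co-regulation probability
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("mSize", "mNum", "targetNum", "auxNum"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"prob must be in [0, 1], got {self.prob}")
        if self.auxNum < self.targetNum:
            raise ValueError("auxNum must be >= targetNum (pools must be fillable)")


@dataclass
class SimulatedNetwork:
    network: DirectedNetwork
    planted: dict[str, int]  # regulator -> module label (1-based)
    pools: dict[int, set[str]]  # module label -> pool of candidate targets
    params: SimulationParams


@dataclass
class RewiredNetwork:
    network: DirectedNetwork
    pairs: list[tuple[str, str]]  # (original, duplicate)
    rewire_prob: float
    seed: int | None
    n_swaps: int = 0


def generate_simulated_network(params: SimulationParams) -> SimulatedNetwork:
    """Generate a directed network with planted co-regulatory modules.

    Regulators never receive incoming edges and auxiliary nodes never
    send outgoing edges, so planted regulator modules and their target
    pools are cleanly separable.  Pools are pairwise disjoint whenever
    ``auxNum >= mNum * targetNum``; otherwise each pool is sampled
    independently (with a warning).
    """
    rng = np.random.default_rng(params.seed)
    regulators = [
        f"r{m + 1:03d}_{k + 1:03d}" for m in range(params.mNum) for k in range(params.mSize)
    ]
    planted = {
        reg: m + 1 for m in range(params.mNum) for reg in
        regulators[m * params.mSize : (m + 1) * params.mSize]
    }
    aux = [f"t{i + 1:04d}" for i in range(params.auxNum)]
    aux_arr = np.array(aux)

    pools: dict[int, set[str]] = {}
    if params.auxNum >= params.mNum * params.targetNum:
        perm = rng.permutation(params.auxNum)
        for m in range(params.mNum):
            chunk = perm[m * params.targetNum : (m + 1) * params.targetNum]
            pools[m + 1] = set(aux_arr[chunk])
    else:
        logger.warning(
            "auxNum < mNum * targetNum: module pools are sampled independently "
            "and may overlap"
        )
        for m in range(params.mNum):
            chunk = rng.choice(params.auxNum, size=params.targetNum, replace=False)
            pools[m + 1] = set(aux_arr[chunk])

    edges: list[tuple[str, str]] = []
    for reg in regulators:
        pool = sorted(pools[planted[reg]])
        off_pool = sorted(set(aux) - pools[planted[reg]])
        n_in_pool = int(rng.binomial(params.targetNum, params.prob))
        n_off_pool = params.targetNum - n_in_pool
        if n_off_pool > len(off_pool):
            raise NetworkError(
                f"cannot draw {n_off_pool} off-pool targets: only {len(off_pool)} "
                "auxiliary nodes outside the module pool (increase auxNum)"
            )
        targets: list[str] = []
        if n_in_pool:
            targets.extend(rng.choice(pool, size=n_in_pool, replace=False))
        if n_off_pool:
            targets.extend(rng.choice(off_pool, size=n_off_pool, replace=False))
        edges.extend((reg, t) for t in targets)

    network = DirectedNetwork.from_edges(edges)
    # auxiliary nodes that were never chosen as targets do not appear in the
    # edge list and hence are not part of the network (nodes are defined by
    # edges); planted labels and pools are kept regardless.
    return SimulatedNetwork(network, planted, pools, params)


def _duplicate_name(original: str, taken: set[str]) -> str:
    name = original + DUPLICATE_SUFFIX
    while name in taken:
        name += "x"
    return name


def duplicate_and_rewire(
    net: DirectedNetwork,
    n: int,
    rewire_prob: float,
    seed: int | None = None,
) -> RewiredNetwork:
    """Duplicate ``n`` out-degree-positive nodes, then rewire duplicates.

    Every duplicate inherits all in- and out-edges of its original.  In
    a single deterministic pass, each outgoing edge of each duplicate is
    selected with probability ``rewire_prob``; when selected, its target
    is swapped with the target of a uniformly chosen outgoing edge of a
    *different* duplicate.  Swaps that would create a self-loop or a
    parallel edge are re-drawn (a bounded number of times) so the result
    remains a simple graph with the original degree sequence.
    """
    if not 0.0 <= rewire_prob <= 1.0:
        raise ValueError(f"rewire_prob must be in [0, 1], got {rewire_prob}")
    candidates = [g for g in net.nodes if net.out_degree(g) > 0]
    if n > len(candidates):
        raise NetworkError(
            f"cannot duplicate {n} nodes: only {len(candidates)} have out-degree > 0"
        )
    if n < 2 and rewire_prob > 0:
        raise NetworkError("rewiring needs at least 2 duplicates as swap partners")
    rng = np.random.default_rng(seed)
    chosen = [candidates[i] for i in rng.choice(len(candidates), size=n, replace=False)]

    taken = set(net.nodes)
    pairs: list[tuple[str, str]] = []
    dup_out: dict[str, list[str]] = {}
    extra_in: list[tuple[str, str]] = []
    for orig in chosen:
        dup = _duplicate_name(orig, taken)
        taken.add(dup)
        pairs.append((orig, dup))
        dup_out[dup] = sorted(net.out_neighbors(orig))
        extra_in.extend((r, dup) for r in sorted(net.in_neighbors(orig)))

    dups = [d for _, d in pairs]
    n_swaps = 0
    if rewire_prob > 0:
        # flat index over (duplicate, slot) pairs for partner sampling
        slot_owner: list[tuple[str, int]] = [
            (d, k) for d in dups for k in range(len(dup_out[d]))
        ]
        for d in dups:
            for k in range(len(dup_out[d])):
                if rng.random() >= rewire_prob:
                    continue
                for _attempt in range(50):
                    j = int(rng.integers(len(slot_owner)))
                    e, m = slot_owner[j]
                    if e == d:
                        continue
                    t_d, t_e = dup_out[d][k], dup_out[e][m]
                    if t_e in dup_out[d] or t_d in dup_out[e]:
                        continue  # would create a parallel edge
                    dup_out[d][k], dup_out[e][m] = t_e, t_d
                    n_swaps += 1
                    break

    edges = list(net.edges)
    for d in dups:
        edges.extend((d, t) for t in dup_out[d])
    edges.extend(extra_in)
    weights = dict(net.weights) if net.weights is not None else None
    network = DirectedNetwork.from_edges(edges, weights=weights)
    return RewiredNetwork(network, pairs, rewire_prob, seed, n_swaps)


def sample_negative_pairs(
    rewired: RewiredNetwork,
    count: int,
    seed: int | None = None,
) -> list[tuple[str, str]]:
    """Random pairs of duplicates that come from *different* originals."""
    dups = [d for _, d in rewired.pairs]
    if len(dups) < 2:
        raise NetworkError("need at least 2 duplicated nodes to form negative pairs")
    origin = {d: o for o, d in rewired.pairs}
    candidates = [
        (dups[i], dups[j])
        for i in range(len(dups))
        for j in range(i + 1, len(dups))
        if origin[dups[i]] != origin[dups[j]]
    ]
    if count > len(candidates):
        raise NetworkError(
            f"requested {count} negative pairs but only {len(candidates)} exist"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=count, replace=False)
    return [candidates[i] for i in idx]
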