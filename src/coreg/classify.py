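"""Module type classification by edge-direction composition.

A module is a *regulator* module when more than 90% (configurable) of
the edges incident to its genes are outgoing, a *target* module when
more than 90% are incoming, and *intermediate* otherwise.  Edges are
pooled over the whole module by default: an edge whose head lies in the
module counts as outgoing, one whose tail lies in the module counts as
incoming, and an edge internal to the module counts once in each
direction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from coreg.cluster import ModulePartition
from coreg.netio import DirectedNetwork, NetworkError


class ModuleType(str, enum.Enum):
    REGULATOR = "regulator"
    TARGET = "target"
    INTERMEDIATE = "intermediate"


@dataclass
class ModuleTypeInfo:
    module_type: ModuleType
    out_fraction: float
    edge_count: int  # pooled directed incidences (internal edges count twice)


def _classify_fraction(out_fraction: float, threshold: float) -> ModuleType:
    if out_fraction > threshold:
        return ModuleType.REGULATOR
    if (1.0 - out_fraction) > threshold:
        return ModuleType.TARGET
    return ModuleType.INTERMEDIATE


def classify_modules(
    net: DirectedNetwork,
    partition: ModulePartition,
    threshold: float = 0.9,
    per_gene: bool = False,
) -> dict[int, ModuleTypeInfo]:
    """Label every assigned module as regulator/target/intermediate.

    ``per_gene=True`` switches to a strict mode in which a module is a
    regulator (target) module only when *every* member gene individually
    exceeds the threshold; the default pools edges over the module.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    node_set = set(net.nodes)
    for gene, mod in partition.assignment.items():
        if mod > 0 and gene not in node_set:
            raise NetworkError(f"assigned gene {gene!r} is not in the network")

    modules: dict[int, list[str]] = {}
    for gene, mod in partition.assignment.items():
        if mod > 0:
            modules.setdefault(mod, []).append(gene)

    result: dict[int, ModuleTypeInfo] = {}
    for mod, genes in sorted(modules.items()):
        out_ct = sum(net.out_degree(g) for g in genes)
        in_ct = sum(net.in_degree(g) for g in genes)
        total = out_ct + in_ct
        if total == 0:
            raise NetworkError(f"module {mod} has no incident edges")
        out_fraction = out_ct / total
        if per_gene:
            gene_types = []
            for g in genes:
                g_total = net.out_degree(g) + net.in_degree(g)
                if g_total == 0:
                    raise NetworkError(f"gene {g!r} in module {mod} has no edges")
                gene_types.append(_classify_fraction(net.out_degree(g) / g_total, threshold))
            if all(t is ModuleType.REGULATOR for t in gene_types):
                mtype = ModuleType.REGULATOR
            elif all(t is ModuleType.TARGET for t in gene_types):
                mtype = ModuleType.TARGET
            else:
                mtype = ModuleType.INTERMEDIATE
        else:
            mtype = _classify_fraction(out_fraction, threshold)
        result[mod] = ModuleTypeInfo(mtype, out_fraction, total)
    return result
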