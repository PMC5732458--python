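"""Reading, cleaning and writing directed regulatory networks and module tables.

Edge lists are plain text: one edge per line, first column the regulator
(head), second column the target (tail), optional third column a
non-negative edge weight.  Columns are separated by whitespace or an
explicit delimiter; lines starting with ``#`` are ignored.  Gene
identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

logger = logging.getLogger(__name__)


class NetworkError(ValueError):
    """Raised for malformed or degenerate network input."""


@dataclass
class DirectedNetwork:
    """A directed graph of regulator -> target edges.

    ``nodes`` is kept in first-appearance order of the edge list, which
    makes every downstream matrix ordering deterministic.  ``edges`` may
    contain duplicates and self-loops until :func:`clean_network` is
    applied.
    """

    nodes: list[str]
    edges: list[tuple[str, str]]
    weights: dict[tuple[str, str], float] | None = None
    _out: dict[str, set[str]] | None = field(default=None, repr=False, compare=False)
    _in: dict[str, set[str]] | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        weights: dict[tuple[str, str], float] | None = None,
    ) -> "DirectedNetwork":
        edges = list(edges)
        nodes: list[str] = []
        seen: set[str] = set()
        for u, v in edges:
            for g in (u, v):
                if g not in seen:
                    seen.add(g)
                    nodes.append(g)
        return cls(nodes=nodes, edges=edges, weights=weights)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def _build_adjacency(self) -> None:
        out: dict[str, set[str]] = {g: set() for g in self.nodes}
        inn: dict[str, set[str]] = {g: set() for g in self.nodes}
        for u, v in self.edges:
            out[u].add(v)
            inn[v].add(u)
        self._out, self._in = out, inn

    def out_neighbors(self, gene: str) -> set[str]:
        if self._out is None:
            self._build_adjacency()
        return self._out[gene]

    def in_neighbors(self, gene: str) -> set[str]:
        if self._in is None:
            self._build_adjacency()
        return self._in[gene]

    def out_degree(self, gene: str) -> int:
        return len(self.out_neighbors(gene))

    def in_degree(self, gene: str) -> int:
        return len(self.in_neighbors(gene))

    def degree(self, gene: str) -> int:
        """Total degree (in + out) used by the inverse log-weighted index."""
        return self.in_degree(gene) + self.out_degree(gene)


class CleanResult(NamedTuple):
    network: DirectedNetwork
    self_loops_removed: int
    duplicates_removed: int


def read_edge_list(
    path: str | Path,
    has_weights: bool = False,
    delimiter: str | None = None,
) -> DirectedNetwork:
    """Parse an edge-list file verbatim (no cleaning).

    Parameters
    ----------
    path:
        Text file with >= 2 whitespace/``delimiter``-separated fields per
        non-comment line.
    has_weights:
        If true, a third column with a non-negative numeric weight is
        required on every line.
    delimiter:
        Field separator; ``None`` splits on any whitespace run.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    weights: dict[tuple[str, str], float] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise NetworkError(
                    f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}"
                )
            u, v = fields[0], fields[1]
            if has_weights:
                if len(fields) < 3:
                    raise NetworkError(f"{path}:{lineno}: weight column missing")
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise NetworkError(
                        f"{path}:{lineno}: weight {fields[2]!r} is not numeric"
                    ) from exc
                if w < 0:
                    raise NetworkError(f"{path}:{lineno}: negative weight {w}")
                # first occurrence wins for duplicated weighted edges
                weights.setdefault((u, v), w)
            edges.append((u, v))
    if not edges:
        raise NetworkError(f"{path}: no edges found")
    return DirectedNetwork.from_edges(edges, weights=weights if has_weights else None)


def clean_network(net: DirectedNetwork) -> CleanResult:
    """Remove self-loops and duplicated edges.

    Returns the cleaned network together with removal counts.  Raises if
    nothing is left.  Idempotent: cleaning a clean network is a no-op.
    """
    seen: set[tuple[str, str]] = set()
    kept: list[tuple[str, str]] = []
    n_loops = 0
    n_dups = 0
    for edge in net.edges:
        u, v = edge
        if u == v:
            n_loops += 1
            continue
        if edge in seen:
            n_dups += 1
            continue
        seen.add(edge)
        kept.append(edge)
    if not kept:
        raise NetworkError("network is empty after removing self-loops and duplicates")
    if n_dups and net.weights:
        logger.warning(
            "%d duplicated weighted edge(s) removed; first occurrence kept", n_dups
        )
    weights = None
    if net.weights is not None:
        weights = {e: net.weights[e] for e in kept if e in net.weights}
    return CleanResult(DirectedNetwork.from_edges(kept, weights=weights), n_loops, n_dups)


def write_edge_list(net: DirectedNetwork, path: str | Path) -> None:
    """Write a network back out as a two/three-column TSV."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v in net.edges:
            if net.weights is not None and (u, v) in net.weights:
                fh.write(f"{u}\t{v}\t{net.weights[(u, v)]:g}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def write_modules(
    partition: "ModulePartitionLike",
    path: str | Path,
    module_types: dict[int, str] | None = None,
) -> None:
    """Write a gene/module_id/module_type TSV.

    Module id 0 means "no module assignment"; its type column is left
    empty.  Round-trips losslessly through :func:`read_modules`.
    """
    assignment = getattr(partition, "assignment", partition)
    if not assignment:
        raise NetworkError("cannot write an empty module partition")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene\tmodule_id\tmodule_type\n")
        for gene, mod in assignment.items():
            mtype = ""
            if mod > 0 and module_types is not None:
                mtype = module_types.get(mod, "")
            fh.write(f"{gene}\t{mod}\t{mtype}\n")


def read_modules(path: str | Path) -> tuple[dict[str, int], dict[int, str]]:
    """Read a module TSV written by :func:`write_modules`.

    Returns ``(assignment, module_types)``.
    """
    path = Path(path)
    assignment: dict[str, int] = {}
    types: dict[int, str] = {}
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("gene\t"):
            raise NetworkError(f"{path}: missing module-table header")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise NetworkError(f"{path}:{lineno}: expected >= 2 fields")
            gene, mod = fields[0], int(fields[1])
            assignment[gene] = mod
            if mod > 0 and len(fields) >= 3 and fields[2]:
                types[mod] = fields[2]
    if not assignment:
        raise NetworkError(f"{path}: empty module table")
    return assignment, types


# typing helper: anything with an .assignment dict or a plain dict
ModulePartitionLike = object
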