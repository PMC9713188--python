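"""Heterogeneous drug-disease-protein network: typed nodes, bipartite
association tables, and an undirected typed-adjacency graph.

The network has exactly three node types (``drug``, ``disease``, ``protein``)
and three bipartite edge layers (drug-disease, drug-protein, disease-protein).
Associations are undirected: random walks must be able to traverse an edge in
both directions for symmetric meta-paths to cycle.

Identifiers are namespaced by node type, so a drug and a protein may share a
raw identifier without collision; a duplicate *within* one type is simply the
same node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .exceptions import ConfigError, GraphError, ParseError

NODE_TYPES = ("drug", "disease", "protein")


def _check_type(t: str) -> str:
    if t not in NODE_TYPES:
        raise ConfigError(f"unknown node type {t!r}; must be one of {NODE_TYPES}")
    return t


@dataclass(frozen=True, order=True)
class NodeRef:
    """A typed node reference; identifier is opaque and unique within its type."""

    node_type: str
    identifier: str

    def __post_init__(self) -> None:
        _check_type(self.node_type)


@dataclass(frozen=True)
class AssociationTable:
    """A de-duplicated set of undirected associations between two node types."""

    source_type: str
    target_type: str
    pairs: frozenset[tuple[str, str]]
    duplicates_dropped: int = 0

    def __post_init__(self) -> None:
        _check_type(self.source_type)
        _check_type(self.target_type)
        if self.source_type == self.target_type:
            raise ConfigError(
                f"within-type associations are not supported (got {self.source_type!r} twice)"
            )

    def __len__(self) -> int:
        return len(self.pairs)

    def edges(self) -> Iterator[tuple[NodeRef, NodeRef]]:
        for s, t in sorted(self.pairs):
            yield NodeRef(self.source_type, s), NodeRef(self.target_type, t)


def load_edge_list(
    path: str | Path,
    source_type: str,
    target_type: str,
    delimiter: str = "\t",
    header: bool = False,
) -> AssociationTable:
    """Read a two-column delimited edge list into an :class:`AssociationTable`.

    Duplicate pairs are dropped (the count is kept on the returned table and
    reported as a warning). A line with fewer than two fields raises
    :class:`ParseError` naming the line number; an empty file is an error.
    """
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    dups = 0
    with path.open() as fh:
        lines = fh.read().splitlines()
    if header:
        lines = lines[1:]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: no edges found (empty file)")
    for lineno, line in enumerate(lines, start=2 if header else 1):
        fields = line.split(delimiter)
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(
                f"{path}:{lineno}: expected >=2 {delimiter!r}-separated fields, got {line!r}"
            )
        pair = (fields[0].strip(), fields[1].strip())
        if pair in pairs:
            dups += 1
        else:
            pairs.add(pair)
    if dups:
        warnings.warn(f"{path}: dropped {dups} duplicate pair(s)", stacklevel=2)
    return AssociationTable(source_type, target_type, frozenset(pairs), dups)


class HeteroGraph:
    """Undirected heterogeneous graph with type-partitioned adjacency.

    Stores the node set V, the typed edge set E and the type map as one
    structure: for every node the neighbor set is partitioned by neighbor
    type so meta-path walks can restrict transitions to one type in O(1).
    """

    def __init__(self) -> None:
        self._adj: dict[NodeRef, dict[str, set[NodeRef]]] = {}
        self._edge_layers: set[frozenset[str]] = set()

    # -- construction -----------------------------------------------------

    def add_node(self, node: NodeRef) -> None:
        self._adj.setdefault(node, {t: set() for t in NODE_TYPES})

    def add_edge(self, u: NodeRef, v: NodeRef) -> None:
        if u.node_type == v.node_type:
            raise GraphError(f"within-type edge rejected: {u} -- {v}")
        self.add_node(u)
        self.add_node(v)
        self._adj[u][v.node_type].add(v)
        self._adj[v][u.node_type].add(u)
        self._edge_layers.add(frozenset((u.node_type, v.node_type)))

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> frozenset[NodeRef]:
        return frozenset(self._adj)

    def nodes_of_type(self, t: str) -> list[NodeRef]:
        _check_type(t)
        return sorted(n for n in self._adj if n.node_type == t)

    def has_node(self, node: NodeRef) -> bool:
        return node in self._adj

    def has_edge_layer(self, t1: str, t2: str) -> bool:
        return frozenset((t1, t2)) in self._edge_layers

    def neighbors_of_type(self, node: NodeRef, t: str) -> frozenset[NodeRef]:
        """Adjacent nodes of type ``t``; empty set allowed, unknown node is an error."""
        _check_type(t)
        if node not in self._adj:
            raise GraphError(f"unknown node {node}")
        return frozenset(self._adj[node][t])

    def degree(self, node: NodeRef) -> int:
        if node not in self._adj:
            raise GraphError(f"unknown node {node}")
        return sum(len(s) for s in self._adj[node].values())

    def edges(self) -> Iterator[tuple[NodeRef, NodeRef]]:
        """Each undirected edge once, with endpoints in sorted order."""
        seen = set()
        for u in sorted(self._adj):
            for nbrs in self._adj[u].values():
                for v in nbrs:
                    e = tuple(sorted((u, v)))
                    if e not in seen:
                        seen.add(e)
                        yield e

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HeteroGraph):
            return NotImplemented
        return self._adj == other._adj

    # -- I/O ---------------------------------------------------------------

    def dump_edges(self, path: str | Path) -> None:
        """Write a 4-column TSV: source_type, source_id, target_type, target_id."""
        with Path(path).open("w") as fh:
            for u, v in self.edges():
                fh.write(f"{u.node_type}\t{u.identifier}\t{v.node_type}\t{v.identifier}\n")

    @classmethod
    def from_edge_dump(cls, path: str | Path) -> "HeteroGraph":
        g = cls()
        with Path(path).open() as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 fields")
                g.add_edge(NodeRef(fields[0], fields[1]), NodeRef(fields[2], fields[3]))
        return g


def build_graph(tables: Iterable[AssociationTable]) -> HeteroGraph:
    """Union the bipartite association tables into one heterogeneous graph.

    The node set is the union of all endpoint identifiers with their types;
    adjacency is symmetric. An empty table list is an error.
    """
    tables = list(tables)
    if not tables:
        raise ConfigError("build_graph requires at least one association table")
    g = HeteroGraph()
    for table in tables:
        for u, v in table.edges():
            g.add_edge(u, v)
    return g
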