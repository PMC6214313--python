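"""Patch-adjacency graphs: construction, components, cut-node detection.

A corridor landscape is modelled as a simple undirected graph whose nodes
are homogeneous land patches and whose edges record spatial adjacency
between patches.  Connectivity analysis on this graph — connected
components and articulation points ("cut nodes") — is the first stage of
the critical-patch ranking pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Hashable, Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "GraphInputError",
    "MissingNodeError",
    "PatchGraph",
    "ComponentPartition",
    "build_graph",
    "connected_components",
    "find_cut_nodes",
]


class GraphInputError(ValueError):
    """Raised for malformed graph input (self-loops, undeclared endpoints)."""


class MissingNodeError(KeyError):
    """Raised when an operation references a node absent from the graph."""


def _node_key(v: Hashable) -> tuple[str, Any]:
    # total order across mixed id types: group by type name, then value
    return (type(v).__name__, v)


@dataclass(frozen=True)
class PatchGraph:
    """Simple undirected graph of land patches.

    Wraps a :class:`networkx.Graph` whose node insertion order is sorted,
    so every traversal (and hence every downstream report) is reproducible
    regardless of input order.
    """

    nx_graph: nx.Graph
    node_attrs: Mapping[Hashable, Mapping[str, Any]] = field(default_factory=dict)

    @property
    def node_ids(self) -> list[Hashable]:
        return list(self.nx_graph.nodes)

    @property
    def edges(self) -> list[tuple[Hashable, Hashable]]:
        return list(self.nx_graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.nx_graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.nx_graph.number_of_edges()

    def __contains__(self, v: Hashable) -> bool:
        return v in self.nx_graph

    def degree(self, v: Hashable) -> int:
        if v not in self.nx_graph:
            raise MissingNodeError(v)
        return self.nx_graph.degree[v]

    def subgraph(self, nodes: Iterable[Hashable]) -> "PatchGraph":
        return PatchGraph(nx.Graph(self.nx_graph.subgraph(nodes)), self.node_attrs)


@dataclass(frozen=True)
class ComponentPartition:
    """Disjoint connected blocks covering all nodes, largest first."""

    blocks: tuple[frozenset, ...]

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(b) for b in self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)

    def block_of(self, v: Hashable) -> frozenset:
        for b in self.blocks:
            if v in b:
                return b
        raise MissingNodeError(v)


def build_graph(
    edge_records: Iterable[tuple[Hashable, Hashable]],
    node_records: Mapping[Hashable, Mapping[str, Any]] | Iterable[Hashable] | None = None,
) -> PatchGraph:
    """Build a :class:`PatchGraph` from an edge list and optional node records.

    Duplicate edges (in either orientation) collapse to one; self-loops are
    rejected.  When ``node_records`` is given, every edge endpoint must be
    declared there, and declared nodes without edges become isolated nodes.

    Parameters
    ----------
    edge_records
        Unordered id pairs.
    node_records
        Either a mapping ``id -> attribute dict`` or a plain iterable of ids.

    Raises
    ------
    GraphInputError
        On a self-loop (reporting the offending id) or an edge endpoint not
        present in ``node_records``.
    """
    attrs: dict[Hashable, Mapping[str, Any]] = {}
    declared: set | None = None
    if node_records is not None:
        if isinstance(node_records, Mapping):
            attrs = dict(node_records)
            declared = set(attrs)
        else:
            declared = set(node_records)
            attrs = {v: {} for v in declared}

    edge_set: set[tuple] = set()
    nodes: set = set(declared or ())
    for i, (u, v) in enumerate(edge_records):
        if u == v:
            raise GraphInputError(f"self-loop on node {u!r} (edge record {i})")
        if declared is not None:
            for w in (u, v):
                if w not in declared:
                    raise GraphInputError(
                        f"edge record {i} references undeclared node {w!r}"
                    )
        nodes.update((u, v))
        edge_set.add(tuple(sorted((u, v), key=_node_key)))

    g = nx.Graph()
    g.add_nodes_from(sorted(nodes, key=_node_key))
    g.add_edges_from(sorted(edge_set, key=lambda e: (_node_key(e[0]), _node_key(e[1]))))
    return PatchGraph(g, attrs)


def connected_components(g: PatchGraph) -> ComponentPartition:
    """Partition the graph into connected components.

    Blocks are ordered by descending size, ties broken by the smallest
    contained id, so the partition is stable under input reordering.
    """
    blocks = [frozenset(c) for c in nx.connected_components(g.nx_graph)]
    blocks.sort(key=lambda b: (-len(b), min(_node_key(v) for v in b)))
    return ComponentPartition(tuple(blocks))


def find_cut_nodes(g: PatchGraph) -> set:
    """Return the articulation points of the graph.

    A cut node is a node whose removal splits its connected component into
    two or more smaller components.  Isolated nodes and leaves are never
    cut nodes; detection runs in linear time (Hopcroft–Tarjan via networkx).
    """
    return set(nx.articulation_points(g.nx_graph))
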