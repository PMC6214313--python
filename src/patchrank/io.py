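"""Graph interchange: edge-list CSV and GraphML."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Hashable, Mapping

import networkx as nx

from .graph import GraphInputError, PatchGraph, build_graph

__all__ = ["read_edge_csv", "write_edge_csv", "read_graphml", "write_graphml"]

_HEADERS = {"source", "target", "from", "to", "u", "v", "node1", "node2"}


def _coerce(token: str) -> Hashable:
    """Parse integer-looking ids as ints so CSV round-trips numeric ids."""
    try:
        return int(token)
    except ValueError:
        return token


def read_edge_csv(
    path: str | Path,
    node_records: Mapping[Hashable, Mapping] | None = None,
) -> PatchGraph:
    """Read a two-column edge list (optional header) into a graph.

    Malformed rows raise :class:`GraphInputError` with the line number.
    """
    edges = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and row[0].strip().lower() in _HEADERS:
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                raise GraphInputError(f"{path}:{lineno}: expected two id columns")
            edges.append((_coerce(row[0].strip()), _coerce(row[1].strip())))
    try:
        return build_graph(edges, node_records)
    except GraphInputError as exc:
        raise GraphInputError(f"{path}: {exc}") from exc


def write_edge_csv(g: PatchGraph, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target"])
        for u, v in g.edges:
            w.writerow([u, v])


def read_graphml(path: str | Path) -> PatchGraph:
    raw = nx.read_graphml(path)
    attrs = {_coerce(str(v)): dict(d) for v, d in raw.nodes(data=True)}
    edges = [(_coerce(str(u)), _coerce(str(v))) for u, v in raw.edges()]
    return build_graph(edges, attrs)


def write_graphml(g: PatchGraph, path: str | Path) -> None:
    out = nx.Graph()
    for v in g.node_ids:
        out.add_node(v, **dict(g.node_attrs.get(v, {})))
    out.add_edges_from(g.edges)
    nx.write_graphml(out, path)
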