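"""Single-node removal simulation and fragmentation metrics.

Removing a cut node v from its connected component G' = (V', E') splits it
into n >= 2 components with sizes |V'_0| >= |V'_1| >= ... >= |V'_{n-1}|.
Two attributes summarise the damage:

* additional component count  C_A(v) = n - 1
* second-size                 C_S(v) = |V'_1|

C_S = 1 flags removals that only detach leaf nodes — in corridor maps these
leaves are typically enclaves (patches surrounded by another patch, often
artifacts of the source data) rather than genuine corridor interruptions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable

import networkx as nx
import pandas as pd

from .graph import MissingNodeError, PatchGraph, _node_key

__all__ = ["SplitResult", "simulate_removal", "removal_metrics_all"]


@dataclass(frozen=True)
class SplitResult:
    """Outcome of removing one node from its host component.

    ``second_size`` is defined only for cut nodes (``is_cut``); for a
    non-cut node it is ``None`` rather than 0 so that non-cut nodes cannot
    silently enter a percentile population.
    """

    node_id: Hashable
    host_component_size: int
    split_sizes: tuple[int, ...]  # descending

    @property
    def additional_count(self) -> int:
        return len(self.split_sizes) - 1

    @property
    def second_size(self) -> int | None:
        return self.split_sizes[1] if self.is_cut else None

    @property
    def is_cut(self) -> bool:
        return len(self.split_sizes) >= 2

    def __post_init__(self) -> None:
        if sum(self.split_sizes) != self.host_component_size - 1:
            raise AssertionError(
                f"split sizes {self.split_sizes} do not sum to "
                f"{self.host_component_size - 1} for node {self.node_id!r}"
            )


def simulate_removal(g: PatchGraph, v: Hashable) -> SplitResult:
    """Simulate deleting ``v`` and report the resulting component sizes.

    The search is restricted to the component hosting ``v``; the graph is
    not modified.  A single-node host yields an empty split.
    """
    if v not in g:
        raise MissingNodeError(v)
    host = nx.node_connected_component(g.nx_graph, v)
    remainder = g.nx_graph.subgraph(host - {v})
    sizes = sorted((len(c) for c in nx.connected_components(remainder)), reverse=True)
    return SplitResult(node_id=v, host_component_size=len(host), split_sizes=tuple(sizes))


def removal_metrics_all(g: PatchGraph, cut_nodes: Iterable[Hashable]) -> pd.DataFrame:
    """Tabulate C_A and C_S for every node in ``cut_nodes``.

    Returns one row per node with columns ``node_id``, ``C_A``, ``C_S``,
    ``host_component_size``, ``is_cut``, sorted by node id.  Nodes that are
    not actually cut nodes get ``C_A = 0`` and a missing ``C_S``.
    """
    rows = []
    for v in cut_nodes:
        r = simulate_removal(g, v)
        rows.append(
            {
                "node_id": r.node_id,
                "C_A": r.additional_count,
                "C_S": r.second_size,
                "host_component_size": r.host_component_size,
                "is_cut": r.is_cut,
            }
        )
    df = pd.DataFrame(
        rows, columns=["node_id", "C_A", "C_S", "host_component_size", "is_cut"]
    )
    if len(df):
        df = df.sort_values("node_id", key=lambda s: s.map(_node_key)).reset_index(
            drop=True
        )
    return df
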