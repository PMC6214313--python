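"""Betweenness centrality with pair-count normalization.

Raw betweenness of a node v is the sum over unordered node pairs (s, t),
s != v != t, of sigma_st(v) / sigma_st, where sigma_st counts shortest
paths between s and t and sigma_st(v) those passing through v.  The raw
value is normalized to [0, 1] by the number of node pairs excluding v,
(N - 1)(N - 2) / 2.

By default N is the size of the node's own connected component, which is
the meaningful population in a landscape graph made of many disjoint
corridors: with a global N every node in a small component would be pinned
near zero regardless of its structural role.  A ``scope="global"`` override
(N = |V| of the whole graph) is available for sensitivity checks.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .graph import PatchGraph, connected_components

__all__ = ["betweenness"]


def betweenness(g: PatchGraph, scope: str = "component") -> pd.DataFrame:
    """Raw and normalized betweenness for every node.

    Parameters
    ----------
    g
        Patch graph (unweighted, undirected).
    scope
        ``"component"`` (default) normalizes each node by its component
        size; ``"global"`` normalizes by the whole node count.

    Returns
    -------
    DataFrame with columns ``node_id``, ``raw``, ``normalized``,
    ``component_size``, one row per node in deterministic (sorted) order.
    Components with fewer than 3 nodes have no valid pair population and
    get normalized value 0.
    """
    if scope not in ("component", "global"):
        raise ValueError(f"scope must be 'component' or 'global', got {scope!r}")

    raw = nx.betweenness_centrality(g.nx_graph, normalized=False)

    comp_size = {}
    for block in connected_components(g).blocks:
        for v in block:
            comp_size[v] = len(block)

    n_global = g.n_nodes
    rows = []
    for v in g.node_ids:  # insertion order is sorted -> reproducible
        n = comp_size[v] if scope == "component" else n_global
        pairs = (n - 1) * (n - 2) / 2
        rows.append(
            {
                "node_id": v,
                "raw": raw[v],
                "normalized": raw[v] / pairs if pairs > 0 else 0.0,
                "component_size": comp_size[v],
            }
        )
    return pd.DataFrame(rows, columns=["node_id", "raw", "normalized", "component_size"])
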