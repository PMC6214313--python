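"""Shared fixtures and independent brute-force oracles.

The oracles here work on plain node/edge collections with textbook
algorithms (flood fill, delete-and-recount, BFS path counting) so they
share no code path with the package implementations they check.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest


def adjacency(nodes, edges):
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def flood_components(nodes, edges):
    """Connected components by breadth-first flood fill."""
    adj = adjacency(nodes, edges)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        block, queue = set(), deque([start])
        seen.add(start)
        while queue:
            u = queue.popleft()
            block.add(u)
            for w in adj[u]:
                if w not in seen:
                    seen.add(w)
                    queue.append(w)
        comps.append(frozenset(block))
    return comps


def brute_cut_nodes(nodes, edges):
    """Delete each node in turn and recount components."""
    base = len(flood_components(nodes, edges))
    cut = set()
    for v in nodes:
        rest_nodes = [u for u in nodes if u != v]
        rest_edges = [(a, b) for a, b in edges if v not in (a, b)]
        # removing an isolated node lowers the count; cut nodes raise it
        if len(flood_components(rest_nodes, rest_edges)) > base:
            cut.add(v)
    return cut


def brute_split_sizes(nodes, edges, v):
    """Component sizes of v's host component after deleting v."""
    host = next(c for c in flood_components(nodes, edges) if v in c)
    rest = host - {v}
    rest_edges = [(a, b) for a, b in edges if a in rest and b in rest]
    return sorted((len(c) for c in flood_components(sorted(rest), rest_edges)),
                  reverse=True)


def brute_betweenness(nodes, edges):
    """Raw betweenness via BFS distances and shortest-path counting.

    sigma_st(v) = sigma_sv * sigma_vt when dist(s,v) + dist(v,t) = dist(s,t).
    """
    adj = adjacency(nodes, edges)

    def bfs(src):
        dist = {src: 0}
        sigma = {src: 1}
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    sigma[w] = 0
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
        return dist, sigma

    info = {v: bfs(v) for v in nodes}
    raw = {v: 0.0 for v in nodes}
    node_list = list(nodes)
    for i, s in enumerate(node_list):
        dist_s, sig_s = info[s]
        for t in node_list[i + 1 :]:
            if t not in dist_s:
                continue
            d = dist_s[t]
            total = sig_s[t]
            for v in nodes:
                if v in (s, t) or v not in dist_s:
                    continue
                dist_v, sig_v = info[v]
                if t in dist_v and dist_s[v] + dist_v[t] == d:
                    raw[v] += sig_s[v] * sig_v[t] / total
    return raw


def random_edge_list(rng: np.random.Generator, n: int, p: float):
    """Erdos-Renyi style node/edge lists with integer ids."""
    nodes = list(range(n))
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    return nodes, edges


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
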