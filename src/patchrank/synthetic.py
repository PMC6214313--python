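"""Seeded generators of corridor-like graphs and toy polygon landscapes.

Real corridor networks extracted from land-cover maps have a recognizable
topology: each connected component is a corridor (or a braid of corridors)
whose ends anchor on protected sites, with chain-like backbones of patches,
dense patch clusters at the site boundaries, dangling leaf patches
(enclaves, often data artifacts), and occasional redundant adjacencies that
close cycles.  The generators here emulate exactly that shape and emit a
ground truth — declared cut nodes with their expected fragmentation
metrics, declared adjacency and exact site distances — computed purely from
the construction bookkeeping, so every downstream stage can be tested
against values it did not itself produce.

Determinism: a single integer seed drives one ``numpy`` Generator; all
stochastic choices are drawn from it in a fixed documented order (per
component: leaf attachments in node order, then shortcut edges in skeleton
order), so the same spec and seed always give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import numpy as np

from .graph import PatchGraph, build_graph

__all__ = [
    "SyntheticSpec",
    "ExpectedSplit",
    "GroundTruth",
    "generate_corridor_graph",
    "generate_grid_landscape",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the corridor-landscape generator.

    Defaults describe a mid-sized corridor system: a handful of disjoint
    corridors, backbones of ~12 patches, 3-patch site-anchor cliques at both
    ends, a 20% chance of an enclave leaf per patch and no redundant edges
    (pure tree-of-blocks skeleton, the worst case for cut-node abundance).
    """

    n_components: int = 5
    backbone_length: int = 12
    anchor_clusters: int = 2          # 0, 1 or 2 cliques at the backbone ends
    anchor_size: int = 3              # clique size, >= 3
    leaf_probability: float = 0.2     # per skeleton node, one enclave leaf
    redundancy_probability: float = 0.0  # per bypass candidate, adds a cycle
    seed: int = 0
    # grid mode
    grid_rows: int = 3
    grid_cols: int = 8
    prune_probability: float = 0.0    # per interior grid cell

    def __post_init__(self) -> None:
        if not 0 <= self.leaf_probability <= 1:
            raise ValueError("leaf_probability must be in [0, 1]")
        if not 0 <= self.redundancy_probability <= 1:
            raise ValueError("redundancy_probability must be in [0, 1]")
        if not 0 <= self.prune_probability <= 1:
            raise ValueError("prune_probability must be in [0, 1]")
        if self.backbone_length < 1:
            raise ValueError("backbone_length must be >= 1")
        if self.anchor_clusters not in (0, 1, 2):
            raise ValueError("anchor_clusters must be 0, 1 or 2")
        if self.anchor_clusters and self.anchor_size < 3:
            raise ValueError("anchor_size must be >= 3")


@dataclass(frozen=True)
class ExpectedSplit:
    """Construction-time expectation for one cut node's removal."""

    additional_count: int
    second_size: int


@dataclass(frozen=True)
class GroundTruth:
    """Declared properties of a generated landscape.

    ``cut_nodes`` maps each declared cut node to its expected split, or to
    ``None`` when the metrics are not pinned down by the construction.
    ``exhaustive`` is True when ``cut_nodes`` lists *every* cut node of the
    emitted graph (guaranteed at redundancy 0).
    """

    cut_nodes: dict[Hashable, ExpectedSplit | None]
    exhaustive: bool
    adjacency: tuple[tuple[Hashable, Hashable], ...] = ()
    site_distances: dict[Hashable, float] = field(default_factory=dict)


def generate_corridor_graph(spec: SyntheticSpec) -> tuple[PatchGraph, GroundTruth]:
    """Generate a corridor-shaped graph with declared cut-node ground truth.

    Each component is a chain backbone optionally capped by anchor cliques
    (site boundaries), with Bernoulli enclave leaves on skeleton nodes and
    Bernoulli shortcut edges that bypass skeleton articulation.  Node ids
    are consecutive integers, mirroring the progressive patch numbering of
    GIS-derived graphs.
    """
    rng = np.random.default_rng(spec.seed)
    edges: list[tuple[int, int]] = []
    nodes: list[int] = []
    truth: dict[int, ExpectedSplit | None] = {}
    next_id = 0

    def fresh() -> int:
        nonlocal next_id
        v = next_id
        next_id += 1
        nodes.append(v)
        return v

    for _ in range(spec.n_components):
        backbone = [fresh() for _ in range(spec.backbone_length)]
        edges += list(zip(backbone, backbone[1:]))

        cliques: list[list[int]] = []
        for c in range(spec.anchor_clusters):
            members = [fresh() for _ in range(spec.anchor_size)]
            edges += [
                (a, b) for i, a in enumerate(members) for b in members[i + 1 :]
            ]
            junction = members[0]
            edges.append((junction, backbone[0] if c == 0 else backbone[-1]))
            cliques.append(members)

        skeleton = backbone + [v for cl in cliques for v in cl]
        # one enclave leaf per skeleton node, Bernoulli(leaf_probability)
        leaves: dict[int, int] = {}
        for u in skeleton:
            if rng.random() < spec.leaf_probability:
                leaf = fresh()
                edges.append((u, leaf))
                leaves[u] = leaf

        # bypass candidates: for every skeleton node on the chain, the edge
        # joining its two chain neighbours (clique junctions are bypassed
        # through the second clique member), so redundancy 1 makes the whole
        # skeleton biconnected
        left = {b: a for a, b in zip(backbone, backbone[1:])}
        right = {a: b for a, b in zip(backbone, backbone[1:])}
        if cliques:
            left[backbone[0]] = cliques[0][0]
            right[cliques[0][0]] = backbone[0]
            left[cliques[0][0]] = cliques[0][1]
        if len(cliques) == 2:
            right[backbone[-1]] = cliques[1][0]
            left[cliques[1][0]] = backbone[-1]
            right[cliques[1][0]] = cliques[1][1]
        bypass_candidates = [
            (left[u], right[u])
            for u in sorted(left)
            if u in right and left[u] != right[u]
        ]
        added_shortcut = False
        for a, b in bypass_candidates:
            if rng.random() < spec.redundancy_probability:
                if (a, b) not in edges and (b, a) not in edges:
                    edges.append((a, b))
                    added_shortcut = True

        _declare_component_truth(
            truth,
            backbone,
            cliques,
            leaves,
            skeleton_cut_known=not added_shortcut,
        )

    g = build_graph(edges, nodes)
    exhaustive = spec.redundancy_probability == 0.0
    return g, GroundTruth(cut_nodes=truth, exhaustive=exhaustive)


def _declare_component_truth(
    truth: dict[int, ExpectedSplit | None],
    backbone: list[int],
    cliques: list[list[int]],
    leaves: dict[int, int],
    skeleton_cut_known: bool,
) -> None:
    """Record cut nodes and expected splits for one generated component.

    With no shortcut edges the skeleton is a tree of blocks and every split
    size follows from counting nodes on each side; with shortcuts only the
    leaf-host nodes are still guaranteed cut nodes, and their metrics are
    left undeclared (``None``).
    """
    c_sizes = [len(cl) for cl in cliques]
    n_leaves = len(leaves)
    host = len(backbone) + sum(c_sizes) + n_leaves
    L = len(backbone)

    def leaves_on(nodes_subset: list[int]) -> int:
        return sum(1 for u in nodes_subset if u in leaves)

    if not skeleton_cut_known:
        for u in leaves:
            truth[u] = None
        return

    # backbone node i (0-based): left side = clique A + earlier chain,
    # right side = later chain + clique B, plus its own leaf
    for i, u in enumerate(backbone):
        left_nodes = backbone[:i] + (cliques[0] if cliques else [])
        right_nodes = backbone[i + 1 :] + (cliques[1] if len(cliques) == 2 else [])
        pieces = [
            n for n in (
                len(left_nodes) + leaves_on(left_nodes),
                len(right_nodes) + leaves_on(right_nodes),
            ) if n > 0
        ]
        if u in leaves:
            pieces.append(1)
        if len(pieces) >= 2:
            sizes = sorted(pieces, reverse=True)
            truth[u] = ExpectedSplit(len(pieces) - 1, sizes[1])

    # clique members
    for ci, cl in enumerate(cliques):
        junction, rest = cl[0], cl[1:]
        # junction: clique side stays connected through the remaining members
        clique_side = len(rest) + leaves_on(rest)
        other_side = host - 1 - clique_side - (1 if junction in leaves else 0)
        pieces = [n for n in (clique_side, other_side) if n > 0]
        if junction in leaves:
            pieces.append(1)
        if len(pieces) >= 2:
            sizes = sorted(pieces, reverse=True)
            truth[junction] = ExpectedSplit(len(pieces) - 1, sizes[1])
        # non-junction members are cut only if they carry a leaf
        for u in rest:
            if u in leaves:
                truth[u] = ExpectedSplit(1, 1)


def generate_grid_landscape(
    spec: SyntheticSpec,
) -> tuple["PatchLayer", "SiteSet", GroundTruth]:
    """Generate a toy polygon landscape: a grid corridor between two sites.

    Unit-square patches tile a ``grid_rows x grid_cols`` strip whose left
    and right edges touch two rectangular protected sites.  Interior cells
    (columns other than the first and last) are pruned independently with
    ``prune_probability``.  The ground truth declares the rook adjacency of
    the kept cells and each cell's exact boundary distance to the nearest
    site, both from integer bookkeeping, independent of any geometry code.
    """
    from shapely.geometry import box

    from .spatial import PatchLayer, SiteSet

    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid_rows, spec.grid_cols
    kept: dict[tuple[int, int], int] = {}
    polygons, ids, landuse = [], [], []
    pid = 0
    for r in range(rows):
        for c in range(cols):
            interior = 0 < c < cols - 1
            if interior and rng.random() < spec.prune_probability:
                continue
            kept[(r, c)] = pid
            polygons.append(box(c, r, c + 1, r + 1))
            ids.append(pid)
            landuse.append("corridor")
            pid += 1

    adjacency = []
    for (r, c), i in sorted(kept.items()):
        for dr, dc in ((0, 1), (1, 0)):  # rook neighbours, forward only
            j = kept.get((r + dr, c + dc))
            if j is not None:
                adjacency.append((i, j))

    # sites flank the strip: x in [-2, 0] and [cols, cols + 2]
    sites = SiteSet(
        ids=("site_west", "site_east"),
        polygons=(box(-2, 0, 0, rows), box(cols, 0, cols + 2, rows)),
    )
    distances = {
        i: float(min(c, cols - 1 - c)) for (r, c), i in sorted(kept.items())
    }

    layer = PatchLayer(ids=tuple(ids), polygons=tuple(polygons),
                       land_use=tuple(landuse))
    truth = GroundTruth(
        cut_nodes={},
        exhaustive=False,
        adjacency=tuple(adjacency),
        site_distances=distances,
    )
    return layer, sites, truth
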