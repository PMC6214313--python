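# Methods

## Model

A corridor landscape is a simple undirected graph G = (V, E): nodes are
land patches homogeneous in land-use code, edges are spatial adjacency.
The graph is unweighted and undirected — adjacency either exists or it
does not, and multi-adjacency in the source data collapses to a single
edge. Isolated patches form size-1 components and can never be cut nodes.

The ranking procedure is five stages: build the graph; census connected
components; detect cut nodes (and attach site distances); simulate each
single cut-node removal, recording the additional component count
C_A = n − 1 and the second-size C_S = |V′₁| of the resulting split (sizes
ordered descending); convert metrics to strictly-less percentile scores
and sum them into the combined score. Simultaneous removal of several cut
nodes is out of scope.

C_S is defined only for cut nodes (n ≥ 2 guarantees |V′₁| exists);
non-cut nodes are flagged with a missing value rather than assigned 0, so
they cannot silently enter a percentile population. Split sizes always
satisfy Σ|V′ₖ| = |V′| − 1, which both the tests and the removal code check.

## Percentile scoring

The percentile of x over the population of all cut nodes is
100 × (# values strictly below x) / population size. This choice makes the
minimum score exactly 0 (no contribution to priorities), keeps 100
unattainable, and gives equal raw values equal scores; near the top of the
distribution it deliberately compresses differences between extreme raw
values — the goal is to flag abnormally high values, not to weight by them.

Two conventions are pinned down by published worked rows:

- the percentile **population is global** (all cut nodes across all
  components, not per component): per-node percentiles in the worked
  component equal the global histogram scores;
- the combined score sums **unrounded** percentiles and rounds only at
  report time: one published row prints 103.16 where its 2-dp addends sum
  to 103.17.

A distribution built from a truncated histogram excerpt must declare
`complete_below`; scores beyond that point raise instead of silently using
elided counts.

Ranking is by descending combined score; ties are ordered by higher
normalized betweenness, then smaller node id (a total order is needed for
a definite priority list), and tied combined scores share the better rank
position. An optional noise filter (off by default) drops cut nodes with
C_S = 1 — the enclave signature — before reporting.

## Betweenness normalization

Raw betweenness (Brandes, via networkx) is normalized by the pair count
(N − 1)(N − 2)/2. N defaults to the size of the node's **own connected
component**: corridor graphs are highly disconnected, and with a global N
the maximum achievable value in any but the largest component would be
orders of magnitude below 1, destroying comparability — published
component-level values (e.g. 0.171 for a node of a 298-node component in a
6995-node graph) are only attainable under component-level N. A
`scope="global"` override exists for sensitivity checks. Components with
fewer than 3 nodes have an empty pair population and get 0. Betweenness is
a comparison column by default, not a score component; the reported
Pearson/Spearman correlation between combined score and betweenness
quantifies how differently they rank.

## Spatial adapter

Geometry runs on projected planar coordinates through shapely; layers are
plain GeoJSON (no GeoPackage read, no reprojection — inputs must share one
projected CRS, and declared CRS names are compared when present). At
corridor scale, projection distortion is negligible relative to patch
size. Geometry validity is repaired (make_valid) before any predicate;
unrepairable features error with their ids rather than being dropped.

Adjacency defaults to **rook** contiguity (shared boundary of positive
length, DE-9IM boundary∩boundary dimension 1): corner-touching patches do
not form a plausible corridor through a single point. Queen contiguity
(corners included) is available by flag and always yields a superset of
the rook edges. Site distance is Euclidean boundary-to-boundary
(`shapely.distance`), 0 for touching or overlapping geometries. A sliver
filter (area threshold, default 0 = keep all) can drop post-overlay
fragments, a known source of enclave noise.

## Synthetic landscapes

The corridor generator emulates the topology of GIS-derived corridor
graphs: per component, a chain backbone of corridor patches capped by
anchor cliques (size ≥ 3, internally biconnected so articulation happens
at the corridor, not inside the site boundary), Bernoulli enclave leaves
(one per skeleton node), and Bernoulli shortcut edges that bypass skeleton
nodes and close cycles. Defaults — 5 components, backbone 12, two 3-patch
anchors, leaf probability 0.2, redundancy 0 — describe a mid-sized
corridor system in the worst case for cut-node abundance (a pure tree of
blocks). One integer seed drives a single numpy Generator; draws occur in
a fixed documented order, so identical specs give byte-identical output.

Ground truth is computed purely from construction bookkeeping (side sizes
along the skeleton), never by running the detection code. At redundancy 0
the declared cut-node set is exhaustive and carries exact expected C_A and
C_S; at redundancy > 0 only the leaf-host nodes — cut regardless of any
shortcut — are declared, without metrics, giving the subset guarantee the
round-trip tests rely on.

The grid generator builds unit-square corridors between two flanking
rectangular sites, with optional pruning of interior cells, and declares
rook adjacency and exact site distances from integer bookkeeping,
independent of the geometry code it is used to test.

What the generators do **not** emulate: irregular patch shapes and areas,
realistic land-use mosaics, resistance-surface-based corridor selection,
and spatially autocorrelated noise. Passing tests therefore demonstrate
correctness of the graph analysis and scoring on corridor-shaped
topologies, not ecological realism of any particular landscape.

## Numerical and design choices

- Deterministic orderings everywhere: node insertion sorted by id, blocks
  by (size desc, smallest id), reports with fixed column order and
  rounding (2 dp for scores, 5 dp for normalized betweenness and
  percentile histograms) — reruns are byte-identical.
- Raw betweenness uses Brandes accumulation in a fixed traversal order;
  agreement with a path-counting oracle is checked to 1e−9.
- Correlation: product-moment Pearson and mid-rank Spearman (scipy); zero
  variance in either variable is reported as a degenerate flag, not an
  exception.
- Problem sizes in the test and acceptance runs (random graphs n ≤ 60 for
  cut-node oracles, n ≤ 40 for betweenness oracles, 200 graphs per batch,
  generator defaults ~100 nodes) are chosen so the brute-force oracles
  remain exact references while the whole suite runs in seconds.
- The distance percentile population is the same global cut-node set as
  the other metrics; when no site layer is given, requesting the D metric
  fails before any computation, and the default metric set degrades to
  (C_A, C_S).

## Known limitations

- Single-node removal only; no simultaneous multi-node scenarios.
- Unweighted, undirected connectivity; no edge (bridge) ranking, no
  weighted or approximate betweenness.
- No raster/resistance preprocessing: corridor selection is upstream of
  this tool's inputs.
- GeoJSON only for vector I/O, with no CRS transformation.
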