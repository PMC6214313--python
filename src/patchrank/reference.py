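"""Reference distributions from a regional corridor-network study.

These constants describe the corridor network of the Metropolitan City of
Cagliari (southern Sardinia): a patch-adjacency graph of 6995 nodes and
17464 edges in 18 connected components, of which 569 nodes are cut nodes.
They serve as a published ground truth for the percentile-scoring
arithmetic — reconstructing the percentile columns from the occurrence
histograms must reproduce the printed values exactly — and as realistic
metric distributions for examples.

``SECOND_SIZE_HISTOGRAM_PREFIX`` is an excerpt: the published table prints
only the low end (plus the two largest values, 764 and 810); scores are
therefore computable only for values whose strictly-smaller values all lie
in the prefix.
"""

from __future__ import annotations

N_NODES = 6995
N_EDGES = 17464
N_COMPONENTS = 18
N_CUT_NODES = 569

#: Sizes of the connected components, largest first.
COMPONENT_SIZES = (
    2464, 1177, 975, 479, 656, 298, 224, 159, 62, 57, 47, 19, 13, 12, 7, 6, 7, 3,
)

#: Occurrences of the additional component count C_A over all 569 cut nodes.
COMPONENT_COUNT_HISTOGRAM = {
    1: 372, 2: 108, 3: 45, 4: 18, 5: 10, 6: 6, 7: 2, 8: 2, 9: 2,
    11: 1, 12: 1, 17: 1, 35: 1,
}

#: Printed prefix of the second-size (C_S) histogram; complete for values
#: below SECOND_SIZE_COMPLETE_BELOW only.  The published maxima are 764
#: and 810 (one occurrence each); values between 12 and 764 were elided.
SECOND_SIZE_HISTOGRAM_PREFIX = {
    1: 338, 2: 50, 3: 17, 4: 15, 5: 9, 6: 10, 7: 10, 8: 5, 9: 5,
    10: 6, 11: 3, 12: 3,
}
SECOND_SIZE_COMPLETE_BELOW = 13
SECOND_SIZE_MAXIMA = (764, 810)

#: Worked ranking rows for the sixth-largest component (298 nodes, 13 cut
#: nodes): per node the raw value and percentile of C_A, C_S and site
#: distance D, the printed combined score, and the normalized betweenness
#: with its within-component rank.
WORKED_COMPONENT_SIZE = 298
WORKED_ROWS = [
    # node, C_A, C_A_pctl, C_S, C_S_pctl, D, D_pctl, combined, C_B_norm, C_B_rank
    (1949, 5, 95.43, 21, 85.06, 532.0, 21.62, 202.11, 0.17130, 2),
    (6884, 3, 84.36, 1, 0.0, 1997.8, 45.17, 129.53, 0.06987, 5),
    (4383, 2, 65.38, 1, 0.0, 1469.3, 37.79, 103.16, 0.01674, 9),
    (6869, 1, 0.0, 2, 59.40, 1684.5, 41.48, 100.88, 0.05562, 6),
    (6889, 1, 0.0, 1, 0.0, 2855.0, 55.89, 55.89, 0.00980, 11),
    (6885, 1, 0.0, 1, 0.0, 1806.8, 43.41, 43.41, 0.00673, 13),
    (5541, 1, 0.0, 1, 0.0, 1489.6, 38.31, 38.31, 0.01513, 10),
    (5094, 1, 0.0, 1, 0.0, 1039.6, 30.40, 30.40, 0.07742, 4),
    (2712, 1, 0.0, 1, 0.0, 952.3, 28.30, 28.30, 0.19063, 1),
    (1607, 1, 0.0, 1, 0.0, 860.3, 26.36, 26.36, 0.03149, 8),
    (2638, 1, 0.0, 1, 0.0, 681.1, 23.90, 23.90, 0.08808, 3),
    (1604, 1, 0.0, 1, 0.0, 0.0, 0.0, 0.00, 0.00675, 12),
    (4579, 1, 0.0, 1, 0.0, 0.0, 0.0, 0.00, 0.04956, 7),
]

#: Combined scores are sums of *unrounded* percentiles rounded to 2 dp at
#: report time; node 4383's printed 103.16 differs from the sum of its
#: rounded addends (103.17), which pins down that convention.
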