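"""Chromosome proximity graph and force-directed embedding.

Plants two chromosome blocks whose members share a trans factor, builds
the Hellinger-weighted chromosome graph and embeds it: chromosomes of
the same block should land closer together than chromosomes of
different blocks.
"""

import itertools
import math

import numpy as np

from grpspace import (
    SimulationConfig,
    build_chromosome_graph,
    cis_trans_comparison,
    compute_mi_matrix,
    force_directed_layout,
    generate_annotation,
    generate_expression_pair,
    partition_grp,
)

blocks = [["1", "2", "3"], ["4", "5", "6"]]
config = SimulationConfig(
    n_genes=120,
    chromosome_weights={c: 1.0 for c in "123456"},
    trans_factor_groups=blocks,
    seed=7,
)
annotation = generate_annotation(config)
control, _ = generate_expression_pair(annotation, config)
collection = partition_grp(compute_mi_matrix(control), annotation)
collection.condition = "control"

graph = build_chromosome_graph(cis_trans_comparison(collection, "hellinger"))
layout = force_directed_layout(graph, seed=0)
block_of = {c: (0 if c in blocks[0] else 1) for c in "123456"}
within, between = [], []
for a, b in itertools.combinations(layout.coordinates, 2):
    (xa, ya), (xb, yb) = layout.coordinates[a], layout.coordinates[b]
    d = math.hypot(xa - xb, ya - yb)
    (within if block_of[a] == block_of[b] else between).append(d)
print(f"graph: {len(graph.nodes)} chromosomes, {graph.n_edges} directed edges")
print(f"mean layout distance within blocks:  {np.mean(within):.3f}")
print(f"mean layout distance between blocks: {np.mean(between):.3f}")
print("co-regulated chromosomes are pulled together by their similar programs")
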