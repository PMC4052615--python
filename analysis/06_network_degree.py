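#!/usr/bin/env python
"""Degree of detected target genes on a simulated interaction network.

Maps the MMPV targets of the enrichment study onto a scale-free PPI-style
network in which those genes occupy hub positions, and tests whether their
mean distinct-neighbour degree exceeds the network mean (one-tailed
one-sample t-test). Writes results/network/degree_test.tsv.
"""

import sys
from pathlib import Path

REPO = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(REPO / "src"))

import pandas as pd

from mmpv.network import degree_map, mean_degree_test, network_mean_degree
from mmpv.synth import simulate_ppi_graph

OUT = REPO / "results" / "network"
OUT.mkdir(parents=True, exist_ok=True)

genes = [f"G{i}" for i in range(12)]  # the planted MMPV targets of script 05
graph = simulate_ppi_graph(genes, n_extra=250, m=2, seed=600)
net_mean = network_mean_degree(graph)
mapped, unmapped = degree_map(genes, graph)
res = mean_degree_test(list(mapped.values()), net_mean, n_unmapped=len(unmapped))

table = pd.DataFrame(
    [
        {"feature": "ER", "mean_degree": res.mean_degree,
         "p_value": res.p_one_tailed, "n_mapped": res.n_mapped,
         "n_unmapped": res.n_unmapped},
        {"feature": "network", "mean_degree": net_mean,
         "p_value": float("nan"), "n_mapped": graph.number_of_nodes(),
         "n_unmapped": 0},
    ]
)
table.to_csv(OUT / "degree_test.tsv", sep="\t", index=False)
print(table.to_string(index=False))
print(f"one-tailed p = {res.p_one_tailed:.2e}: MMPV targets sit on "
      f"better-connected nodes than the network average")
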