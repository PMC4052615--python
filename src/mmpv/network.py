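"""Degree statistics of MMPV target genes on a protein-interaction network.

Detected target genes are mapped onto an undirected PPI network and their
mean degree is compared with the network-wide mean by a one-sample one-tailed
t-test (alternative: the gene set sits on better-connected nodes than the
network average). Genes absent from the network are missing, not isolated:
they are excluded from the test and reported as unmapped.

Degree convention: the number of distinct neighbours, so a self-loop adds 1
(not the 2 of the usual handshake count).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError
from .io_model import PPIGraph


@dataclass(frozen=True)
class DegreeTestResult:
    n_mapped: int
    n_unmapped: int
    mean_degree: float
    network_mean_degree: float
    t: float
    p_one_tailed: float


def node_degree(graph: PPIGraph, node: str) -> int:
    """Distinct-neighbour degree; a self-loop contributes 1."""
    if node not in graph:
        raise KeyError(f"node {node!r} absent from the graph")
    return len(graph.adj[node])


def network_mean_degree(graph: PPIGraph) -> float:
    """Mean distinct-neighbour degree over all nodes of the network."""
    if graph.number_of_nodes() == 0:
        raise DegenerateDataError("empty graph has no mean degree")
    return float(np.mean([len(graph.adj[v]) for v in graph.nodes]))


def degree_map(
    genes: Iterable[str], graph: PPIGraph
) -> tuple[dict[str, int], list[str]]:
    """Degrees of the genes present in the graph, plus the unmapped list."""
    mapped: dict[str, int] = {}
    unmapped: list[str] = []
    for gene in genes:
        if gene in graph:
            mapped[gene] = node_degree(graph, gene)
        else:
            unmapped.append(gene)
    return mapped, unmapped


def mean_degree_test(
    gene_degrees: Sequence[int],
    network_mean: float,
    n_unmapped: int = 0,
) -> DegreeTestResult:
    """One-sample t-test of the gene degrees against the network mean.

    One-tailed p for the alternative mean(gene degrees) > network_mean; the
    network mean enters as a fixed population constant.
    """
    degrees = np.asarray(gene_degrees, dtype=float)
    if degrees.size < 2:
        raise InsufficientDataError("need >= 2 mapped genes for a t-test")
    if float(np.var(degrees, ddof=1)) == 0.0:
        raise DegenerateDataError("zero degree variance: t-test undefined")
    res = stats.ttest_1samp(degrees, popmean=network_mean, alternative="greater")
    return DegreeTestResult(
        n_mapped=int(degrees.size),
        n_unmapped=int(n_unmapped),
        mean_degree=float(degrees.mean()),
        network_mean_degree=float(network_mean),
        t=float(res.statistic),
        p_one_tailed=float(res.pvalue),
    )


def mean_degree_test_two_sample(
    gene_degrees: Sequence[int], network_degrees: Sequence[int]
) -> DegreeTestResult:
    """Welch two-sample variant: gene degrees vs all network degrees."""
    degrees = np.asarray(gene_degrees, dtype=float)
    population = np.asarray(network_degrees, dtype=float)
    if degrees.size < 2 or population.size < 2:
        raise InsufficientDataError("need >= 2 degrees in each sample")
    res = stats.ttest_ind(
        degrees, population, equal_var=False, alternative="greater"
    )
    return DegreeTestResult(
        n_mapped=int(degrees.size),
        n_unmapped=0,
        mean_degree=float(degrees.mean()),
        network_mean_degree=float(population.mean()),
        t=float(res.statistic),
        p_one_tailed=float(res.pvalue),
    )
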