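"""Degree centrality of genes in a protein-protein interaction network.

The input is an undirected edge list of gene-id pairs (STRING-shaped).
Directed or duplicated edges are symmetrized and deduplicated and self-loops
dropped; any confidence scores present in the source table are ignored.
Degree is the number of distinct interaction partners.  The centrality
contrast asks, one-tailed, whether CNV genes (restricted to genes with at
least one interaction) have lower degree than neutral genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .ranksum import RankSumOutcome, wilcoxon_rank_sum

__all__ = [
    "InteractionNetwork",
    "build_network",
    "compute_degrees",
    "compare_centrality",
]


@dataclass(frozen=True)
class InteractionNetwork:
    """A cleaned undirected interaction graph (no self-loops, no multi-edges)."""

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(edges: Iterable[tuple[str, str]]) -> InteractionNetwork:
    """Build an interaction network from raw (possibly dirty) edge pairs."""
    g = nx.Graph()
    for a, b in edges:
        if a == b:
            continue  # self-loops carry no partner information
        g.add_edge(a, b)
    return InteractionNetwork(graph=g)


def compute_degrees(
    network: InteractionNetwork, genes: Iterable[str] | None = None
) -> dict[str, int]:
    """Distinct-neighbor degree per gene.

    When ``genes`` is given, every listed gene appears in the result; genes
    absent from the edge list get degree 0.
    """
    degrees = {node: int(d) for node, d in network.graph.degree()}
    if genes is not None:
        for g in genes:
            degrees.setdefault(g, 0)
    return degrees


def compare_centrality(
    class_genes: set[str],
    neutral_genes: set[str],
    degrees: Mapping[str, int],
    alternative: str = "less",
) -> RankSumOutcome:
    """One-tailed rank-sum contrast of node degrees between two gene groups.

    Both groups are restricted to genes with at least one interaction before
    testing, mirroring the ">= 1 interaction" condition of the analysis.
    """
    x = [degrees[g] for g in class_genes if degrees.get(g, 0) >= 1]
    y = [degrees[g] for g in neutral_genes if degrees.get(g, 0) >= 1]
    if not x or not y:
        raise ValueError("both groups must contain genes with >= 1 interaction")
    return wilcoxon_rank_sum(x, y, alternative=alternative)
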