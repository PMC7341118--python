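"""Thresholded Pearson co-expression networks and their topology.

Edges connect gene pairs whose Pearson correlation r over the chosen
samples satisfies r > threshold (positive edge) or r < −threshold
(negative edge); the inequality is strict, so |r| equal to the threshold
draws no edge.  Node degree is mapped into an importance weight through
the logistic function ω = 1/(1+e^(−degree)), which lives in [0.5, 1):
genes absent from the network default to the minimum weight 0.5.

Topology conventions (graphs here are routinely disconnected):

* average shortest path (ASP): mean shortest-path length over connected
  ordered pairs only, 0.0 when no pair is connected;
* closeness of node v: (number of other reachable nodes) / (sum of
  distances to them), 0 for isolated nodes;
* clustering coefficient: closed triplets / possible triplets, 0 for
  degree < 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import ValidationError


@dataclass
class CoexpressionNetwork:
    """Signed thresholded-correlation graph over a gene set."""

    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "r": d["r"], "sign": d["sign"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "sign"])

    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())


@dataclass
class TopologySummary:
    average_shortest_path: float
    closeness: dict[str, float]
    clustering: dict[str, float]
    degree_histogram: dict[int, int]

    def to_dict(self) -> dict:
        return {
            "average_shortest_path": self.average_shortest_path,
            "closeness": self.closeness,
            "clustering": self.clustering,
            "degree_histogram": {str(k): v for k, v in self.degree_histogram.items()},
        }


def build_network(
    matrix: pd.DataFrame,
    genes: list[str] | set[str] | None = None,
    samples: list[str] | set[str] | None = None,
    threshold: float = 0.5,
) -> CoexpressionNetwork:
    """Build the signed co-expression graph over the given genes and samples.

    All requested genes appear as nodes (possibly isolated).  Pairs where a
    gene has zero variance over the samples have undefined correlation and
    draw no edge.
    """
    gene_list = sorted(set(genes) & set(matrix.index)) if genes is not None else list(matrix.index)
    sample_list = (
        [s for s in matrix.columns if s in set(samples)] if samples is not None else list(matrix.columns)
    )
    if len(sample_list) < 3:
        raise ValidationError(f"need >=3 samples for correlation, have {len(sample_list)}")
    sub = matrix.loc[gene_list, sample_list]

    G = nx.Graph()
    G.add_nodes_from(gene_list)
    if len(gene_list) >= 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.corrcoef(sub.to_numpy())
        iu, ju = np.triu_indices(len(gene_list), k=1)
        r = corr[iu, ju]
        hit = np.abs(r) > threshold  # strict: |r| == threshold draws no edge
        hit &= np.isfinite(r)
        for i, j, rij in zip(iu[hit], ju[hit], r[hit]):
            G.add_edge(
                gene_list[i],
                gene_list[j],
                r=float(rij),
                sign="positive" if rij > 0 else "negative",
            )
    return CoexpressionNetwork(graph=G, threshold=threshold)


def count_edge_signs(network: CoexpressionNetwork) -> tuple[int, int, int]:
    """(positive, negative, total) edge tallies."""
    pos = sum(1 for *_, d in network.graph.edges(data=True) if d["sign"] == "positive")
    total = network.graph.number_of_edges()
    return pos, total - pos, total


def topology(network: CoexpressionNetwork) -> TopologySummary:
    """ASP, per-node closeness and clustering, and the degree histogram."""
    G = network.graph
    total = 0.0
    n_pairs = 0
    closeness: dict[str, float] = {}
    for node, lengths in nx.all_pairs_shortest_path_length(G):
        dists = [d for other, d in lengths.items() if other != node]
        total += sum(dists)
        n_pairs += len(dists)
        closeness[node] = (len(dists) / sum(dists)) if dists else 0.0
    asp = total / n_pairs if n_pairs else 0.0
    clustering = {n: float(c) for n, c in nx.clustering(G).items()}
    hist: dict[int, int] = {}
    for _, d in G.degree():
        hist[d] = hist.get(d, 0) + 1
    return TopologySummary(
        average_shortest_path=asp,
        closeness=closeness,
        clustering=clustering,
        degree_histogram=dict(sorted(hist.items())),
    )


def degree_weights(
    network: CoexpressionNetwork, all_genes: list[str] | set[str] | None = None
) -> dict[str, float]:
    """Logistic degree weight ω = 1/(1+e^(−degree)); absent genes get 0.5."""
    deg = network.degree()
    genes = set(deg) | (set(all_genes) if all_genes is not None else set())
    return {g: float(1.0 / (1.0 + np.exp(-deg.get(g, 0)))) for g in genes}
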