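"""TF-anchored gene regulatory networks, community clustering, and
hub-gene ranking.

From a co-expression module, each transcription factor's neighborhood is the
top-n module genes by signed-adjacency weight to that TF; the union graph is
clustered into communities by weighted modularity, and hub genes are ranked
by three complementary centralities — strength (summed edge weights), degree
(edge count), and betweenness centrality — combined as the mean of the three
dense ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd

from .network import CoexpressionNetwork, GeneModule

__all__ = ["GRNGraph", "select_tf_neighborhoods", "community_cluster", "hub_scores"]


@dataclass
class GRNGraph:
    """Weighted undirected gene graph with TF flags and community labels."""

    graph: nx.Graph
    tf_genes: list = field(default_factory=list)
    communities: dict = field(default_factory=dict)

    @property
    def nodes(self):
        return list(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "weight": d["weight"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])


def select_tf_neighborhoods(
    network: CoexpressionNetwork,
    module: GeneModule,
    tf_list,
    n_top: int = 100,
    edge_floor: float = 0.02,
) -> GRNGraph:
    """Union of per-TF neighborhoods within a module.

    For each TF in the module, the ``n_top`` module genes with the highest
    adjacency weight to that TF are selected (ties by gene symbol); the
    graph holds the TF-gene edges plus gene-gene edges among selected nodes
    whose weight reaches ``edge_floor``.
    """
    gene_idx = {str(g): i for i, g in enumerate(network.genes)}
    module_genes = [g for g in module.genes if g in gene_idx]
    tfs = sorted(set(tf_list) & set(module_genes))
    if not tfs:
        raise ValueError(f"module {module.label} contains no TF from the list")

    G = nx.Graph()
    selected = set(tfs)
    for tf in tfs:
        ti = gene_idx[tf]
        partners = [g for g in module_genes if g != tf]
        ranked = sorted(partners, key=lambda g: (-network.adjacency[ti, gene_idx[g]], g))
        for g in ranked[:n_top]:
            w = float(network.adjacency[ti, gene_idx[g]])
            if w > 0:
                G.add_edge(tf, g, weight=w)
                selected.add(g)
    nodes = sorted(selected)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if G.has_edge(a, b):
                continue
            w = float(network.adjacency[gene_idx[a], gene_idx[b]])
            if w >= edge_floor:
                G.add_edge(a, b, weight=w)
    for n in G.nodes:
        G.nodes[n]["is_tf"] = n in tfs
    return GRNGraph(graph=G, tf_genes=tfs)


def community_cluster(grn: GRNGraph, seed: int = 0) -> dict:
    """Weighted modularity communities (deterministic given seed); singleton
    components receive their own labels. Labels are stored on the graph and
    returned as a gene -> community dict."""
    G = grn.graph
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(G.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in G.edges]
    weights = [G.edges[a, b]["weight"] for a, b in G.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    g.es["weight"] = weights
    part = leidenalg.find_partition(
        g, leidenalg.ModularityVertexPartition, weights="weight", seed=seed,
        n_iterations=-1,
    )
    labels = {n: int(part.membership[index[n]]) for n in nodes}
    grn.communities = labels
    for n, c in labels.items():
        G.nodes[n]["community"] = c
    return labels


def hub_scores(grn: GRNGraph, top_k: int = 5) -> pd.DataFrame:
    """Three-component hub ranking.

    strength = summed edge weights; degree = edge count; BC = unnormalized
    betweenness centrality on the unweighted edge set. Each metric is dense-
    ranked descending (1 = best); ``combined_rank`` is their arithmetic mean
    and the ``top_k`` lowest combined ranks are flagged as hubs.
    """
    G = grn.graph
    if G.number_of_nodes() < 3:
        raise ValueError("hub scoring needs at least 3 nodes")
    genes = sorted(G.nodes)
    strength = pd.Series(
        {n: float(sum(d["weight"] for _, _, d in G.edges(n, data=True))) for n in genes}
    )
    degree = pd.Series({n: G.degree(n) for n in genes}, dtype=float)
    bc = pd.Series(nx.betweenness_centrality(G, normalized=False, weight=None))
    bc = bc.reindex(genes).fillna(0.0)

    df = pd.DataFrame({"strength": strength, "degree": degree, "bc": bc})
    df["rank_strength"] = df["strength"].rank(method="dense", ascending=False).astype(int)
    df["rank_degree"] = df["degree"].rank(method="dense", ascending=False).astype(int)
    df["rank_bc"] = df["bc"].rank(method="dense", ascending=False).astype(int)
    df["combined_rank"] = df[["rank_strength", "rank_degree", "rank_bc"]].mean(axis=1)
    df = df.sort_values(["combined_rank", "strength"], ascending=[True, False])
    df["is_hub"] = False
    df.iloc[: min(top_k, len(df)), df.columns.get_loc("is_hub")] = True
    df.index.name = "gene"
    if grn.communities:
        df["community"] = pd.Series(grn.communities).reindex(df.index)
    return df
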