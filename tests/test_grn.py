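import itertools

import networkx as nx
import numpy as np
import pytest

from chondronet.grn import GRNGraph, community_cluster, hub_scores, select_tf_neighborhoods
from chondronet.network import CoexpressionNetwork, GeneModule, NetworkConfig
from chondronet.pipeline import make_fixture


def _bc_oracle(G):
    """Unnormalized betweenness centrality by exhaustive shortest-path
    enumeration over all simple paths (unweighted)."""
    nodes = list(G.nodes)
    bc = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = []
        shortest = None
        try:
            shortest = nx.shortest_path_length(G, s, t)
        except nx.NetworkXNoPath:
            continue
        for p in nx.all_simple_paths(G, s, t, cutoff=shortest):
            if len(p) - 1 == shortest:
                paths.append(p)
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / sigma
    return bc


def _network_from_adjacency(adj, genes):
    n = len(genes)
    return CoexpressionNetwork(
        genes=np.array(genes, dtype=object),
        correlation=np.eye(n),
        adjacency=np.asarray(adj, dtype=float),
        connectivity=np.asarray(adj).sum(axis=1) - 1.0,
        tom=np.eye(n),
        config=NetworkConfig(),
    )


def test_star_graph_centralities():
    grn = make_fixture("star_graph")
    df = hub_scores(grn, top_k=1)
    # star on 5 nodes: center BC = C(4,2) = 6, leaves 0
    assert df.loc["CENTER", "bc"] == pytest.approx(6.0)
    assert df.loc["L1", "bc"] == 0.0
    assert df.loc["CENTER", "degree"] == 4
    assert df.loc["CENTER", "strength"] == pytest.approx(2.0)
    assert df.loc["CENTER", "combined_rank"] == 1.0
    assert df["is_hub"].sum() == 1 and df.loc["CENTER", "is_hub"]


def test_path_graph_midpoint_bc():
    G = nx.path_graph(3)
    G = nx.relabel_nodes(G, {0: "a", 1: "mid", 2: "b"})
    for a, b in G.edges:
        G.edges[a, b]["weight"] = 1.0
    df = hub_scores(GRNGraph(graph=G), top_k=1)
    assert df.loc["mid", "bc"] == pytest.approx(1.0)


def test_bc_matches_oracle_on_random_graphs(rng):
    for _ in range(20):
        n = int(rng.integers(4, 8))
        G = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
        ref = _bc_oracle(G)
        got = nx.betweenness_centrality(G, normalized=False, weight=None)
        for v in G.nodes:
            assert got[v] == pytest.approx(ref[v], abs=1e-9)


def test_neighborhood_top_n_selection():
    """TF weights {g1: 0.9, g2: 0.5, g3: 0.4} with n_top=2 select g1, g2."""
    genes = ["TF", "g1", "g2", "g3"]
    adj = np.full((4, 4), 0.01)
    np.fill_diagonal(adj, 1.0)
    adj[0, 1] = adj[1, 0] = 0.9
    adj[0, 2] = adj[2, 0] = 0.5
    adj[0, 3] = adj[3, 0] = 0.4
    net = _network_from_adjacency(adj, genes)
    module = GeneModule(label=1, genes=genes)
    grn = select_tf_neighborhoods(net, module, ["TF"], n_top=2, edge_floor=0.02)
    assert set(grn.nodes) == {"TF", "g1", "g2"}
    assert grn.graph.edges["TF", "g1"]["weight"] == pytest.approx(0.9)
    assert grn.graph.nodes["TF"]["is_tf"]
    assert not grn.graph.nodes["g1"]["is_tf"]


def test_gene_gene_edges_respect_floor():
    genes = ["TF", "g1", "g2"]
    adj = np.eye(3)
    adj[0, 1] = adj[1, 0] = 0.5
    adj[0, 2] = adj[2, 0] = 0.5
    adj[1, 2] = adj[2, 1] = 0.019  # below floor 0.02
    net = _network_from_adjacency(adj, genes)
    grn = select_tf_neighborhoods(net, GeneModule(1, genes), ["TF"], n_top=5)
    assert not grn.graph.has_edge("g1", "g2")
    adj[1, 2] = adj[2, 1] = 0.021
    grn2 = select_tf_neighborhoods(
        _network_from_adjacency(adj, genes), GeneModule(1, genes), ["TF"], n_top=5
    )
    assert grn2.graph.has_edge("g1", "g2")


def test_module_without_tf_raises():
    genes = ["a", "b", "c"]
    net = _network_from_adjacency(np.eye(3) + 0.1, genes)
    with pytest.raises(ValueError, match="no TF"):
        select_tf_neighborhoods(net, GeneModule(1, genes), ["MISSING"])


def test_community_cluster_two_cliques():
    G = nx.Graph()
    for grp in (["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]):
        for x, y in itertools.combinations(grp, 2):
            G.add_edge(x, y, weight=1.0)
    G.add_edge("a1", "b1", weight=0.05)
    grn = GRNGraph(graph=G)
    labels = community_cluster(grn, seed=0)
    assert len({labels[n] for n in ["a1", "a2", "a3", "a4"]}) == 1
    assert len({labels[n] for n in ["b1", "b2", "b3", "b4"]}) == 1
    assert labels["a1"] != labels["b1"]
    # deterministic given the seed
    assert community_cluster(GRNGraph(graph=G), seed=0) == labels


def test_hub_scores_dense_ranks_and_community_column():
    G = nx.Graph()
    G.add_edge("h", "x", weight=1.0)
    G.add_edge("h", "y", weight=1.0)
    G.add_edge("h", "z", weight=1.0)
    G.add_edge("x", "y", weight=0.5)
    grn = GRNGraph(graph=G)
    community_cluster(grn, seed=0)
    df = hub_scores(grn, top_k=2)
    assert df.loc["h", "rank_strength"] == 1
    assert df.loc["h", "rank_degree"] == 1
    assert df.loc["h", "rank_bc"] == 1
    assert df.loc["h", "combined_rank"] == 1.0
    # dense ranking: x and y tie on degree 2 -> same rank, z next rank (3)
    assert df.loc["x", "rank_degree"] == df.loc["y", "rank_degree"] == 2
    assert df.loc["z", "rank_degree"] == 3
    assert "community" in df.columns
    assert df["is_hub"].sum() == 2


def test_hub_scores_too_small_raises():
    G = nx.Graph()
    G.add_edge("a", "b", weight=1.0)
    with pytest.raises(ValueError, match="3 nodes"):
        hub_scores(GRNGraph(graph=G))


def test_planted_hub_ranks_first():
    # heterogeneous loadings (0.4-0.8) with the hub at the maximum: the hub
    # should top the combined centrality ranking inside its community
    from chondronet.network import CoexpressionNetworkBuilder
    from chondronet.preprocess import apply_cell_qc, log_normalize
    from chondronet.simulate import ModuleSpec, SimulationSpec, simulate_counts

    spec = SimulationSpec(
        n_cells=500,
        n_genes=500,
        modules=[
            ModuleSpec(name=f"MOD{i}", gene_count=50, loading_range=(0.4, 0.8),
                       hub_gene=f"MOD{i}_TF")
            for i in range(1, 5)
        ],
        seed=0,
    )
    cm, truth = simulate_counts(spec)
    filtered, _ = apply_cell_qc(cm)
    norm = log_normalize(filtered)
    builder = CoexpressionNetworkBuilder(beta=8).fit(norm)
    present = set(builder.network_.genes.tolist())
    found_first = 0
    for i in range(1, 5):
        members = [
            g for g in truth.genes.index[truth.genes["module"] == f"MOD{i}"]
            if g in present
        ]
        module = GeneModule(label=i, genes=members)
        hub = f"MOD{i}_TF"
        grn = select_tf_neighborhoods(builder.network_, module, [hub], n_top=100)
        community_cluster(grn, seed=0)
        df = hub_scores(grn, top_k=5)
        comm = df.loc[hub, "community"]
        in_comm = df[df["community"] == comm]
        if in_comm["combined_rank"].idxmin() == hub:
            found_first += 1
    assert found_first >= 3
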