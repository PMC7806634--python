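import itertools

import numpy as np
import pytest
import scipy.stats
from sklearn.metrics import adjusted_rand_score

from chondronet.cluster import (
    PCAEmbedder,
    annotate_clusters,
    cluster_cells,
    embed_cells,
    find_markers,
    log_fold_change,
    snn_graph,
)
from chondronet.matrix import NormalizedMatrix
from chondronet.preprocess import select_hvg


def _norm_from(values, genes=None, barcodes=None):
    values = np.asarray(values, dtype=float)
    n_g, n_c = values.shape
    return NormalizedMatrix(
        values=values,
        gene_symbols=np.array(genes or [f"G{i}" for i in range(n_g)], dtype=object),
        barcodes=np.array(barcodes or [f"c{j}" for j in range(n_c)], dtype=object),
        scale_factor=10_000.0,
        provenance=[],
        cell_meta=None,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_pca_matches_sklearn_on_scaled_data(rng):
    values = rng.standard_normal((30, 80))
    emb = PCAEmbedder(n_pcs=5).fit(_norm_from(values))
    from sklearn.decomposition import PCA

    Z = PCAEmbedder._scale(values, 10.0)
    ref = PCA(n_components=5, svd_solver="full").fit_transform(Z.T)
    # same subspace up to per-component sign
    for k in range(5):
        c = np.corrcoef(emb.embedding_[:, k], ref[:, k])[0, 1]
        assert abs(c) > 1 - 1e-9


def test_pca_sign_convention_deterministic(rng):
    values = rng.standard_normal((20, 50))
    a = PCAEmbedder(n_pcs=4).fit(_norm_from(values))
    b = PCAEmbedder(n_pcs=4).fit(_norm_from(values))
    assert np.allclose(a.embedding_, b.embedding_)
    for k in range(4):
        j = np.argmax(np.abs(a.components_[k]))
        assert a.components_[k, j] > 0


def test_pca_clip_bounds_extreme_cells(rng):
    values = rng.standard_normal((10, 40))
    values[0, 0] = 1e6  # extreme outlier
    Z = PCAEmbedder._scale(values, 10.0)
    assert Z.max() <= 10.0 and Z.min() >= -10.0


def test_constant_genes_contribute_nothing(rng):
    values = rng.standard_normal((10, 40))
    with_const = np.vstack([values, np.full((5, 40), 3.0)])
    e1 = PCAEmbedder(n_pcs=3).fit(_norm_from(values)).embedding_
    e2 = PCAEmbedder(n_pcs=3).fit(_norm_from(with_const)).embedding_
    assert np.allclose(np.abs(e1), np.abs(e2), atol=1e-8)


# ---------------------------------------------------------------------------
# SNN graph + clustering
# ---------------------------------------------------------------------------


def test_snn_jaccard_weights_exact():
    # two tight pairs far apart; k=1 (+self): each cell's kNN set is its pair
    pts = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 0.0], [10.1, 0.0]])
    g = snn_graph(pts, k_neighbors=1, prune=0.0)
    dense = g.toarray()
    # identical 2-sets: jaccard = 2/(4-2) = 1 within pairs, 0 across
    assert dense[0, 1] == pytest.approx(1.0)
    assert dense[2, 3] == pytest.approx(1.0)
    assert dense[0, 2] == 0.0 and dense[1, 3] == 0.0


def test_snn_prune_removes_weak_edges(rng):
    pts = rng.standard_normal((60, 3))
    g_all = snn_graph(pts, k_neighbors=10, prune=0.0)
    g_pruned = snn_graph(pts, k_neighbors=10, prune=1 / 15)
    assert g_pruned.nnz <= g_all.nnz
    assert g_pruned.data.min() >= 1 / 15 - 1e-12


def test_clustering_separates_gaussian_blobs(rng):
    centers = np.array([[0, 0, 0], [15, 0, 0], [0, 15, 0]], dtype=float)
    labels_true = np.repeat([0, 1, 2], 80)
    pts = centers[labels_true] + rng.standard_normal((240, 3))
    assignment = cluster_cells(pts, k_neighbors=15, seed=0)
    assert adjusted_rand_score(labels_true, assignment.labels) > 0.95
    # labels contiguous from 0, ordered by decreasing size
    sizes = np.bincount(assignment.labels)
    assert np.all(np.diff(sizes) <= 0)


def test_clustering_deterministic(rng):
    pts = rng.standard_normal((120, 4))
    a = cluster_cells(pts, k_neighbors=10, seed=3).labels
    b = cluster_cells(pts, k_neighbors=10, seed=3).labels
    assert np.array_equal(a, b)


def test_clustering_too_few_cells_raises(rng):
    with pytest.raises(ValueError, match="at least"):
        cluster_cells(rng.standard_normal((5, 2)), k_neighbors=30)


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------


def _wilcoxon_oracle(x, y):
    """Exact two-sided rank-sum p-value by full enumeration of group
    assignments (no ties assumed)."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for comb in itertools.combinations(range(n + m), n):
        us.append(ranks[list(comb)].sum() - n * (n + 1) / 2)
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_low, p_high))


def test_wilcoxon_exact_convention_matches_enumeration(rng):
    for _ in range(5):
        x = rng.standard_normal(5)
        y = rng.standard_normal(6) + 0.5
        p_scipy = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="exact"
        ).pvalue
        assert p_scipy == pytest.approx(_wilcoxon_oracle(x, y), abs=1e-12)


def test_lnfc_convention():
    # ln(mean(e^x - 1) + 1) difference, not mean of logs
    vin = np.log1p(np.array([10.0, 20.0]))
    vout = np.log1p(np.array([1.0, 3.0]))
    expected = np.log1p(15.0) - np.log1p(2.0)
    assert log_fold_change(vin, vout) == pytest.approx(expected, abs=1e-12)


def test_marker_thresholds_are_strict_gates():
    rng = np.random.default_rng(0)
    n_in, n_out = 40, 60
    base = rng.uniform(0.5, 1.0, (4, n_in + n_out))
    values = base.copy()
    # gene 0: strong marker (high pct, high lnfc) -> reported
    values[0, :n_in] += 3.0
    # gene 1: high lnfc but expressed in <25% of the cluster -> suppressed
    values[1] = 0.0
    values[1, : int(0.2 * n_in)] = 5.0
    # gene 2: expressed everywhere, lnfc ~ 0 -> suppressed
    # gene 3: marker of the complement -> not reported for cluster 0
    values[3, n_in:] += 3.0
    norm = _norm_from(values, genes=["MK", "RARE", "FLAT", "OTHER"])
    from chondronet.cluster import ClusterAssignment

    labels = np.array([0] * n_in + [1] * n_out)
    asg = ClusterAssignment(
        labels=labels, barcodes=norm.barcodes, resolution=0.6,
        n_pcs=0, k_neighbors=0, seed=0,
    )
    markers = find_markers(norm, asg)
    c0 = markers[markers["cluster"] == 0]
    assert set(c0["gene"]) == {"MK"}
    assert (c0["pct_in"] >= 0.25).all()
    assert (c0["ln_fc"] > 0.25).all()
    c1 = markers[markers["cluster"] == 1]
    assert "OTHER" in set(c1["gene"])
    # Bonferroni: adjusted = min(1, p * n_genes)
    assert np.allclose(
        markers["adjusted_p"],
        np.minimum(1.0, markers["p_value"] * norm.n_genes),
    )


def test_markers_recover_planted_population_genes(small_norm):
    _, norm, truth = small_norm
    hvgs = select_hvg(norm, n_hvg=300)
    emb = embed_cells(norm, hvgs, n_pcs=15)
    asg = cluster_cells(emb, k_neighbors=20, seed=0, barcodes=norm.barcodes)
    markers = find_markers(norm, asg)
    reported = set(markers["gene"])
    present = set(norm.gene_symbols.tolist())
    planted = {
        g for g in truth.genes.index[truth.genes["role"] == "marker"] if g in present
    }
    assert len(planted & reported) / len(planted) > 0.8


def test_single_cluster_raises(small_norm):
    _, norm, _ = small_norm
    from chondronet.cluster import ClusterAssignment

    asg = ClusterAssignment(
        labels=np.zeros(norm.n_cells, dtype=int), barcodes=norm.barcodes,
        resolution=0.6, n_pcs=0, k_neighbors=0, seed=0,
    )
    with pytest.raises(ValueError, match="2 clusters"):
        find_markers(norm, asg)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def test_annotate_clusters_picks_best_signature():
    import pandas as pd

    markers = pd.DataFrame(
        {
            "gene": ["SOX9", "COL2A1", "ACAN", "COMP", "SOX2", "PAX6"],
            "cluster": [0, 0, 0, 0, 1, 1],
            "ln_fc": [1.0, 1.2, 0.9, 1.1, 2.0, 1.5],
        }
    )
    labels, scores = annotate_clusters(markers)
    assert labels[0] == "chondrocyte"
    assert labels[1] == "neural"
    assert scores.loc[0, "chondrocyte"] == pytest.approx(np.mean([1.0, 1.2, 0.9, 1.1]))


def test_annotate_unassigned_when_no_signal():
    import pandas as pd

    markers = pd.DataFrame({"gene": ["GENEX"], "cluster": [0], "ln_fc": [3.0]})
    labels, _ = annotate_clusters(markers)
    assert labels[0] == "unassigned"
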