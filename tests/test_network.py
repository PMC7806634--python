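import numpy as np
import pytest

from chondronet.matrix import NormalizedMatrix
from chondronet.network import (
    CoexpressionNetworkBuilder,
    NetworkConfig,
    clean_genes_samples,
    compute_tom,
    detect_modules,
    module_eigengene,
    pick_soft_threshold,
    scale_free_fit,
    signed_adjacency,
)
from chondronet.pipeline import make_fixture
from chondronet.preprocess import log_normalize


def _norm_from(values, genes=None):
    values = np.asarray(values, dtype=float)
    n_g, n_c = values.shape
    return NormalizedMatrix(
        values=values,
        gene_symbols=np.array(genes or [f"G{i:04d}" for i in range(n_g)], dtype=object),
        barcodes=np.array([f"c{j}" for j in range(n_c)], dtype=object),
        scale_factor=10_000.0,
    )


def _tom_oracle(a):
    """Brute-force TOM by explicit triple loop, diagonal excluded."""
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            t[i, j] = (shared + a[i, j]) / (min(ki, kj) + 1.0 - a[i, j])
    return t


def test_signed_adjacency_worked_example():
    cor = np.array([[1.0, 0.5], [0.5, 1.0]])
    adj = signed_adjacency(cor, beta=8)
    assert adj[0, 1] == pytest.approx(0.75**8, abs=1e-12)
    assert adj[0, 1] == pytest.approx(0.1001, abs=1e-4)
    assert adj[0, 0] == 1.0


def test_signed_adjacency_negative_correlation_suppressed():
    cor = np.array([[1.0, -0.9], [-0.9, 1.0]])
    adj = signed_adjacency(cor, beta=8)
    assert adj[0, 1] == pytest.approx(0.05**8, abs=1e-15)
    with pytest.raises(ValueError):
        signed_adjacency(cor, beta=0)


def test_tom_toy_worked_example():
    """a12=0.5, a13=0.2, a23=0.4: TOM_12 = (0.2*0.4 + 0.5) / (min(0.7,0.9)
    + 1 - 0.5) = 0.58/1.2."""
    a = make_fixture("tom_toy")
    tom = compute_tom(a)
    assert tom[0, 1] == pytest.approx(0.58 / 1.2, abs=1e-12)
    assert tom[0, 1] == pytest.approx(_tom_oracle(a)[0, 1], abs=1e-14)
    assert np.allclose(np.diag(tom), 1.0)


def test_tom_matches_oracle_random(rng):
    for _ in range(10):
        n = rng.integers(4, 12)
        cor = np.corrcoef(rng.standard_normal((n, 3 * n)))
        a = signed_adjacency(cor, beta=4)
        assert np.max(np.abs(compute_tom(a) - _tom_oracle(a))) < 1e-10


def test_tom_symmetric_bounded(rng):
    cor = np.corrcoef(rng.standard_normal((20, 100)))
    tom = compute_tom(signed_adjacency(cor, beta=8))
    assert np.allclose(tom, tom.T, atol=1e-12)
    assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12


def test_clean_removes_zero_variance_genes(rng):
    values = rng.standard_normal((10, 30))
    values[3] = 1.5  # constant gene
    cleaned, log = clean_genes_samples(_norm_from(values))
    assert cleaned.n_genes == 9
    assert log["genes_removed_zero_variance"] == 1
    assert "G0003" not in set(cleaned.gene_symbols.tolist())


def test_scale_free_fit_signs():
    rng = np.random.default_rng(0)
    # power-law degrees: many small, few large -> negative slope -> positive R2
    k_power = rng.pareto(2.0, 2000) + 0.5
    assert scale_free_fit(k_power) > 0.5
    # uniform-ish degrees give a poor or negative signed fit
    assert scale_free_fit(rng.uniform(5, 6, 2000)) < 0.5


def test_pick_soft_threshold_monotone_connectivity(rng):
    values = rng.standard_normal((60, 120))
    table, beta = pick_soft_threshold(_norm_from(values))
    mk = table["mean_k"].to_numpy()
    assert np.all(np.diff(mk) < 0)  # strictly decreasing in the power
    assert beta in set(table["power"]) or beta == 8


def test_pick_soft_threshold_fallback_warns():
    rng = np.random.default_rng(1)
    values = rng.standard_normal((60, 30))  # pure noise: no scale-free fit
    cfg = NetworkConfig(scale_free_r2_target=0.999999)
    with pytest.warns(UserWarning, match="falling back"):
        _, beta = pick_soft_threshold(_norm_from(values), cfg)
    assert beta == cfg.beta


def test_pick_soft_threshold_too_few_genes(rng):
    with pytest.raises(ValueError, match="50 genes"):
        pick_soft_threshold(_norm_from(rng.standard_normal((20, 30))))


def _correlated_block(rng, n_genes, n_cells, factor, loading=0.8):
    eps = rng.standard_normal((n_genes, n_cells))
    return loading * factor[None, :] + np.sqrt(1 - loading**2) * eps


def test_module_eigengene_tracks_latent_factor(rng):
    f = rng.standard_normal(200)
    values = _correlated_block(rng, 12, 200, f)
    norm = _norm_from(values)
    eig = module_eigengene(norm, list(norm.gene_symbols))
    assert abs(np.corrcoef(eig, f)[0, 1]) > 0.95
    # sign convention: positively correlated with members on average
    mean_cor = np.mean([np.corrcoef(values[i], eig)[0, 1] for i in range(12)])
    assert mean_cor > 0


def test_detect_modules_recovers_planted_blocks(rng):
    f1, f2 = rng.standard_normal(300), rng.standard_normal(300)
    block1 = _correlated_block(rng, 35, 300, f1)
    block2 = _correlated_block(rng, 35, 300, f2)
    noise = rng.standard_normal((30, 300))
    values = np.vstack([block1, block2, noise])
    genes = (
        [f"A{i:03d}" for i in range(35)]
        + [f"B{i:03d}" for i in range(35)]
        + [f"N{i:03d}" for i in range(30)]
    )
    norm = _norm_from(values, genes)
    tom = compute_tom(signed_adjacency(np.corrcoef(values), beta=8))
    # small dense Gaussian panel: block genes share more neighbors with the
    # noise background than sparse count data does, so use a tighter cut
    modules = detect_modules(tom, norm, NetworkConfig(min_module_size=30, cut_height=0.9))
    assert len(modules) == 2
    sets = [set(m.genes) for m in modules]
    assert any(s >= {f"A{i:03d}" for i in range(35)} for s in sets)
    assert any(s >= {f"B{i:03d}" for i in range(35)} for s in sets)
    # labels 1..n by decreasing size
    assert [m.label for m in modules] == [1, 2]
    assert len(modules[0].genes) >= len(modules[1].genes)


def test_detect_modules_merges_correlated_eigengenes(rng):
    # two blocks driven by the SAME factor -> eigengene cor ~ 1 -> merged
    f = rng.standard_normal(300)
    values = np.vstack(
        [_correlated_block(rng, 35, 300, f), _correlated_block(rng, 35, 300, f)]
    )
    norm = _norm_from(values)
    tom = compute_tom(signed_adjacency(np.corrcoef(values), beta=8))
    modules = detect_modules(tom, norm, NetworkConfig(min_module_size=30))
    assert len(modules) == 1
    assert len(modules[0].genes) == 70


def test_min_module_size_filter(rng):
    f = rng.standard_normal(200)
    values = np.vstack(
        [_correlated_block(rng, 10, 200, f), rng.standard_normal((40, 200))]
    )
    norm = _norm_from(values)
    tom = compute_tom(signed_adjacency(np.corrcoef(values), beta=8))
    with pytest.warns(UserWarning, match="min_module_size"):
        modules = detect_modules(tom, norm, NetworkConfig(min_module_size=30))
    assert modules == []


def test_builder_on_planted_simulation(modules_sim):
    cm, truth = modules_sim
    from chondronet.preprocess import apply_cell_qc

    filtered, _ = apply_cell_qc(cm)
    norm = log_normalize(filtered)
    builder = CoexpressionNetworkBuilder(beta=8).fit(norm)
    assert builder.beta_ == 8
    assert builder.network_.tom.shape[0] == builder.cleaned_.n_genes
    labels = {}
    for m in builder.modules_:
        for g in m.genes:
            labels[g] = m.label
    planted = truth.genes[truth.genes["module"] != ""]
    from sklearn.metrics import adjusted_rand_score

    common = [g for g in planted.index if g in labels]
    assert len(common) > 150
    ari = adjusted_rand_score(
        planted.loc[common, "module"], [labels[g] for g in common]
    )
    assert ari > 0.8
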