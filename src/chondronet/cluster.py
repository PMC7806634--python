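"""Dimensionality reduction, shared-nearest-neighbor modularity clustering,
marker detection, and signature-based cluster annotation.

Clustering follows the droplet toolchain convention: PCA on scaled highly
variable genes, a k-nearest-neighbor graph reweighted by shared-neighbor
Jaccard overlap with weak edges pruned, and modularity community detection
at a configurable resolution (0.6 by default). Markers are one-vs-rest
Wilcoxon rank-sum tests reported only when expressed in at least 25% of the
cluster's cells with a natural-log fold change above 0.25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.neighbors import NearestNeighbors

from .genesets import POPULATION_SIGNATURES
from .matrix import NormalizedMatrix

__all__ = [
    "ClusterAssignment",
    "PCAEmbedder",
    "SNNModularityClusterer",
    "embed_cells",
    "cluster_cells",
    "find_markers",
    "annotate_clusters",
    "log_fold_change",
]


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    barcodes: np.ndarray
    resolution: float
    n_pcs: int
    k_neighbors: int
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


class PCAEmbedder(BaseEstimator, TransformerMixin):
    """PCA on z-scored (clipped at +/-``clip``) gene rows.

    Components carry a deterministic sign convention: the largest-magnitude
    gene loading of each component is made positive. Constant genes z-score
    to zero and contribute nothing.
    """

    def __init__(self, n_pcs: int = 20, clip: float = 10.0):
        self.n_pcs = n_pcs
        self.clip = clip

    @staticmethod
    def _scale(values: np.ndarray, clip: float) -> np.ndarray:
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=0, keepdims=True)
        z = np.where(sd > 0, (values - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        return np.clip(z, -clip, clip)

    def fit(self, X: NormalizedMatrix, y=None):
        Z = self._scale(X.values, self.clip)  # genes x cells
        n_pcs = self.n_pcs
        max_rank = min(Z.shape) - 1
        if n_pcs > max_rank:
            warnings.warn(f"n_pcs={n_pcs} exceeds rank bound; using {max_rank}")
            n_pcs = max(max_rank, 1)
        # rows are features: SVD of cells x genes
        U, S, Vt = np.linalg.svd(Z.T, full_matrices=False)
        signs = np.ones(n_pcs)
        for k in range(n_pcs):
            j = np.argmax(np.abs(Vt[k]))
            if Vt[k, j] < 0:
                signs[k] = -1.0
        self.components_ = Vt[:n_pcs] * signs[:, None]  # n_pcs x genes
        self.singular_values_ = S[:n_pcs]
        self.n_pcs_ = n_pcs
        self.embedding_ = (U[:, :n_pcs] * S[:n_pcs]) * signs[None, :]
        return self

    def transform(self, X: NormalizedMatrix) -> np.ndarray:
        Z = self._scale(X.values, self.clip)
        return Z.T @ self.components_.T


def embed_cells(norm: NormalizedMatrix, hvgs=None, n_pcs: int = 20) -> np.ndarray:
    """Cell x component PCA scores on the given highly variable genes."""
    X = norm if hvgs is None else norm.subset_genes(hvgs)
    if hvgs is not None and len(hvgs) < n_pcs:
        warnings.warn("fewer HVGs than requested components")
    return PCAEmbedder(n_pcs=n_pcs).fit(X).embedding_


def snn_graph(
    embedding: np.ndarray, k_neighbors: int = 30, prune: float = 1 / 15
) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph: Jaccard overlap of k-NN sets
    (self-inclusive, Euclidean), edges below ``prune`` removed."""
    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k_neighbors + 1, n)).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    rows = np.repeat(np.arange(n), idx.shape[1])
    A = sp.csr_matrix(
        (np.ones(idx.size), (rows, idx.ravel())), shape=(n, n)
    )  # binary membership, self included
    shared = (A @ A.T).tocoo()
    set_size = idx.shape[1]
    jac = shared.data / (2 * set_size - shared.data)
    keep = (jac >= prune) & (shared.row != shared.col)
    return sp.csr_matrix((jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))


class SNNModularityClusterer(BaseEstimator, ClusterMixin):
    """Modularity community detection on the SNN graph (Leiden refinement of
    the Louvain objective), deterministic for a fixed seed."""

    def __init__(
        self,
        k_neighbors: int = 30,
        resolution: float = 0.6,
        prune: float = 1 / 15,
        seed: int = 0,
    ):
        self.k_neighbors = k_neighbors
        self.resolution = resolution
        self.prune = prune
        self.seed = seed

    def fit(self, X: np.ndarray, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.k_neighbors + 1:
            raise ValueError(
                f"need at least {self.k_neighbors + 1} cells, got {X.shape[0]}"
            )
        g_sparse = snn_graph(X, self.k_neighbors, self.prune)
        sym = g_sparse.maximum(g_sparse.T).tocoo()
        mask = sym.row < sym.col
        edges = list(zip(sym.row[mask].tolist(), sym.col[mask].tolist()))
        graph = ig.Graph(n=X.shape[0], edges=edges)
        graph.es["weight"] = sym.data[mask].tolist()
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=self.resolution,
            seed=self.seed,
            n_iterations=-1,
        )
        labels = np.array(part.membership)
        # relabel contiguously by decreasing cluster size, ties by old label
        sizes = pd.Series(labels).value_counts().sort_index()
        order = sizes.sort_values(ascending=False, kind="stable").index
        remap = {old: new for new, old in enumerate(order)}
        self.labels_ = np.array([remap[l] for l in labels])
        return self

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_


def cluster_cells(
    embedding: np.ndarray,
    k_neighbors: int = 30,
    resolution: float = 0.6,
    seed: int = 0,
    barcodes=None,
) -> ClusterAssignment:
    labels = SNNModularityClusterer(
        k_neighbors=k_neighbors, resolution=resolution, seed=seed
    ).fit_predict(embedding)
    return ClusterAssignment(
        labels=labels,
        barcodes=np.asarray(
            barcodes if barcodes is not None else np.arange(len(labels)), dtype=object
        ),
        resolution=resolution,
        n_pcs=embedding.shape[1],
        k_neighbors=k_neighbors,
        seed=seed,
    )


def log_fold_change(values_in: np.ndarray, values_out: np.ndarray) -> np.ndarray:
    """Natural-log fold change on back-transformed means:
    ln(mean(e^x - 1) + 1)_in - ln(mean(e^x - 1) + 1)_out (row-wise)."""
    m_in = np.expm1(values_in).mean(axis=-1)
    m_out = np.expm1(values_out).mean(axis=-1)
    return np.log1p(m_in) - np.log1p(m_out)


def find_markers(
    norm: NormalizedMatrix,
    assignment: ClusterAssignment,
    min_pct: float = 0.25,
    lnfc_min: float = 0.25,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    A record is emitted only when the gene is expressed in at least
    ``min_pct`` of the cluster's cells AND the natural-log fold change
    exceeds ``lnfc_min``. P-values are Bonferroni-adjusted by the number of
    genes; output sorted by cluster then descending ln fold change.
    """
    labels = assignment.labels
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("marker detection needs at least 2 clusters")
    expressed = norm.values > 0
    records = []
    for c in clusters:
        in_mask = labels == c
        if in_mask.sum() < 3:
            warnings.warn(f"cluster {c} has fewer than 3 cells; skipped")
            continue
        vin, vout = norm.values[:, in_mask], norm.values[:, ~in_mask]
        pct_in = expressed[:, in_mask].mean(axis=1)
        pct_out = expressed[:, ~in_mask].mean(axis=1)
        lnfc = log_fold_change(vin, vout)
        passing = np.flatnonzero((pct_in >= min_pct) & (lnfc > lnfc_min))
        if passing.size == 0:
            continue
        if max(vin.shape[1], vout.shape[1]) <= 8:
            pvals = np.array(
                [
                    scipy.stats.mannwhitneyu(
                        vin[g], vout[g], alternative="two-sided", method="auto"
                    ).pvalue
                    for g in passing
                ]
            )
        else:
            res = scipy.stats.mannwhitneyu(
                vin[passing], vout[passing], alternative="two-sided",
                method="asymptotic", axis=1,
            )
            pvals = np.atleast_1d(res.pvalue)
        for g, p in zip(passing, pvals):
            records.append(
                {
                    "gene": str(norm.gene_symbols[g]),
                    "cluster": int(c),
                    "ln_fc": float(lnfc[g]),
                    "pct_in": float(pct_in[g]),
                    "pct_out": float(pct_out[g]),
                    "p_value": float(p),
                    "adjusted_p": float(min(1.0, p * norm.n_genes)),
                }
            )
    df = pd.DataFrame(
        records,
        columns=["gene", "cluster", "ln_fc", "pct_in", "pct_out", "p_value", "adjusted_p"],
    )
    return df.sort_values(["cluster", "ln_fc"], ascending=[True, False]).reset_index(
        drop=True
    )


def annotate_clusters(markers: pd.DataFrame, signature_table: dict = None):
    """Label clusters by the population signature with the maximal mean
    marker ln fold change; ties or all-nonpositive scores -> "unassigned".

    Returns ``(cluster -> label dict, score matrix DataFrame)``.
    """
    signatures = signature_table if signature_table is not None else POPULATION_SIGNATURES
    if not signatures:
        raise ValueError("empty signature table")
    clusters = sorted(markers["cluster"].unique()) if len(markers) else []
    scores = pd.DataFrame(0.0, index=clusters, columns=list(signatures))
    for c in clusters:
        sub = markers[markers["cluster"] == c].set_index("gene")["ln_fc"]
        for pop, genes in signatures.items():
            vals = [float(sub.get(g, 0.0)) for g in genes]
            scores.loc[c, pop] = float(np.mean(vals)) if vals else 0.0
    labels = {}
    for c in clusters:
        row = scores.loc[c]
        best = row.max()
        if best <= 0 or (row == best).sum() > 1:
            labels[c] = "unassigned"
        else:
            labels[c] = str(row.idxmax())
    return labels, scores
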