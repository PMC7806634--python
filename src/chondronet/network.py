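"""Weighted gene co-expression network construction.

Pearson correlations across cells are mapped to a signed adjacency
a_ij = ((1 + cor_ij)/2)^beta, with the soft-thresholding power beta chosen
as the smallest candidate whose connectivity distribution approximates
scale-free topology (signed R^2 of the log-log degree fit above a target),
falling back to the shipped default of 8. The unsigned topological overlap
matrix (TOM) combines direct adjacency with shared-neighbor similarity;
modules are detected by average-linkage hierarchical clustering of 1 - TOM
with a static cut, a minimum size, and iterative merging of modules whose
eigengenes correlate above 1 - merge_cut_height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.base import BaseEstimator

from .matrix import NormalizedMatrix

__all__ = [
    "NetworkConfig",
    "CoexpressionNetwork",
    "GeneModule",
    "CoexpressionNetworkBuilder",
    "clean_genes_samples",
    "signed_adjacency",
    "pick_soft_threshold",
    "compute_tom",
    "detect_modules",
    "module_eigengene",
]


@dataclass
class NetworkConfig:
    candidate_powers: tuple = tuple(range(1, 21))
    beta: int = 8
    merge_cut_height: float = 0.25
    min_module_size: int = 30
    scale_free_r2_target: float = 0.8
    n_degree_bins: int = 10
    cut_height: float = 0.99

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0.0 < self.merge_cut_height < 1.0:
            raise ValueError("merge_cut_height must be in (0,1)")


@dataclass
class CoexpressionNetwork:
    genes: np.ndarray
    correlation: np.ndarray
    adjacency: np.ndarray
    connectivity: np.ndarray
    tom: np.ndarray
    config: NetworkConfig


@dataclass
class GeneModule:
    label: int
    genes: list
    eigengene: np.ndarray = None  # type: ignore[assignment]


def clean_genes_samples(norm: NormalizedMatrix, max_missing: float = 0.5):
    """Remove zero-variance genes and genes/cells with too many missing
    entries (UMI-derived matrices have none; the rule is kept for
    generality). Returns ``(cleaned, removal_log)``."""
    V = norm.values
    gene_missing = np.isnan(V).mean(axis=1)
    keep_genes = gene_missing <= max_missing
    cell_missing = np.isnan(V).mean(axis=0)
    keep_cells = cell_missing <= max_missing
    V2 = V[np.ix_(keep_genes, keep_cells)]
    var = np.nanvar(V2, axis=1)
    nonconst = var > 0
    keep_genes[np.flatnonzero(keep_genes)[~nonconst]] = False
    log = {
        "genes_removed_missing": int((gene_missing > max_missing).sum()),
        "cells_removed_missing": int((cell_missing > max_missing).sum()),
        "genes_removed_zero_variance": int((~nonconst).sum()),
    }
    if not keep_genes.any() or not keep_cells.any():
        raise ValueError("cleaning removed all genes or all cells")
    out = NormalizedMatrix(
        values=V[np.ix_(keep_genes, keep_cells)],
        gene_symbols=norm.gene_symbols[keep_genes],
        barcodes=norm.barcodes[keep_cells],
        scale_factor=norm.scale_factor,
        provenance=norm.provenance + [{"step": "clean_genes_samples", **log}],
        cell_meta=norm.cell_meta.loc[keep_cells].copy(),
    )
    return out, log


def signed_adjacency(cor: np.ndarray, beta: int) -> np.ndarray:
    """Signed network adjacency ((1 + cor)/2)^beta with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = ((1.0 + np.asarray(cor, dtype=float)) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def _connectivity(adjacency: np.ndarray) -> np.ndarray:
    k = adjacency.sum(axis=1) - np.diag(adjacency)
    return k


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log10(frequency) ~ log10(mean k) fit over
    equal-width connectivity bins (nonempty bins only); negative slope
    yields positive signed R^2."""
    k = np.asarray(k, dtype=float)
    if k.max() <= k.min():
        return np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size and members.mean() > 0:
            xs.append(np.log10(members.mean()))
            ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return np.nan
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * np.asarray(xs) + intercept
    ss_res = float(np.sum((np.asarray(ys) - pred) ** 2))
    ss_tot = float(np.sum((np.asarray(ys) - np.mean(ys)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return -np.sign(slope) * r2 if np.isfinite(r2) else np.nan


def pick_soft_threshold(norm: NormalizedMatrix, config: NetworkConfig = None):
    """Scan candidate powers, reporting signed scale-free R^2 and mean
    connectivity per power; returns ``(table, chosen_beta)``. The chosen
    power is the smallest reaching the R^2 target, falling back to the
    default with a warning when none does."""
    config = config or NetworkConfig()
    if norm.n_genes < 50:
        raise ValueError("soft-threshold scan needs at least 50 genes")
    cor = np.corrcoef(norm.values)
    if not np.isfinite(cor).all():
        raise ValueError("correlations undefined (constant genes present?)")
    rows = []
    chosen = None
    for power in config.candidate_powers:
        adj = signed_adjacency(cor, power)
        k = _connectivity(adj)
        r2 = scale_free_fit(k, config.n_degree_bins)
        rows.append({"power": power, "signed_r2": r2, "mean_k": float(k.mean())})
        if chosen is None and np.isfinite(r2) and r2 >= config.scale_free_r2_target:
            chosen = power
    table = pd.DataFrame(rows)
    if chosen is None:
        warnings.warn(
            f"no candidate power reached signed R^2 >= {config.scale_free_r2_target}; "
            f"falling back to beta={config.beta}"
        )
        chosen = config.beta
    return table, chosen


def compute_tom(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap.

    With the diagonal excluded from all sums,
    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, and TOM_ii = 1.
    """
    a = np.asarray(adjacency, dtype=float)
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    shared = a0 @ a0
    numer = shared + a0
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def module_eigengene(norm: NormalizedMatrix, genes) -> np.ndarray:
    """Per-cell module summary: first principal component of the z-scored
    member expression, sign-oriented to correlate positively with the
    members on average."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty module")
    sub = norm.subset_genes(genes).values  # members x cells
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    U, S, Vt = np.linalg.svd(z, full_matrices=False)
    eig = Vt[0] * S[0]
    cors = []
    for row in z:
        if row.std() > 0 and eig.std() > 0:
            cors.append(np.corrcoef(row, eig)[0, 1])
    if cors and np.mean(cors) < 0:
        eig = -eig
    return eig


def detect_modules(
    tom: np.ndarray, norm: NormalizedMatrix, config: NetworkConfig = None
) -> list:
    """Average-linkage hierarchical clustering of 1 - TOM with a static cut,
    minimum module size, and eigengene-correlation merging.

    Modules whose eigengenes correlate above ``1 - merge_cut_height`` are
    merged iteratively (closest pair first). Surviving modules are labeled
    1, 2, ... by decreasing size; unassigned genes carry label 0.
    """
    config = config or NetworkConfig()
    n = tom.shape[0]
    if norm.n_genes != n:
        raise ValueError("TOM size does not match gene count")
    diss = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    Z = sch.linkage(ssd.squareform(diss, checks=False), method="average")
    raw = sch.fcluster(Z, t=config.cut_height, criterion="distance")

    genes = norm.gene_symbols
    groups = {}
    for lbl in np.unique(raw):
        members = [str(genes[i]) for i in np.flatnonzero(raw == lbl)]
        if len(members) >= config.min_module_size:
            groups[lbl] = members
    if not groups:
        warnings.warn("no module reached min_module_size; all genes unassigned")
        return []

    modules = [list(m) for m in groups.values()]
    merge_threshold = 1.0 - config.merge_cut_height
    while len(modules) > 1:
        eigs = [module_eigengene(norm, m) for m in modules]
        best, best_cor = None, merge_threshold
        for i in range(len(modules)):
            for j in range(i + 1, len(modules)):
                c = np.corrcoef(eigs[i], eigs[j])[0, 1]
                if np.isfinite(c) and c > best_cor:
                    best, best_cor = (i, j), c
        if best is None:
            break
        i, j = best
        modules[i] = modules[i] + modules[j]
        del modules[j]

    modules.sort(key=lambda m: (-len(m), m[0]))
    return [
        GeneModule(label=i + 1, genes=m, eigengene=module_eigengene(norm, m))
        for i, m in enumerate(modules)
    ]


class CoexpressionNetworkBuilder(BaseEstimator):
    """End-to-end network construction: clean, correlate, soft-threshold,
    adjacency, TOM, module detection.

    Fitted attributes: ``network_`` (:class:`CoexpressionNetwork`),
    ``modules_`` (list of :class:`GeneModule`), ``soft_threshold_table_``,
    ``beta_``.
    """

    def __init__(
        self,
        beta: int = 8,
        auto_beta: bool = False,
        merge_cut_height: float = 0.25,
        min_module_size: int = 30,
        scale_free_r2_target: float = 0.8,
    ):
        self.beta = beta
        self.auto_beta = auto_beta
        self.merge_cut_height = merge_cut_height
        self.min_module_size = min_module_size
        self.scale_free_r2_target = scale_free_r2_target

    def fit(self, X: NormalizedMatrix, y=None):
        config = NetworkConfig(
            beta=self.beta,
            merge_cut_height=self.merge_cut_height,
            min_module_size=self.min_module_size,
            scale_free_r2_target=self.scale_free_r2_target,
        )
        cleaned, _ = clean_genes_samples(X)
        beta = self.beta
        self.soft_threshold_table_ = None
        if self.auto_beta:
            self.soft_threshold_table_, beta = pick_soft_threshold(cleaned, config)
        self.beta_ = beta
        cor = np.corrcoef(cleaned.values)
        adj = signed_adjacency(cor, beta)
        tom = compute_tom(adj)
        self.network_ = CoexpressionNetwork(
            genes=cleaned.gene_symbols,
            correlation=cor,
            adjacency=adj,
            connectivity=_connectivity(adj),
            tom=tom,
            config=config,
        )
        self.modules_ = detect_modules(tom, cleaned, config)
        self.cleaned_ = cleaned
        return self
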