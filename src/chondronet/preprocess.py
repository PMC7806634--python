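"""Cell and gene quality control, depth normalization, variable-gene
selection, cell-cycle scoring, covariate regression, and species-mixing
multiplet estimation.

Filtering follows the droplet scRNA-seq conventions for this assay: cells
are dropped when they have fewer than 200 or more than 7000 detected genes,
or more than 5% mitochondrial UMIs (strict inequalities); genes detected in
fewer than 3 remaining cells are then dropped. Expression is depth-scaled to
10,000 molecules per cell and natural-log transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .genesets import G2M_GENES, S_GENES
from .matrix import CountMatrix, NormalizedMatrix

__all__ = [
    "QCThresholds",
    "CellCycleScores",
    "CellQC",
    "LogNormalizer",
    "HVGSelector",
    "CovariateRegressor",
    "call_cell_barcodes",
    "apply_cell_qc",
    "log_normalize",
    "select_hvg",
    "score_cell_cycle",
    "regress_out",
    "estimate_multiplet_rate",
]


@dataclass
class QCThresholds:
    min_genes: int = 200
    max_genes: int = 7000
    max_mito_fraction: float = 0.05
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction outside [0,1]")


@dataclass
class CellCycleScores:
    s_score: np.ndarray
    g2m_score: np.ndarray
    phase: np.ndarray  # "G1" | "S" | "G2M"
    barcodes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"s_score": self.s_score, "g2m_score": self.g2m_score, "phase": self.phase},
            index=pd.Index(self.barcodes, name="barcode"),
        )


def call_cell_barcodes(umi_per_barcode, expected_cells: int) -> np.ndarray:
    """Empty-droplet removal: keep barcodes with at least 10% of the 99th
    percentile of the top ``expected_cells`` barcodes' UMI totals.

    Returns a boolean mask over the input barcodes.
    """
    if expected_cells < 1:
        raise ValueError("expected_cells must be >= 1")
    umis = np.asarray(umi_per_barcode, dtype=float)
    top = np.sort(umis)[::-1][: min(expected_cells, umis.size)]
    threshold = 0.10 * np.percentile(top, 99)
    return umis >= threshold


class CellQC(BaseEstimator, TransformerMixin):
    """Cell-then-gene quality filter.

    Cells are removed iff detected genes < ``min_genes``, detected genes >
    ``max_genes``, or mitochondrial fraction > ``max_mito_fraction`` (strict
    inequalities, so boundary cells are retained); genes detected in fewer
    than ``min_cells_per_gene`` of the remaining cells are then removed.
    After ``transform``, ``provenance_`` records the removals in order.
    """

    def __init__(
        self,
        min_genes: int = 200,
        max_genes: int = 7000,
        max_mito_fraction: float = 0.05,
        min_cells_per_gene: int = 3,
    ):
        self.min_genes = min_genes
        self.max_genes = max_genes
        self.max_mito_fraction = max_mito_fraction
        self.min_cells_per_gene = min_cells_per_gene

    def fit(self, X: CountMatrix, y=None):
        QCThresholds(
            self.min_genes, self.max_genes, self.max_mito_fraction, self.min_cells_per_gene
        )
        return self

    def transform(self, X: CountMatrix) -> CountMatrix:
        detected = X.detected_genes()
        mito = X.mito_fraction()
        keep_cells = (
            (detected >= self.min_genes)
            & (detected <= self.max_genes)
            & (mito <= self.max_mito_fraction)
        )
        if not keep_cells.any():
            raise ValueError("cell QC removed every cell")
        after_cells = X.subset(cell_mask=keep_cells)
        cells_per_gene = np.asarray((after_cells.counts > 0).sum(axis=1)).ravel()
        keep_genes = cells_per_gene >= self.min_cells_per_gene
        out = after_cells.subset(gene_mask=keep_genes)
        self.provenance_ = [
            {
                "step": "cell_qc",
                "cells_in": X.n_cells,
                "cells_removed": int((~keep_cells).sum()),
                "cells_out": int(keep_cells.sum()),
            },
            {
                "step": "gene_filter",
                "genes_in": X.n_genes,
                "genes_removed": int((~keep_genes).sum()),
                "genes_out": int(keep_genes.sum()),
            },
        ]
        return out


def apply_cell_qc(matrix: CountMatrix, thresholds: QCThresholds = None):
    """Apply the cell/gene QC rule; returns ``(filtered, provenance)``."""
    t = thresholds or QCThresholds()
    qc = CellQC(t.min_genes, t.max_genes, t.max_mito_fraction, t.min_cells_per_gene)
    out = qc.fit(matrix).transform(matrix)
    return out, qc.provenance_


class LogNormalizer(BaseEstimator, TransformerMixin):
    """Depth normalization to ``scale_factor`` molecules per cell, then
    ln(1 + x). Zero-depth cells are left all-zero with a warning."""

    def __init__(self, scale_factor: float = 10_000.0):
        self.scale_factor = scale_factor

    def fit(self, X: CountMatrix, y=None):
        return self

    def transform(self, X: CountMatrix) -> NormalizedMatrix:
        total = X.total_counts().astype(float)
        zero_depth = total == 0
        if zero_depth.any():
            warnings.warn(f"{int(zero_depth.sum())} zero-depth cells left all-zero")
        dense = np.asarray(X.counts.todense(), dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = dense / np.where(zero_depth, 1.0, total)[None, :] * self.scale_factor
        scaled[:, zero_depth] = 0.0
        return NormalizedMatrix(
            values=np.log1p(scaled),
            gene_symbols=X.gene_symbols,
            barcodes=X.barcodes,
            scale_factor=self.scale_factor,
            provenance=[{"step": "log_normalize", "scale_factor": self.scale_factor}],
            cell_meta=X.cell_meta.copy(),
        )


def log_normalize(matrix: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    if matrix.n_cells == 0:
        raise ValueError("no cells to normalize")
    return LogNormalizer(scale_factor).fit(matrix).transform(matrix)


class HVGSelector(BaseEstimator, TransformerMixin):
    """Highly variable genes by binned dispersion z-score.

    Per gene, the mean and dispersion (variance/mean) of the back-transformed
    expression ``exp(x) - 1`` are computed; dispersions are z-scored within
    equal-frequency bins of the mean, and the top ``n_hvg`` by z-score are
    selected (ties broken by gene symbol).
    """

    def __init__(self, n_hvg: int = 2000, n_bins: int = 20):
        self.n_hvg = n_hvg
        self.n_bins = n_bins

    def fit(self, X: NormalizedMatrix, y=None):
        back = np.expm1(X.values)
        mean = back.mean(axis=1)
        var = back.var(axis=1, ddof=1) if X.n_cells > 1 else np.zeros(X.n_genes)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)
        if int((mean > 0).sum()) < self.n_bins:
            raise ValueError("fewer genes with nonzero mean than bins")
        df = pd.DataFrame(
            {"gene": X.gene_symbols.astype(str), "mean": mean, "disp": disp}
        )
        bins = pd.qcut(df["mean"].rank(method="first"), self.n_bins, labels=False)
        z = np.zeros(len(df))
        for b in range(self.n_bins):
            m = bins == b
            mu, sd = df.loc[m, "disp"].mean(), df.loc[m, "disp"].std(ddof=1)
            z[m] = 0.0 if not np.isfinite(sd) or sd == 0 else (df.loc[m, "disp"] - mu) / sd
        df["z"] = z
        n = self.n_hvg
        if n > len(df):
            warnings.warn(f"n_hvg={n} exceeds gene count {len(df)}; returning all genes")
            n = len(df)
        order = df.sort_values(["z", "gene"], ascending=[False, True])
        self.dispersions_ = df.set_index("gene")
        self.hvg_genes_ = order["gene"].to_numpy(dtype=object)[:n]
        return self

    def transform(self, X: NormalizedMatrix) -> NormalizedMatrix:
        return X.subset_genes(self.hvg_genes_)


def select_hvg(norm: NormalizedMatrix, n_hvg: int = 2000, n_bins: int = 20) -> np.ndarray:
    return HVGSelector(n_hvg, n_bins).fit(norm).hvg_genes_


def score_cell_cycle(
    norm: NormalizedMatrix,
    s_genes=None,
    g2m_genes=None,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> CellCycleScores:
    """Cell-cycle phase scores from S and G2/M marker programs.

    Each program's score is the mean expression of its genes minus the mean
    of control genes sampled (``n_ctrl`` per program gene, deterministically
    given ``seed``) from the same average-expression bin; phase is the argmax
    program, G1 when both scores are <= 0.
    """
    s_genes = list(S_GENES if s_genes is None else s_genes)
    g2m_genes = list(G2M_GENES if g2m_genes is None else g2m_genes)
    symbols = norm.gene_symbols.astype(str)
    sym_to_idx = {g: i for i, g in enumerate(symbols)}

    mean_expr = norm.values.mean(axis=1)
    bins = pd.qcut(
        pd.Series(mean_expr).rank(method="first"), min(n_bins, norm.n_genes), labels=False
    ).to_numpy()
    rng = np.random.default_rng(seed)

    def program_score(genes, label):
        present = [g for g in genes if g in sym_to_idx]
        if not present:
            missing = ", ".join(genes[:10])
            raise ValueError(f"no {label} genes found in matrix (looked for {missing}, ...)")
        idx = np.array([sym_to_idx[g] for g in present])
        ctrl_idx = []
        for gi in idx:
            pool = np.flatnonzero(bins == bins[gi])
            ctrl_idx.append(rng.choice(pool, size=min(n_ctrl, pool.size), replace=False))
        ctrl_idx = np.concatenate(ctrl_idx)
        return norm.values[idx].mean(axis=0) - norm.values[ctrl_idx].mean(axis=0)

    s = program_score(s_genes, "S-phase")
    g2m = program_score(g2m_genes, "G2/M-phase")
    phase = np.where((s <= 0) & (g2m <= 0), "G1", np.where(g2m > s, "G2M", "S"))
    return CellCycleScores(s_score=s, g2m_score=g2m, phase=phase, barcodes=norm.barcodes)


class CovariateRegressor(BaseEstimator, TransformerMixin):
    """Remove per-cell covariates (cell-cycle scores, mitochondrial content)
    from each gene by ordinary least squares; output is the residual plus the
    gene mean. Collinear covariate columns are dropped with a warning."""

    def __init__(self, covariates: pd.DataFrame = None):
        self.covariates = covariates

    def fit(self, X: NormalizedMatrix, y=None):
        cov = pd.DataFrame(self.covariates)
        if len(cov) != X.n_cells:
            raise ValueError("covariate rows do not align with cells")
        design = np.column_stack([np.ones(X.n_cells), cov.to_numpy(dtype=float)])
        # drop collinear columns (QR with pivoting; intercept always kept)
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            keep = [0]
            for j in range(1, design.shape[1]):
                trial = design[:, keep + [j]]
                if np.linalg.matrix_rank(trial) > len(keep):
                    keep.append(j)
            dropped = [c for j, c in enumerate(cov.columns) if (j + 1) not in keep]
            warnings.warn(f"dropping collinear covariate columns: {dropped}")
            design = design[:, keep]
        self.design_ = design
        return self

    def transform(self, X: NormalizedMatrix) -> NormalizedMatrix:
        Y = X.values.T  # cells x genes
        beta, *_ = np.linalg.lstsq(self.design_, Y, rcond=None)
        resid = Y - self.design_ @ beta
        out = (resid + X.values.mean(axis=1)[None, :]).T
        return NormalizedMatrix(
            values=out,
            gene_symbols=X.gene_symbols,
            barcodes=X.barcodes,
            scale_factor=X.scale_factor,
            provenance=X.provenance + [{"step": "regress_out", "n_covariates": self.design_.shape[1] - 1}],
            cell_meta=X.cell_meta.copy(),
        )


def regress_out(norm: NormalizedMatrix, covariates: pd.DataFrame) -> NormalizedMatrix:
    return CovariateRegressor(covariates).fit(norm).transform(norm)


def estimate_multiplet_rate(barnyard: CountMatrix, purity_threshold: float = 0.9):
    """Multiplet rate from a 1:1 two-species mixing experiment.

    A barcode is called cross-species when its majority-species UMI fraction
    is below ``purity_threshold``. Because same-species collisions are
    invisible, the inferred total rate is twice the cross-species rate under
    a 1:1 mixture. Returns ``(cross_species_rate, inferred_total_rate)``.
    """
    prefixes = np.array([str(s).split("_")[0] for s in barnyard.gene_symbols])
    species = np.unique(prefixes)
    if len(species) < 2:
        raise ValueError("single-species input: species prefixes required on genes")
    if len(species) > 2:
        raise ValueError(f"expected 2 species, found {list(species)}")
    a = np.asarray(barnyard.counts[prefixes == species[0]].sum(axis=0)).ravel()
    b = np.asarray(barnyard.counts[prefixes == species[1]].sum(axis=0)).ravel()
    total = (a + b).astype(float)
    nonzero = total > 0
    purity = np.maximum(a, b)[nonzero] / total[nonzero]
    cross_rate = float(np.mean(purity < purity_threshold)) if nonzero.any() else 0.0
    return cross_rate, 2.0 * cross_rate
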