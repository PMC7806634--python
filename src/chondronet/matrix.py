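"""Count and normalized expression containers plus 10x-style triplet I/O.

Matrices are stored genes-by-cells: UMI counts for a given gene (row) in an
individual cell (column), the layout droplet pipelines emit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "read_counts_10x",
    "write_counts_10x",
]

MITO_PREFIX = "MT-"


@dataclass
class CountMatrix:
    """Integer UMI matrix (genes x cells) with identities and per-cell metadata.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, genes as rows, cells as columns.
    gene_ids, gene_symbols
        Per-gene identifiers; ``gene_symbols`` carries the human-readable
        symbols used for mitochondrial (``MT-``) detection and marker rules.
    barcodes
        Unique per-cell barcode strings.
    cell_meta
        Optional per-cell table (population labels, doublet flags, ...),
        indexed by barcode.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    gene_symbols: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes"
            )
        if len(self.gene_symbols) != len(self.gene_ids):
            raise ValueError("gene_ids and gene_symbols lengths differ")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")
        if self.counts.nnz and np.any(self.counts.data != np.round(self.counts.data)):
            raise ValueError("non-integer counts")
        self.counts = self.counts.astype(np.int64)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))
        else:
            self.cell_meta = self.cell_meta.copy()
            self.cell_meta.index = pd.Index(self.barcodes, name="barcode")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def total_counts(self) -> np.ndarray:
        """Total UMIs per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def detected_genes(self) -> np.ndarray:
        """Number of genes with count > 0 per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Fraction of UMIs from ``MT-`` genes per cell (0 where depth is 0)."""
        is_mito = np.array([str(s).startswith(MITO_PREFIX) for s in self.gene_symbols])
        total = self.total_counts().astype(float)
        mito = np.asarray(self.counts[is_mito].sum(axis=0)).ravel().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
        return frac

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        return CountMatrix(
            counts=self.counts[gm][:, cm],
            gene_ids=self.gene_ids[gm],
            gene_symbols=self.gene_symbols[gm],
            barcodes=self.barcodes[cm],
            cell_meta=self.cell_meta.loc[cm].copy(),
        )

    def copy(self) -> "CountMatrix":
        return replace(
            self,
            counts=self.counts.copy(),
            gene_ids=self.gene_ids.copy(),
            gene_symbols=self.gene_symbols.copy(),
            barcodes=self.barcodes.copy(),
            cell_meta=self.cell_meta.copy(),
        )


@dataclass
class NormalizedMatrix:
    """Natural-log, depth-scaled expression: ``ln(1 + count/total * scale)``.

    ``provenance`` accumulates a record per filter/transform applied so a run
    can state how many cells and genes each step removed.
    """

    values: np.ndarray
    gene_symbols: np.ndarray
    barcodes: np.ndarray
    scale_factor: float = 10_000.0
    provenance: list = field(default_factory=list)
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.values.shape != (len(self.gene_symbols), len(self.barcodes)):
            raise ValueError("values shape inconsistent with genes/barcodes")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_symbols == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not found")
        return int(idx[0])

    def subset_genes(self, genes) -> "NormalizedMatrix":
        idx = [self.gene_index(g) for g in genes]
        return NormalizedMatrix(
            values=self.values[idx],
            gene_symbols=self.gene_symbols[idx],
            barcodes=self.barcodes,
            scale_factor=self.scale_factor,
            provenance=list(self.provenance),
            cell_meta=self.cell_meta,
        )


def write_counts_10x(matrix: CountMatrix, path: str) -> None:
    """Write ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` under ``path``."""
    os.makedirs(path, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(path, "matrix.mtx"),
        sp.coo_matrix(matrix.counts),
        field="integer",
    )
    with open(os.path.join(path, "genes.tsv"), "w") as fh:
        for gid, sym in zip(matrix.gene_ids, matrix.gene_symbols):
            fh.write(f"{gid}\t{sym}\n")
    with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
        for bc in matrix.barcodes:
            fh.write(f"{bc}\n")


def read_counts_10x(path: str) -> CountMatrix:
    """Read a 10x-style triplet directory written by :func:`write_counts_10x`."""
    mtx = scipy.io.mmread(os.path.join(path, "matrix.mtx"))
    genes = pd.read_csv(
        os.path.join(path, "genes.tsv"), sep="\t", header=None, names=["id", "symbol"]
    )
    with open(os.path.join(path, "barcodes.tsv")) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    if mtx.shape[0] != len(genes):
        raise ValueError(
            f"matrix.mtx has {mtx.shape[0]} rows but genes.tsv lists {len(genes)} genes"
        )
    if mtx.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix.mtx has {mtx.shape[1]} cols but barcodes.tsv lists {len(barcodes)} barcodes"
        )
    return CountMatrix(
        counts=sp.csr_matrix(mtx),
        gene_ids=genes["id"].to_numpy(dtype=object),
        gene_symbols=genes["symbol"].to_numpy(dtype=object),
        barcodes=np.array(barcodes, dtype=object),
    )
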