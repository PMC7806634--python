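"""Shipped gene sets: cell-cycle phase markers, mitochondrial genes,
population signatures for annotation, and a demonstration WNT/FZD
ligand-receptor pair table.

The cell-cycle sets are the standard expression-program marker lists used by
droplet scRNA-seq toolchains: 43 S-phase and 54 G2/M-phase genes. The
population signatures cover the lineages arising during directed hiPSC
chondrogenesis, including the off-target neural and melanocyte populations.
Full curated ligand-receptor tables (thousands of pairs) are user-supplied
TSV; the shipped table is a small WNT-family demonstration set.
"""

from __future__ import annotations

import pandas as pd

# 43 S-phase markers
S_GENES = [
    "MCM5", "PCNA", "TYMS", "FEN1", "MCM2", "MCM4", "RRM1", "UNG", "GINS2",
    "MCM6", "CDCA7", "DTL", "PRIM1", "UHRF1", "MLF1IP", "HELLS", "RFC2",
    "RPA2", "NASP", "RAD51AP1", "GMNN", "WDR76", "SLBP", "CCNE2", "UBR7",
    "POLD3", "MSH2", "ATAD2", "RAD51", "RRM2", "CDC45", "CDC6", "EXO1",
    "TIPIN", "DSCC1", "BLM", "CASP8AP2", "USP1", "CLSPN", "POLA1", "CHAF1B",
    "BRIP1", "E2F8",
]

# 54 G2/M-phase markers
G2M_GENES = [
    "HMGB2", "CDK1", "NUSAP1", "UBE2C", "BIRC5", "TPX2", "TOP2A", "NDC80",
    "CKS2", "NUF2", "CKS1B", "MKI67", "TMPO", "CENPF", "TACC3", "FAM64A",
    "SMC4", "CCNB2", "CKAP2L", "CKAP2", "AURKB", "BUB1", "KIF11", "ANP32E",
    "TUBB4B", "GTSE1", "KIF20B", "HJURP", "CDCA3", "HN1", "CDC20", "TTK",
    "CDC25C", "KIF2C", "RANGAP1", "NCAPD2", "DLGAP5", "CDCA2", "CDCA8",
    "ECT2", "KIF23", "HMMR", "AURKA", "PSRC1", "ANLN", "LBR", "CKAP5",
    "CENPE", "CTCF", "NEK2", "G2E3", "GAS2L3", "CBX5", "CENPA",
]

# the 13 human mitochondrial protein-coding genes
MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]

# Broad population signatures for automated cluster annotation.
POPULATION_SIGNATURES = {
    "chondrocyte": ["SOX9", "COL2A1", "ACAN", "COMP"],
    "neural": ["SOX2", "PAX6", "OTX1", "OTX2", "NES"],
    "melanocyte": ["MITF"],
    "neural crest": ["PAX3", "FOXD3"],
    "mesenchyme": ["PRRX1", "COL1A1", "COL3A1"],
}

# Transcription factors among the lineage markers; default anchors for
# TF-neighborhood GRN construction.
TF_MARKERS = ["SOX9", "SOX2", "PAX6", "OTX1", "OTX2", "MITF", "PAX3", "FOXD3", "PRRX1"]

# Demonstration WNT ligand / frizzled receptor pairs.
DEMO_LR_PAIRS = [
    ("WNT3A", "FZD2"),
    ("WNT3A", "FZD4"),
    ("WNT2B", "FZD4"),
    ("WNT2B", "FZD2"),
    ("WNT5B", "FZD2"),
    ("WNT5B", "FZD5"),
    ("WNT4", "FZD2"),
    ("WNT7B", "FZD5"),
]


def demo_pair_table() -> pd.DataFrame:
    """The shipped WNT/FZD demonstration ligand-receptor pair table."""
    return pd.DataFrame(DEMO_LR_PAIRS, columns=["ligand", "receptor"]).assign(
        source="demo-wnt-fzd"
    )


def load_pair_table(path: str) -> pd.DataFrame:
    """Read a ligand<TAB>receptor pair table, rejecting duplicates."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :2]
    df.columns = ["ligand", "receptor"]
    # tolerate a header row
    if str(df.iloc[0, 0]).lower() == "ligand":
        df = df.iloc[1:].reset_index(drop=True)
    if df.duplicated().any():
        raise ValueError("duplicate ligand-receptor pairs in table")
    if (df["ligand"].str.len() == 0).any() or (df["receptor"].str.len() == 0).any():
        raise ValueError("empty gene names in pair table")
    return df.assign(source=path)
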