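"""Directed heterocellular ligand-receptor signaling inference.

For every curated ligand-receptor pair and every ordered (sender, receiver)
population combination, an interaction is reported when the ligand is
specifically expressed in the sender and the receptor in the receiver —
both exceeding a natural-log fold change of 0.25 versus all other cells.
Percent-expressing values (fraction of cells with raw count > 0) quantify
how much of each population participates, matching the detection-frequency
convention of droplet data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cluster import log_fold_change
from .matrix import CountMatrix, NormalizedMatrix

__all__ = [
    "percent_expressing",
    "population_lnfc",
    "build_interaction_table",
    "population_edge_summary",
]


def _population_mask(labels, population) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    mask = labels == population
    if not mask.any():
        raise KeyError(f"population {population!r} not found or empty")
    return mask


def percent_expressing(counts: CountMatrix, labels, gene: str, population) -> float:
    """Fraction of the population's cells with raw count > 0 for ``gene``."""
    idx = np.flatnonzero(counts.gene_symbols == gene)
    if idx.size == 0:
        raise KeyError(f"gene {gene!r} not found")
    mask = _population_mask(labels, population)
    row = np.asarray(counts.counts[int(idx[0])].todense()).ravel()
    return float((row[mask] > 0).mean())


def population_lnfc(norm: NormalizedMatrix, labels, gene: str, population) -> float:
    """Natural-log fold change of ``gene`` in the population versus all other
    cells, on back-transformed means (same convention as marker detection)."""
    gi = norm.gene_index(gene)
    mask = _population_mask(labels, population)
    if mask.all():
        raise ValueError("population complement is empty")
    return float(log_fold_change(norm.values[gi, mask], norm.values[gi, ~mask]))


def build_interaction_table(
    counts: CountMatrix,
    norm: NormalizedMatrix,
    labels,
    pairs: pd.DataFrame,
    lnfc_min: float = 0.25,
    min_pct: float = 0.0,
) -> pd.DataFrame:
    """Directed (sender population, ligand) -> (receiver population, receptor)
    interaction records.

    A record is emitted iff the ligand passes the ln-FC specificity filter in
    the sender AND the receptor passes it in the receiver (each > ``lnfc_min``
    versus all other cells), with percent-expressing at least ``min_pct`` on
    both sides. Pairs whose genes are absent from the matrix are skipped.
    Sorted by pct_sender * pct_receiver descending.
    """
    if pairs is None or len(pairs) == 0:
        raise ValueError("empty ligand-receptor pair table")
    labels = np.asarray(labels, dtype=object)
    populations = sorted(set(labels.tolist()))
    present = set(norm.gene_symbols.astype(str))
    genes_needed = sorted(
        ({*pairs["ligand"], *pairs["receptor"]} & present)
    )
    # per-gene, per-population statistics computed once
    pct = {}
    lnfc = {}
    for g in genes_needed:
        for p in populations:
            pct[(g, p)] = percent_expressing(counts, labels, g, p)
            lnfc[(g, p)] = population_lnfc(norm, labels, g, p)

    records = []
    for _, row in pairs.iterrows():
        lig, rec = str(row["ligand"]), str(row["receptor"])
        if lig not in present or rec not in present:
            continue
        for sender in populations:
            if lnfc[(lig, sender)] <= lnfc_min or pct[(lig, sender)] < min_pct:
                continue
            for receiver in populations:
                if lnfc[(rec, receiver)] <= lnfc_min or pct[(rec, receiver)] < min_pct:
                    continue
                records.append(
                    {
                        "ligand": lig,
                        "receptor": rec,
                        "sender": sender,
                        "receiver": receiver,
                        "pct_sender": pct[(lig, sender)],
                        "pct_receiver": pct[(rec, receiver)],
                        "lnfc_sender": lnfc[(lig, sender)],
                        "lnfc_receiver": lnfc[(rec, receiver)],
                    }
                )
    df = pd.DataFrame(
        records,
        columns=[
            "ligand", "receptor", "sender", "receiver",
            "pct_sender", "pct_receiver", "lnfc_sender", "lnfc_receiver",
        ],
    )
    if len(df):
        df = df.assign(_score=df["pct_sender"] * df["pct_receiver"]).sort_values(
            "_score", ascending=False
        ).drop(columns="_score").reset_index(drop=True)
    return df


def population_edge_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate qualifying pairs per ordered population pair: count of
    ligand-receptor pairs and summed pct product (chord-diagram-ready)."""
    cols = ["sender", "receiver", "n_pairs", "pct_product_sum"]
    if records is None or len(records) == 0:
        return pd.DataFrame(columns=cols)
    grouped = (
        records.assign(pct_product=records["pct_sender"] * records["pct_receiver"])
        .groupby(["sender", "receiver"], as_index=False)
        .agg(n_pairs=("ligand", "size"), pct_product_sum=("pct_product", "sum"))
    )
    return grouped[cols]
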