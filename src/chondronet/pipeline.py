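"""Config-driven orchestration: simulate -> QC -> normalize -> cell cycle /
regression -> cluster -> markers -> co-expression network -> GRN hubs ->
ligand-receptor signaling, with a provenance manifest.

The run configuration is validated against a strict schema (unknown keys
rejected) before any stage executes; every stage's outputs are hashed so a
rerun with the same config and seed can be checked for bit-identical
results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import cluster as _cluster
from . import grn as _grn
from . import network as _network
from . import preprocess as _pre
from . import signaling as _sig
from .genesets import demo_pair_table, load_pair_table
from .matrix import CountMatrix, read_counts_10x, write_counts_10x
from .simulate import (
    ModuleSpec,
    PopulationSpec,
    SimulationSpec,
    simulate_barnyard,
    simulate_counts,
)

logger = logging.getLogger("chondronet")

__all__ = [
    "RunConfig",
    "RunManifest",
    "run_pipeline",
    "make_fixture",
    "demo_simulation_spec",
    "FIXTURE_NAMES",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    enabled: bool = True
    n_cells: int = 1500
    n_genes: int = 1500
    doublet_rate: float = 0.0
    low_quality_cell_fraction: float = 0.05


class QCConfig(_Strict):
    min_genes: int = 200
    max_genes: int = 7000
    max_mito_fraction: float = 0.05
    min_cells_per_gene: int = 3


class RegressConfig(_Strict):
    enabled: bool = True


class ClusterConfig(_Strict):
    n_hvg: int = 1000
    n_pcs: int = 20
    k_neighbors: int = 30
    resolution: float = 0.6


class NetworkStageConfig(_Strict):
    enabled: bool = True
    n_genes: int = 0  # cap on network genes (top HVGs); 0 = full gene panel
    beta: int = 8
    auto_beta: bool = False
    merge_cut_height: float = 0.25
    min_module_size: int = 30


class GRNConfig(_Strict):
    enabled: bool = True
    n_top: int = 100
    top_k: int = 5
    tf_list: list = Field(default_factory=list)  # empty -> simulated hub TFs


class LRConfig(_Strict):
    enabled: bool = True
    pair_table: str = ""  # empty -> shipped WNT/FZD demo table
    lnfc_min: float = 0.25
    min_pct: float = 0.0


class RunConfig(_Strict):
    seed: int = 0
    input_path: str = ""  # 10x triplet directory; empty -> simulate
    output_path: str = "chondronet_run"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    qc: QCConfig = Field(default_factory=QCConfig)
    regress: RegressConfig = Field(default_factory=RegressConfig)
    cluster: ClusterConfig = Field(default_factory=ClusterConfig)
    network: NetworkStageConfig = Field(default_factory=NetworkStageConfig)
    grn: GRNConfig = Field(default_factory=GRNConfig)
    lr: LRConfig = Field(default_factory=LRConfig)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


class RunManifest(dict):
    """Per-stage parameter snapshots, output hashes and survivor counts."""

    def stage_hashes(self) -> dict:
        return {
            stage: info.get("hashes", {})
            for stage, info in self.items()
            if isinstance(info, dict)
        }


def _sha256_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_array(arr) -> str:
    return _sha256_bytes(np.ascontiguousarray(arr).tobytes())


def demo_simulation_spec(
    n_cells: int = 1500,
    n_genes: int = 1500,
    seed: int = 0,
    doublet_rate: float = 0.0,
    low_quality_cell_fraction: float = 0.05,
) -> SimulationSpec:
    """The default demonstration pellet: five populations with
    population-restricted WNT ligands and FZD receptors, plus two planted
    co-expression modules anchored on hub TFs."""
    populations = [
        PopulationSpec(
            name="chondrocyte",
            proportion=0.40,
            marker_genes=["SOX9", "COL2A1", "ACAN", "COMP"],
            ligand_genes={"WNT5B": 0.10},
            receptor_genes={"FZD2": 0.32},
        ),
        PopulationSpec(
            name="neural",
            proportion=0.20,
            marker_genes=["SOX2", "PAX6", "OTX1", "OTX2", "NES"],
            ligand_genes={"WNT3A": 0.10, "WNT4": 0.15, "WNT7B": 0.12},
        ),
        PopulationSpec(
            name="melanocyte",
            proportion=0.10,
            marker_genes=["MITF"],
            ligand_genes={"WNT2B": 0.30},
            receptor_genes={"FZD5": 0.30},
        ),
        PopulationSpec(
            name="neural crest",
            proportion=0.10,
            marker_genes=["PAX3", "FOXD3"],
        ),
        PopulationSpec(
            name="mesenchyme",
            proportion=0.20,
            marker_genes=["PRRX1", "COL1A1", "COL3A1"],
        ),
    ]
    modules = [
        ModuleSpec(name="NEURO", gene_count=50, loading_range=(0.4, 0.8), hub_gene="NEURO_TF"),
        ModuleSpec(name="MELANO", gene_count=50, loading_range=(0.4, 0.8), hub_gene="MELANO_TF"),
    ]
    return SimulationSpec(
        n_cells=n_cells,
        n_genes=n_genes,
        populations=populations,
        modules=modules,
        low_quality_cell_fraction=low_quality_cell_fraction,
        doublet_rate=doublet_rate,
        seed=seed,
    )


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all enabled stages in dependency order; write stage outputs
    and a ``manifest.json`` under ``config.output_path``."""
    t0 = time.time()
    out = config.output_path
    os.makedirs(out, exist_ok=True)
    manifest = RunManifest()

    def record(stage: str, params: dict, hashes: dict, **counts) -> None:
        manifest[stage] = {"params": params, "hashes": hashes, **counts}
        logger.info("stage %s done: %s", stage, counts)

    # --- input: simulate or read -------------------------------------------
    truth = None
    if config.input_path:
        cm = read_counts_10x(config.input_path)
        record("input", {"path": config.input_path}, {"counts": _hash_array(cm.counts.toarray())},
               n_cells=cm.n_cells, n_genes=cm.n_genes)
    else:
        spec = demo_simulation_spec(
            n_cells=config.simulate.n_cells,
            n_genes=config.simulate.n_genes,
            seed=config.seed,
            doublet_rate=config.simulate.doublet_rate,
            low_quality_cell_fraction=config.simulate.low_quality_cell_fraction,
        )
        cm, truth = simulate_counts(spec)
        truth.cells.to_csv(os.path.join(out, "truth_cells.tsv"), sep="\t")
        truth.genes.to_csv(os.path.join(out, "truth_genes.tsv"), sep="\t")
        record(
            "simulate",
            config.simulate.model_dump(),
            {
                "counts": _hash_array(cm.counts.toarray()),
                "truth_cells": _sha256_file(os.path.join(out, "truth_cells.tsv")),
            },
            n_cells=cm.n_cells,
            n_genes=cm.n_genes,
        )

    # --- QC ----------------------------------------------------------------
    thresholds = _pre.QCThresholds(**config.qc.model_dump())
    filtered, prov = _pre.apply_cell_qc(cm, thresholds)
    with open(os.path.join(out, "qc_provenance.json"), "w") as fh:
        json.dump(prov, fh, indent=1)
    record("qc", config.qc.model_dump(),
           {"counts": _hash_array(filtered.counts.toarray())},
           n_cells=filtered.n_cells, n_genes=filtered.n_genes)

    # --- normalize + optional covariate regression -------------------------
    norm = _pre.log_normalize(filtered)
    record("normalize", {"scale_factor": norm.scale_factor},
           {"values": _hash_array(norm.values)}, n_cells=norm.n_cells)

    # variable genes are chosen on the normalized data, before regression
    # (the dispersion statistic assumes non-negative back-transformed values)
    hvgs = _pre.select_hvg(norm, n_hvg=config.cluster.n_hvg)

    if config.regress.enabled:
        try:
            cc = _pre.score_cell_cycle(norm, seed=config.seed)
            covariates = pd.DataFrame(
                {"s_score": cc.s_score, "g2m_score": cc.g2m_score,
                 "mito_fraction": filtered.mito_fraction()}
            )
            cc.to_frame().to_csv(os.path.join(out, "cell_cycle.tsv"), sep="\t")
        except ValueError:
            # cycle gene programs absent from the matrix: regress mito only
            covariates = pd.DataFrame({"mito_fraction": filtered.mito_fraction()})
        norm = _pre.regress_out(norm, covariates)
        record("regress", {"covariates": list(covariates.columns)},
               {"values": _hash_array(norm.values)})

    # --- embedding, clustering, markers, annotation ------------------------
    embedding = _cluster.embed_cells(norm, hvgs, n_pcs=config.cluster.n_pcs)
    assignment = _cluster.cluster_cells(
        embedding,
        k_neighbors=config.cluster.k_neighbors,
        resolution=config.cluster.resolution,
        seed=config.seed,
        barcodes=norm.barcodes,
    )
    labels_df = pd.DataFrame(
        {"cluster": assignment.labels}, index=pd.Index(norm.barcodes, name="barcode")
    )
    markers = _cluster.find_markers(norm, assignment)
    annotation, scores = _cluster.annotate_clusters(markers)
    labels_df["population"] = [annotation.get(c, "unassigned") for c in assignment.labels]
    labels_df.to_csv(os.path.join(out, "clusters.tsv"), sep="\t")
    markers.to_csv(os.path.join(out, "markers.tsv"), sep="\t", index=False)
    scores.to_csv(os.path.join(out, "annotation_scores.tsv"), sep="\t")
    record("cluster", config.cluster.model_dump(),
           {"clusters": _sha256_file(os.path.join(out, "clusters.tsv")),
            "markers": _sha256_file(os.path.join(out, "markers.tsv"))},
           n_clusters=assignment.n_clusters, n_markers=len(markers))

    # --- co-expression network + GRN hubs ----------------------------------
    hub_table = pd.DataFrame()
    if config.network.enabled:
        net_input = (
            norm.subset_genes(list(hvgs[: config.network.n_genes]))
            if config.network.n_genes
            else norm
        )
        builder = _network.CoexpressionNetworkBuilder(
            beta=config.network.beta,
            auto_beta=config.network.auto_beta,
            merge_cut_height=config.network.merge_cut_height,
            min_module_size=config.network.min_module_size,
        ).fit(net_input)
        module_rows = [
            {"gene": g, "module": m.label}
            for m in builder.modules_
            for g in m.genes
        ]
        pd.DataFrame(module_rows, columns=["gene", "module"]).to_csv(
            os.path.join(out, "modules.tsv"), sep="\t", index=False
        )
        record("network", config.network.model_dump(),
               {"modules": _sha256_file(os.path.join(out, "modules.tsv")),
                "tom": _hash_array(builder.network_.tom)},
               n_modules=len(builder.modules_), beta=builder.beta_)

        if config.grn.enabled and builder.modules_:
            tf_list = list(config.grn.tf_list)
            if not tf_list:
                from .genesets import TF_MARKERS

                tf_list = list(TF_MARKERS)
                if truth is not None:
                    tf_list += list(truth.genes.index[truth.genes["role"] == "module_hub"])
            tables = []
            for module in builder.modules_:
                if not set(tf_list) & set(module.genes):
                    continue
                g = _grn.select_tf_neighborhoods(
                    builder.network_, module, tf_list, n_top=config.grn.n_top
                )
                _grn.community_cluster(g, seed=config.seed)
                tbl = _grn.hub_scores(g, top_k=config.grn.top_k)
                tbl["module"] = module.label
                tables.append(tbl)
            if tables:
                hub_table = pd.concat(tables)
                hub_table.to_csv(os.path.join(out, "hubs.tsv"), sep="\t")
                record("grn", config.grn.model_dump(),
                       {"hubs": _sha256_file(os.path.join(out, "hubs.tsv"))},
                       n_hub_tables=len(tables))

    # --- ligand-receptor signaling -----------------------------------------
    if config.lr.enabled:
        pairs = (
            load_pair_table(config.lr.pair_table)
            if config.lr.pair_table
            else demo_pair_table()
        )
        cell_pops = labels_df["population"].to_numpy(dtype=object)
        interactions = _sig.build_interaction_table(
            filtered, norm, cell_pops, pairs,
            lnfc_min=config.lr.lnfc_min, min_pct=config.lr.min_pct,
        )
        edges = _sig.population_edge_summary(interactions)
        interactions.to_csv(os.path.join(out, "interactions.tsv"), sep="\t", index=False)
        edges.to_csv(os.path.join(out, "population_edges.tsv"), sep="\t", index=False)
        record("lr", config.lr.model_dump(),
               {"interactions": _sha256_file(os.path.join(out, "interactions.tsv"))},
               n_interactions=len(interactions))

    manifest["run"] = {
        "seed": config.seed,
        "elapsed_s": round(time.time() - t0, 2),
        "config": config.model_dump(),
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


# ---------------------------------------------------------------------------
# fixture registry
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "qc_toy",
    "gene_filter_toy",
    "tom_toy",
    "star_graph",
    "lr_planted",
    "barnyard_3pct",
    "modules_planted",
)


def _qc_toy() -> CountMatrix:
    """5 cells with detected-gene counts {150, 200, 500, 7000, 7500} and
    mito fractions {0, 0, ~0.06, 0, 0}: only the 200- and 7000-gene cells
    survive the cell filter under the shipped thresholds."""
    from .genesets import MITO_GENES

    n_genes = 7501  # 7500 regular + 1 mitochondrial
    detected = [150, 200, 500, 7000, 7500]
    counts = np.zeros((n_genes, 5), dtype=int)
    for j, d in enumerate(detected):
        counts[1 : d + 1, j] = 1  # row 0 reserved for the MT gene
    # third cell: mito UMIs pushing its fraction just above 5%
    counts[0, 2] = 32  # 32 / (500 + 32) ~ 0.0601
    symbols = [MITO_GENES[0]] + [f"G{i:05d}" for i in range(1, n_genes)]
    return CountMatrix(
        counts=counts,
        gene_ids=np.array(symbols, dtype=object),
        gene_symbols=np.array(symbols, dtype=object),
        barcodes=np.array([f"C{j}" for j in range(5)], dtype=object),
    )


def _gene_filter_toy() -> CountMatrix:
    """6 healthy cells; gene GA detected in 3 cells (kept), GB in 2
    (removed), plus 300 background genes in all cells."""
    rng = np.random.default_rng(7)
    n_bg, n_cells = 300, 6
    counts = np.zeros((n_bg + 2, n_cells), dtype=int)
    counts[:n_bg] = rng.poisson(2.0, (n_bg, n_cells)) + 1
    counts[n_bg, :3] = 5  # GA: 3 cells
    counts[n_bg + 1, :2] = 5  # GB: 2 cells
    symbols = [f"BG{i:04d}" for i in range(n_bg)] + ["GA", "GB"]
    return CountMatrix(
        counts=counts,
        gene_ids=np.array(symbols, dtype=object),
        gene_symbols=np.array(symbols, dtype=object),
        barcodes=np.array([f"C{j}" for j in range(n_cells)], dtype=object),
    )


def _tom_toy() -> np.ndarray:
    a = np.ones((3, 3))
    a[0, 1] = a[1, 0] = 0.5
    a[0, 2] = a[2, 0] = 0.2
    a[1, 2] = a[2, 1] = 0.4
    return a


def _star_graph():
    import networkx as nx

    from .grn import GRNGraph

    G = nx.Graph()
    for leaf in ["L1", "L2", "L3", "L4"]:
        G.add_edge("CENTER", leaf, weight=0.5)
    for n in G.nodes:
        G.nodes[n]["is_tf"] = n == "CENTER"
    return GRNGraph(graph=G, tf_genes=["CENTER"])


def lr_planted_spec(seed: int = 0, n_cells: int = 1000) -> SimulationSpec:
    """Three populations with exactly three directed WNT/FZD interactions,
    including the 10%-sender / ~30%-receiver geometry."""
    populations = [
        PopulationSpec(
            name="chondrocyte", proportion=0.5,
            marker_genes=["SOX9", "COL2A1"],
            ligand_genes={"WNT5B": 0.10},
            receptor_genes={"FZD2": 0.30, "FZD4": 0.15},
        ),
        PopulationSpec(
            name="neural", proportion=0.3,
            marker_genes=["SOX2", "PAX6"],
            ligand_genes={"WNT3A": 0.10},
        ),
        PopulationSpec(
            name="melanocyte", proportion=0.2,
            marker_genes=["MITF"],
            ligand_genes={"WNT2B": 0.30},
            receptor_genes={"FZD5": 0.30},
        ),
    ]
    return SimulationSpec(
        n_cells=n_cells, n_genes=300, populations=populations, modules=[], seed=seed
    )


LR_PLANTED_PAIRS = pd.DataFrame(
    [("WNT3A", "FZD2"), ("WNT2B", "FZD4"), ("WNT5B", "FZD5")],
    columns=["ligand", "receptor"],
)

# the directed truth for lr_planted: (ligand, receptor, sender, receiver)
LR_PLANTED_TRUTH = {
    ("WNT3A", "FZD2", "neural", "chondrocyte"),
    ("WNT2B", "FZD4", "melanocyte", "chondrocyte"),
    ("WNT5B", "FZD5", "chondrocyte", "melanocyte"),
}


def modules_planted_spec(seed: int = 0, n_cells: int = 500, loading: float = 0.8) -> SimulationSpec:
    modules = [
        ModuleSpec(name=f"MOD{i}", gene_count=50, loading_range=(loading, loading),
                   hub_gene=f"MOD{i}_TF")
        for i in range(1, 5)
    ]
    return SimulationSpec(
        n_cells=n_cells, n_genes=500, populations=[], modules=modules, seed=seed
    )


def make_fixture(name: str, path: str = None):
    """Deterministic toy datasets backing the documented examples.

    Returns the in-memory object(s); when ``path`` is given, on-disk copies
    are written (10x triplet for count matrices, TSV otherwise).
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    if name == "qc_toy":
        obj = _qc_toy()
    elif name == "gene_filter_toy":
        obj = _gene_filter_toy()
    elif name == "tom_toy":
        obj = _tom_toy()
    elif name == "star_graph":
        obj = _star_graph()
    elif name == "lr_planted":
        obj = simulate_counts(lr_planted_spec())
    elif name == "barnyard_3pct":
        obj = simulate_barnyard(SimulationSpec(n_cells=2000, n_genes=200, seed=0), 0.03)
    else:  # modules_planted
        obj = simulate_counts(modules_planted_spec())

    if path is not None:
        os.makedirs(path, exist_ok=True)
        if isinstance(obj, CountMatrix):
            write_counts_10x(obj, path)
        elif isinstance(obj, tuple) and isinstance(obj[0], CountMatrix):
            write_counts_10x(obj[0], path)
            obj[1].cells.to_csv(os.path.join(path, "truth_cells.tsv"), sep="\t")
            obj[1].genes.to_csv(os.path.join(path, "truth_genes.tsv"), sep="\t")
        elif isinstance(obj, np.ndarray):
            np.savetxt(os.path.join(path, f"{name}.tsv"), obj, delimiter="\t")
        else:
            obj.edge_table().to_csv(os.path.join(path, f"{name}_edges.tsv"),
                                    sep="\t", index=False)
    return obj
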