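"""Ground-truthed UMI count simulation.

Emulates the cell composition of a differentiating hiPSC chondrogenic pellet:
several populations (chondrocyte subsets, neural cells, melanocytes,
mesenchyme) with population-restricted marker genes and secreted
ligand / receptor genes at controlled percent-expressing levels, planted
co-expression modules anchored on hub transcription factors, variable library
size, mitochondrial content with a low-quality tail, and injectable doublets.

Counts follow a gamma-Poisson (negative binomial) model with a shared
dispersion: gene g in cell c has mean

    mu_gc = baseline_g * marker_fold (if c's population carries g as marker)
            * exp(loading_g * z_{m,c}) (if g belongs to module m)
            * L_c (per-cell library factor, lognormal)

and counts ~ NB(mean=mu_gc, size=nb_dispersion). Dropout (zeros) arises
naturally from the count model; ligand / receptor genes are calibrated so
that the expected fraction of cells with count > 0 in their target
population matches a requested value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp

from .genesets import MITO_GENES
from .matrix import CountMatrix

__all__ = [
    "PopulationSpec",
    "ModuleSpec",
    "SimulationSpec",
    "GroundTruth",
    "simulate_counts",
    "inject_doublets",
    "simulate_barnyard",
]

# expressing fraction of a ligand/receptor gene outside its target population
_OFF_TARGET_FRACTION = 0.005


@dataclass
class PopulationSpec:
    """One simulated cell population.

    ``ligand_genes`` / ``receptor_genes`` map gene symbol to the target
    fraction of this population's cells expressing the gene (count > 0).
    """

    name: str
    proportion: float
    marker_genes: list = field(default_factory=list)
    marker_fold: float = 8.0
    ligand_genes: dict = field(default_factory=dict)
    receptor_genes: dict = field(default_factory=dict)
    # real populations differ across whole expression programs, not just a
    # handful of canonical markers: auto-named program genes get the same
    # fold shift and make populations separable the way real lineages are
    program_gene_count: int = 30

    @property
    def program_genes(self) -> list:
        slug = "".join(ch for ch in self.name.upper() if ch.isalnum())
        return [f"{slug}_P{i:03d}" for i in range(1, self.program_gene_count + 1)]

    @property
    def shifted_genes(self) -> list:
        """All genes carrying the population's fold shift."""
        return list(self.marker_genes) + self.program_genes

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError(f"proportion {self.proportion} outside [0,1]")
        if self.marker_fold < 1.0:
            raise ValueError("marker_fold must be >= 1")
        for d in (self.ligand_genes, self.receptor_genes):
            for g, f in d.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"expressing fraction {f} for {g} outside [0,1]")


@dataclass
class ModuleSpec:
    """A planted co-expression module driven by one latent factor per cell.

    Member genes are named ``<name>_G001`` ... except the hub, which keeps its
    own symbol, is flagged as a TF, and receives the maximal loading.
    """

    name: str
    gene_count: int = 50
    loading_range: tuple = (0.4, 0.8)
    hub_gene: str = ""

    def __post_init__(self) -> None:
        if self.gene_count < 5:
            raise ValueError("modules need at least 5 genes")
        lo, hi = self.loading_range
        if not (0 < lo <= hi):
            raise ValueError("loadings must be strictly positive, min <= max")
        if not self.hub_gene:
            self.hub_gene = f"{self.name}_HUB"

    @property
    def member_genes(self) -> list:
        members = [f"{self.name}_G{i:03d}" for i in range(1, self.gene_count)]
        return [self.hub_gene] + members


@dataclass
class SimulationSpec:
    n_cells: int = 2000
    n_genes: int = 2000
    populations: list = field(default_factory=list)
    modules: list = field(default_factory=list)
    mito_gene_count: int = 13
    baseline_mito_fraction: float = 0.02
    low_quality_cell_fraction: float = 0.0
    low_quality_mito_fraction: float = 0.15
    library_size_logmean: float = 0.0
    library_size_logsd: float = 0.3
    nb_dispersion: float = 2.0
    doublet_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def named_genes(self) -> dict:
        """gene symbol -> (role, owner) over all populations and modules.

        Raises on conflicting roles, e.g. the same gene planted as a marker
        of two populations.
        """
        roles: dict = {}

        def claim(gene: str, role: str, owner: str) -> None:
            if gene in roles:
                prev_role, prev_owner = roles[gene]
                raise ValueError(
                    f"gene {gene!r} assigned twice: {prev_role} of {prev_owner} "
                    f"and {role} of {owner}"
                )
            roles[gene] = (role, owner)

        for pop in self.populations:
            for g in pop.marker_genes:
                claim(g, "marker", pop.name)
            for g in pop.program_genes:
                claim(g, "marker", pop.name)
            for g in pop.ligand_genes:
                claim(g, "ligand", pop.name)
            for g in pop.receptor_genes:
                claim(g, "receptor", pop.name)
        for mod in self.modules:
            for g in mod.member_genes:
                role = "module_hub" if g == mod.hub_gene else "module"
                claim(g, role, mod.name)
        return roles

    def validate(self) -> None:
        if self.populations:
            total = sum(p.proportion for p in self.populations)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"population proportions sum to {total}, not 1")
        if not 0.0 <= self.doublet_rate < 0.5:
            raise ValueError("doublet_rate must be in [0, 0.5)")
        n_named = len(self.named_genes())
        if self.n_genes < n_named + self.mito_gene_count:
            raise ValueError(
                f"n_genes={self.n_genes} smaller than {n_named} named genes "
                f"+ {self.mito_gene_count} mitochondrial genes"
            )


@dataclass
class GroundTruth:
    """Per-cell and per-gene truth tables plus module latent factors."""

    cells: pd.DataFrame  # barcode-indexed: population, is_doublet, is_low_quality
    genes: pd.DataFrame  # symbol-indexed: module, role, population, target_fraction
    module_factors: pd.DataFrame = None  # type: ignore[assignment]  # cells x modules


def _nb_mean_for_fraction(p: float, size: float) -> float:
    """Mean mu with P(NB(mu, size) > 0) = p; closed-form inversion."""
    if p <= 0:
        return 0.0
    if p >= 1:
        raise ValueError("expressing fraction must be < 1")
    return size * ((1.0 - p) ** (-1.0 / size) - 1.0)


def _calibrate_mean(p: float, size: float, lib: np.ndarray) -> float:
    """Base mean mu so that mean_c[ P(NB(mu*L_c, size) > 0) ] = p.

    The per-cell library factors L_c scale the mean, so the closed-form
    inversion at L=1 is only a bracket anchor; the expectation over the
    realized factors is solved with brentq.
    """
    if p <= 0 or lib.size == 0 or np.all(lib == 0):
        return 0.0

    def realized(mu: float) -> float:
        with np.errstate(divide="ignore"):
            p0 = (size / (size + mu * lib)) ** size
        return float(np.mean(1.0 - p0)) - p

    anchor = _nb_mean_for_fraction(p, size)
    lo, hi = anchor * 1e-3, anchor
    while realized(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            return hi
    return float(scipy.optimize.brentq(realized, lo, hi, xtol=1e-12, rtol=1e-10))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    """Gamma-Poisson draw with mean ``mean`` and NB size parameter ``size``."""
    lam = rng.gamma(shape=size, scale=np.maximum(mean, 0.0) / size)
    return rng.poisson(lam)


def _gene_universe(spec: SimulationSpec) -> tuple:
    roles = spec.named_genes()
    mito = list(MITO_GENES[: spec.mito_gene_count])
    if spec.mito_gene_count > len(MITO_GENES):
        mito += [f"MT-SIM{i}" for i in range(spec.mito_gene_count - len(MITO_GENES))]
    named = [g for g in roles]
    n_filler = spec.n_genes - len(named) - len(mito)
    # background genes include the standard cell-cycle program symbols (as
    # plain baseline genes) so cycle scoring runs on simulated data
    from .genesets import G2M_GENES, S_GENES

    cycle = [g for g in S_GENES + G2M_GENES if g not in roles][:n_filler]
    filler = cycle + [f"GENE{i:05d}" for i in range(1, n_filler - len(cycle) + 1)]
    symbols = named + mito + filler
    return symbols, roles, set(mito)


def simulate_counts(spec: SimulationSpec) -> tuple:
    """Simulate a UMI count matrix with full ground truth.

    Returns ``(CountMatrix, GroundTruth)``. Deterministic for a fixed
    ``spec.seed``; all random streams derive from one splittable seed
    sequence. If ``spec.doublet_rate > 0`` doublets are appended via
    :func:`inject_doublets`.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    rng_pop, rng_lib, rng_z, rng_base, rng_counts, rng_lowq = rngs

    n_cells, n_genes = spec.n_cells, spec.n_genes
    size = spec.nb_dispersion
    symbols, roles, mito_set = _gene_universe(spec)
    sym_index = {g: i for i, g in enumerate(symbols)}

    # population assignment
    if spec.populations:
        props = np.array([p.proportion for p in spec.populations])
        pop_idx = rng_pop.choice(len(spec.populations), size=n_cells, p=props)
        pop_names = np.array([spec.populations[i].name for i in pop_idx], dtype=object)
    else:
        pop_idx = np.zeros(n_cells, dtype=int)
        pop_names = np.array(["bulk"] * n_cells, dtype=object)

    # library factors; -inf logmean degenerates to zero depth
    if np.isfinite(spec.library_size_logmean):
        lib = np.exp(
            rng_lib.normal(spec.library_size_logmean, spec.library_size_logsd, n_cells)
        )
    else:
        lib = np.zeros(n_cells)

    # baseline per-gene means (lognormal across genes), set so a typical
    # cell detects roughly half the gene panel — healthy cells sit well
    # inside the 200-7000 detected-genes QC window
    baseline = np.exp(rng_base.normal(-0.3, 0.6, n_genes))

    # mitochondrial budget: scale MT- means so the expected mito fraction
    # matches baseline_mito_fraction (low-quality cells elevated below)
    mito_mask = np.array([g in mito_set for g in symbols])
    non_mito_total = baseline[~mito_mask].sum()
    f0 = spec.baseline_mito_fraction
    if mito_mask.sum():
        mito_budget = f0 / max(1.0 - f0, 1e-12) * non_mito_total
        baseline[mito_mask] *= mito_budget / max(baseline[mito_mask].sum(), 1e-300)

    mean = np.tile(baseline[:, None], (1, n_cells))

    # markers: fold shift in the carrying population
    for k, pop in enumerate(spec.populations):
        cells = pop_idx == k
        for g in pop.shifted_genes:
            mean[sym_index[g], cells] *= pop.marker_fold

    # planted modules: one latent factor per module per cell; members are
    # drawn from the expressed end of the baseline distribution (network
    # analysis operates on well-detected genes, and low means would drown
    # the shared factor in counting noise)
    factors = {}
    for mod in spec.modules:
        z = rng_z.standard_normal(n_cells)
        factors[mod.name] = z
        lo, hi = mod.loading_range
        members = mod.member_genes
        loadings = np.empty(len(members))
        loadings[0] = hi  # hub gets the maximal loading
        loadings[1:] = rng_z.uniform(lo, hi, len(members) - 1)
        for g, w in zip(members, loadings):
            mean[sym_index[g]] = np.exp(rng_z.normal(1.0, 0.3))
            # divide out E[exp(w z)] so the loading does not inflate the mean
            mean[sym_index[g]] *= np.exp(w * z - 0.5 * w**2)

    mean *= lib[None, :]

    # low-quality cells: mito means boosted above the QC cutoff
    low_q = np.zeros(n_cells, dtype=bool)
    if spec.low_quality_cell_fraction > 0:
        n_low = int(round(spec.low_quality_cell_fraction * n_cells))
        low_q[rng_lowq.choice(n_cells, size=n_low, replace=False)] = True
        f1 = spec.low_quality_mito_fraction
        boost = (f1 / max(1 - f1, 1e-12)) / (f0 / max(1 - f0, 1e-12))
        mean[np.ix_(mito_mask, low_q)] *= boost

    # ligand/receptor genes: calibrate the expressing fraction per population
    target_fraction = {}
    for k, pop in enumerate(spec.populations):
        cells = pop_idx == k
        for g, frac in {**pop.ligand_genes, **pop.receptor_genes}.items():
            gi = sym_index[g]
            mu_on = _calibrate_mean(frac, size, lib[cells])
            mu_off = _nb_mean_for_fraction(_OFF_TARGET_FRACTION, size)
            mean[gi] = np.where(cells, mu_on, mu_off) * lib
            target_fraction[g] = frac

    counts = _nb_draw(rng_counts, mean, size)

    barcodes = np.array([f"CELL{i:06d}" for i in range(n_cells)], dtype=object)
    cell_meta = pd.DataFrame(
        {
            "population": pop_names,
            "is_doublet": False,
            "is_low_quality": low_q,
            "library_factor": lib,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    cm = CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=np.array(symbols, dtype=object),
        gene_symbols=np.array(symbols, dtype=object),
        barcodes=barcodes,
        cell_meta=cell_meta,
    )

    gene_truth = pd.DataFrame(
        index=pd.Index(symbols, name="gene"),
        data={
            "module": [roles.get(g, ("", ""))[1] if roles.get(g, ("", ""))[0] in ("module", "module_hub") else "" for g in symbols],
            "role": [roles.get(g, ("none", ""))[0] if g in roles else ("mito" if g in mito_set else "none") for g in symbols],
            "population": [roles.get(g, ("", ""))[1] if roles.get(g, ("", ""))[0] in ("marker", "ligand", "receptor") else "" for g in symbols],
            "target_fraction": [target_fraction.get(g, np.nan) for g in symbols],
        },
    )
    truth = GroundTruth(
        cells=cell_meta.copy(),
        genes=gene_truth,
        module_factors=pd.DataFrame(factors, index=cell_meta.index),
    )

    if spec.doublet_rate > 0:
        cm, truth = inject_doublets(cm, spec.doublet_rate, seed=spec.seed + 1, truth=truth)
    return cm, truth


def inject_doublets(
    counts: CountMatrix, rate: float, seed: int, truth: GroundTruth = None
) -> tuple:
    """Append ``round(rate * n_cells)`` doublet barcodes, each the sum of two
    distinct randomly chosen parent cells. Originals are retained and flags
    recorded; rate 0 returns the input unchanged (with flags)."""
    if not 0.0 <= rate < 0.5:
        raise ValueError("doublet rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n = counts.n_cells
    n_doublets = int(round(rate * n))

    cells = counts.cell_meta.copy()
    if "is_doublet" not in cells:
        cells["is_doublet"] = False
    if n_doublets == 0:
        out = counts.copy()
        out.cell_meta = cells
        if truth is None:
            truth = GroundTruth(cells=cells, genes=pd.DataFrame())
        return out, truth

    parents = np.stack(
        [rng.choice(n, size=2, replace=False) for _ in range(n_doublets)]
    )
    dbl_counts = counts.counts[:, parents[:, 0]] + counts.counts[:, parents[:, 1]]
    dbl_barcodes = np.array([f"DOUBLET{i:05d}" for i in range(n_doublets)], dtype=object)

    new_counts = sp.hstack([counts.counts, sp.csr_matrix(dbl_counts)]).tocsr()
    new_barcodes = np.concatenate([counts.barcodes, dbl_barcodes])
    dbl_meta = pd.DataFrame(index=pd.Index(dbl_barcodes, name="barcode"))
    for col in cells.columns:
        dbl_meta[col] = "doublet" if cells[col].dtype == object else False
    dbl_meta["is_doublet"] = True
    dbl_meta["parent_a"] = counts.barcodes[parents[:, 0]]
    dbl_meta["parent_b"] = counts.barcodes[parents[:, 1]]
    cells["parent_a"] = ""
    cells["parent_b"] = ""
    new_meta = pd.concat([cells, dbl_meta])

    out = CountMatrix(
        counts=new_counts,
        gene_ids=counts.gene_ids,
        gene_symbols=counts.gene_symbols,
        barcodes=new_barcodes,
        cell_meta=new_meta,
    )
    genes = truth.genes if truth is not None else pd.DataFrame()
    factors = truth.module_factors if truth is not None else None
    return out, GroundTruth(cells=new_meta.copy(), genes=genes, module_factors=factors)


def simulate_barnyard(spec: SimulationSpec, doublet_rate: float) -> tuple:
    """Two-species (1:1) mixing experiment for multiplet-rate estimation.

    Gene symbols carry ``hg_`` / ``mm_`` species prefixes over two disjoint
    blocks; each singlet draws counts only from its species' block. Exactly
    ``round(doublet_rate * n_cells)`` of the ``n_cells`` barcodes are
    doublets, formed by summing two extra singlet profiles chosen at random
    (cross- and same-species as the draw falls), so the realized doublet
    fraction equals the nominal rate and the expected cross-species fraction
    is ``doublet_rate / 2``.
    """
    if not 0.0 <= doublet_rate < 0.5:
        raise ValueError("doublet rate must be in [0, 0.5)")
    ss = np.random.SeedSequence(spec.seed)
    rng_lib, rng_base, rng_counts, rng_mix = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    n = spec.n_cells
    size = spec.nb_dispersion
    n_doublets = int(round(doublet_rate * n))
    n_singlets = n - n_doublets
    n_profiles = n_singlets + 2 * n_doublets

    half = spec.n_genes // 2
    symbols = [f"hg_GENE{i:05d}" for i in range(1, half + 1)] + [
        f"mm_GENE{i:05d}" for i in range(1, spec.n_genes - half + 1)
    ]
    species_of_gene = np.array([0] * half + [1] * (spec.n_genes - half))

    # species assigned 1:1 across profiles, then shuffled
    species = np.array([0, 1] * (n_profiles // 2) + [0] * (n_profiles % 2))
    rng_mix.shuffle(species)

    lib = (
        np.exp(rng_lib.normal(spec.library_size_logmean, spec.library_size_logsd, n_profiles))
        if np.isfinite(spec.library_size_logmean)
        else np.zeros(n_profiles)
    )
    baseline = np.exp(rng_base.normal(-1.0, 0.5, spec.n_genes))
    block = (species_of_gene[:, None] == species[None, :]).astype(float)
    mean = baseline[:, None] * block * lib[None, :]
    profiles = _nb_draw(rng_counts, mean, size)

    singlet_cols = profiles[:, :n_singlets]
    parent_a = np.arange(n_singlets, n_singlets + n_doublets)
    parent_b = np.arange(n_singlets + n_doublets, n_profiles)
    doublet_cols = profiles[:, parent_a] + profiles[:, parent_b]
    counts = np.concatenate([singlet_cols, doublet_cols], axis=1)

    barcodes = np.array(
        [f"BC{i:06d}" for i in range(n_singlets)]
        + [f"BCDBL{i:05d}" for i in range(n_doublets)],
        dtype=object,
    )
    is_doublet = np.array([False] * n_singlets + [True] * n_doublets)
    cross = np.concatenate(
        [np.zeros(n_singlets, bool), species[parent_a] != species[parent_b]]
    )
    species_label = np.array(
        ["hg" if s == 0 else "mm" for s in species[:n_singlets]]
        + ["doublet"] * n_doublets,
        dtype=object,
    )
    cell_meta = pd.DataFrame(
        {"species": species_label, "is_doublet": is_doublet, "is_cross_species": cross},
        index=pd.Index(barcodes, name="barcode"),
    )
    cm = CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=np.array(symbols, dtype=object),
        gene_symbols=np.array(symbols, dtype=object),
        barcodes=barcodes,
        cell_meta=cell_meta,
    )
    genes = pd.DataFrame(
        {"species": ["hg" if s == 0 else "mm" for s in species_of_gene]},
        index=pd.Index(symbols, name="gene"),
    )
    return cm, GroundTruth(cells=cell_meta.copy(), genes=genes)
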