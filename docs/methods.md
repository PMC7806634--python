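# Methods

This note states the statistical models and numerical conventions
implemented in `chondronet`, the shipped parameter defaults and their
rationale, and what the simulator does and does not emulate. It makes no
empirical claims beyond what `tests/` and `scripts/acceptance.py` compute.

## 1. Count model and simulation

UMI counts follow a gamma–Poisson (negative binomial) model. Gene *g* in
cell *c* has mean

```
mu_gc = b_g · F_g(c) · M_g(c) · L_c
```

where `b_g ~ LogNormal(-0.3, 0.6)` is the gene baseline, `F_g(c)` is the
population fold shift (`marker_fold`, default 8) when the cell's population
carries *g* in its expression program, `M_g(c) = exp(w_g z_mc − w_g²/2)` is
the planted-module effect for module latent factor `z_mc ~ N(0,1)` and
loading `w_g` (the `−w²/2` term keeps the expected fold at 1), and
`L_c ~ LogNormal(0, 0.3)` is the per-cell library factor. Counts are drawn
as `Poisson(Gamma(size, mu/size))` with a shared dispersion `size = 2`;
zeros (dropout) arise from the count model itself, with
`P(X = 0) = (size/(size+mu))^size`.

Design choices worth stating:

- **Populations differ by programs, not only canonical markers.** Each
  population carries `program_gene_count` (default 30) auto-named genes with
  the same fold shift, because real lineages are separated by whole
  expression programs; with only a handful of marker genes no clustering
  method recovers the mixture from counts.
- **Module members are well expressed.** Module gene baselines are drawn
  from `LogNormal(1.0, 0.3)`; at low baselines the shared latent factor is
  drowned in counting noise and co-expression analysis is not meaningful.
  The hub gene receives the maximal loading of the module's range.
- **Ligand/receptor calibration.** For a target expressing fraction *p* in
  a population, the base mean solves
  `mean_c[1 − (size/(size+mu·L_c))^size] = p` over the realized library
  factors (Brent root-finding bracketed by the closed-form inversion at
  `L = 1`); outside the target population the expressing fraction is 0.005.
- **Doublets.** `inject_doublets` appends `round(rate·n)` barcodes, each the
  sum of two distinct parents. `simulate_barnyard` builds a 1:1 two-species
  mixture in which exactly `round(rate·n)` of the *n* barcodes are doublets,
  so the realized rate equals the nominal rate and the expected
  cross-species fraction is `rate/2`.

**Not emulated:** ambient RNA/index hopping, batch effects, UMI saturation,
gene-length or GC bias, transcriptional bursting beyond NB dispersion,
cell-cycle-driven expression changes (cycle genes are present as plain
baseline genes so scoring runs, but phases are not planted), and spatial or
temporal structure.

## 2. Preprocessing

- **Barcode calling:** keep barcodes with ≥ 10% of the 99th-percentile UMI
  count of the top `expected_cells` barcodes.
- **Cell QC (strict inequalities):** remove cells with fewer than 200 or
  more than 7000 detected genes, or more than 5% mitochondrial UMIs
  (`MT-` symbols); then remove genes detected in fewer than 3 remaining
  cells. Boundary cells (exactly 200 or 7000 genes, exactly 5% mito) are
  retained. Both removals are recorded in a provenance log.
- **Normalization:** `x = ln(1 + count/total · 10000)`, so
  `Σ_g (e^x − 1) = 10000` exactly for every cell with nonzero depth. A gene
  with 100 of a cell's 10,000 counts maps to `ln(101) ≈ 4.6151`.
- **HVG selection:** per-gene mean and dispersion (variance/mean) of the
  back-transformed expression `e^x − 1`; dispersions z-scored within 20
  equal-frequency mean bins; top genes by z (ties by symbol). Binning
  removes the mean–dispersion trend so variable genes are found at every
  expression level.
- **Cell-cycle scores:** mean expression of the 43 S-phase / 54 G2M-phase
  program genes minus the mean of 50 control genes per program gene sampled
  from the same average-expression bin (25 bins, seeded); phase is the
  argmax program, G1 when both scores are ≤ 0.
- **Regression:** per-gene OLS on per-cell covariates (cycle scores,
  mitochondrial fraction); output is residual plus gene mean. Collinear
  covariate columns are dropped with a warning.
- **Multiplet rate:** in a 1:1 two-species mixture a barcode is
  cross-species when its majority-species fraction is below 0.9; because
  same-species collisions are invisible, the inferred total rate is twice
  the cross-species rate.

## 3. Clustering and markers

PCA operates on z-scored gene rows clipped at ±10 (clipping bounds the
influence of extreme cells); components carry a deterministic sign
convention. The SNN graph reweights k-nearest-neighbor edges (k = 30,
self-inclusive sets) by Jaccard overlap and prunes edges below 1/15;
communities are found by Leiden refinement of the modularity objective at
resolution 0.6 with a fixed seed, and labels are renumbered by decreasing
cluster size.

Markers are one-vs-rest Wilcoxon rank-sum tests, reported only when the
gene is expressed in ≥ 25% of the cluster's cells **and** the natural-log
fold change exceeds 0.25. The fold-change convention is
`ln(mean(e^x − 1) + 1)_in − ln(mean(e^x − 1) + 1)_out` — back-transformed
means, not means of logs. P-values are Bonferroni-adjusted by the number of
genes. Exact p-values are used when both groups have ≤ 8 cells, the
tie-corrected normal approximation otherwise. Cluster annotation assigns
the signature with the maximal mean marker fold change; ties or
all-nonpositive scores yield "unassigned".

## 4. Co-expression network

Signed adjacency `a_ij = ((1 + cor_ij)/2)^β` (Pearson, across cells)
suppresses negative correlations smoothly; β defaults to 8. The
soft-threshold scan reports, per candidate power 1–20, the signed scale-free
fit `R²` (log10 frequency vs log10 mean connectivity over 10 equal-width
connectivity bins; sign flipped if the slope is positive) and the mean
connectivity; the smallest power reaching `R² ≥ 0.8` is chosen, falling
back to 8 with a warning. Mean connectivity is strictly decreasing in the
power by construction (`a < 1` off the diagonal).

The unsigned topological overlap, with the diagonal excluded from all sums,
is

```
TOM_ij = (Σ_u a_iu·a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),  TOM_ii = 1.
```

For the toy adjacency `a12 = 0.5, a13 = 0.2, a23 = 0.4`:
`TOM_12 = (0.2·0.4 + 0.5)/(min(0.7, 0.9) + 1 − 0.5) = 0.58/1.2 ≈ 0.4833`.

Modules are average-linkage clusters of `1 − TOM` cut at height 0.99, kept
at ≥ 30 genes, and merged iteratively (closest pair first) while any two
module eigengenes — the sign-oriented first principal component of the
z-scored member expression — correlate above `1 − merge_cut_height = 0.75`.
Surviving modules are labeled 1, 2, ... by decreasing size; unassigned genes
carry label 0.

## 5. GRN hubs

Within a module, each transcription factor's neighborhood is its top-100
module genes by adjacency weight; the union graph additionally keeps
gene–gene edges with weight ≥ 0.02 (`edge_floor`, which removes the dense
floor of near-zero weights that would otherwise swamp betweenness).
Communities come from weighted modularity optimization (seeded). Hubs are
ranked by the mean of three dense ranks — strength (summed edge weights),
degree (edge count), and unnormalized betweenness centrality on the
unweighted edge set — so the three centrality notions contribute equally
regardless of scale; the `top_k = 5` lowest combined ranks are flagged.

## 6. Ligand–receptor model

`percent_expressing` is the fraction of a population's cells with **raw
count > 0** — the detection-frequency convention of droplet data, computed
on counts, not normalized values. A directed interaction
(sender, ligand) → (receiver, receptor) is reported when both genes pass the
ln-fold-change specificity gate (> 0.25 versus all other cells, same
convention as markers) in their respective populations; autocrine edges
(sender = receiver) are allowed. Records are sorted by
`pct_sender · pct_receiver`, and `population_edge_summary` aggregates pair
counts and summed pct products per ordered population pair.

## 7. Pipeline and determinism

`run_pipeline` validates a strict pydantic config (unknown keys rejected),
runs the stages in dependency order, and writes per-stage outputs plus a
`manifest.json` with SHA-256 hashes of every artifact. All randomness —
simulation, control-gene sampling, graph clustering — derives from the
config seed through splittable seed sequences or explicit seed arguments,
so a rerun with the same config is bit-identical (checked by acceptance
test 12). HVGs are selected before covariate regression because the
dispersion statistic assumes non-negative back-transformed values.

## 8. Limitations

- Thresholds (200/7000 genes, 5% mito, 0.25 pct/lnFC gates, β = 8,
  merge at 0.75) are assay conventions, not estimated quantities; they are
  exposed as parameters.
- The static dendrogram cut at 0.99 suits sparse count panels; small dense
  Gaussian panels need a tighter cut (see the test suite) and no dynamic
  tree cut is implemented.
- The LR model scores specificity and detection frequency only; it does not
  model complex stoichiometry, co-factors, or spatial proximity.
- Marker p-values on clusters derived from the same data are
  post-selection; the permuted-label null in the acceptance suite checks
  calibration of the test itself, not of post-clustering inference.
- The asymptotic Wilcoxon approximation is used for groups above 8 cells;
  at droplet sample sizes this is standard practice.
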