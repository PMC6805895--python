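# Methods

`immunemap` re-implements, as a tested pipeline, the analytical machinery
around a hierarchical signalling-map resource of the innate immune response
in cancer: the map/tag/gene-set data model, reaction confidence scoring,
ICA-based single-cell ranking, module activity scoring with group
comparison, and survival z-score enrichment. All external inputs (curated
maps, single-cell accessions, PPI databases, pan-cancer survival tables)
are replaced by synthetic generators with planted ground truth, so every
downstream claim is a measurable recovery.

## The map model

A map is a set of molecular entities (proteins, genes, RNAs, antisense
RNAs, simple molecules, ions, drugs, phenotypes, complexes) connected by
reactions with typed regulators (catalysis, inhibition, modulation,
trigger, physical stimulation). Entities carry free-text tags
`MODULE:<NAME>`, `PATHWAY:<NAME>`, `MAP:<NAME>`; the tag grammar is
token-based (name = maximal non-whitespace run after the colon,
case-sensitive) so tags round-trip losslessly through annotation text.

The hierarchy has four container levels — 2 polarization **zones**
(anti-tumor / pro-tumor) → biological processes (**meta-modules**) →
functional **modules** → signalling **pathways** (sets of gene symbols).
Containers partition containers: each pathway has exactly one parent
module, and so on up; a *gene* may appear in any number of pathways. The
gene set of a container is the union over its children, computed bottom-up
and validated at construction (two-parent children, dangling or orphaned
names and empty pathways are rejected). Every level exports to GMT
(tab-separated: name, description, genes); the description field carries
the ancestry path `zone/meta_module/.../name`, genes are written in
lexicographic order for reproducible diffs, and readers must not rely on
either convention.

## Confidence scores

Both scores are integers 0–5, 0 meaning undefined confidence.

* **REF** = `min(5, floor(Σ weight))` over the annotating publications,
  with weights 1.0 for cell-type-relevant experimental papers and 0.5 for
  reviews and for experimental papers from other cell types. The weights
  and the floor/min aggregation are declared conventions (chosen so five
  directly supporting experimental papers saturate the scale) and are
  overridable per call.
* **FUNC** bins the average breadth-first shortest-path distance d̄
  between all protein participants of a reaction in an external PPI graph:
  d̄ ≤ 1 → 5, ≤ 2 → 4, ≤ 3 → 3, ≤ 4 → 2, larger → 1. Unit-distance bins
  are likewise a declared, overridable convention. A single participant,
  a participant absent from the graph or a disconnected pair makes d̄
  undefined and the score 0 — absence of evidence is never converted into
  a penalized finite distance. Only protein-class participants enter.

## Synthetic data

`SimulationSpec` defaults define the study conditions: 2 zones × 2
meta-modules × 3 modules × 3 pathways × 15 genes = 540 genes, 200 cells,
loading magnitude a = 1, noise σ = 0.5, bimodal latent, half the modules
per zone active. Expression is generated directly on log scale
(`x_gc = s_g t_c + ε`, ε ~ N(0, σ²)); there is no count model because the
pipeline never touches counts. The latent t is ±1 plus N(0, 0.1²) jitter
(or uniform(−1, 1)): ICA needs a non-Gaussian source and a two-state
polarization is naturally bimodal. Exactly one latent component is planted,
matching the analysis assumption that only one sufficiently stable
component exists. Active modules load +a in the anti-tumor zone and −a in
the pro-tumor zone; `fraction_active_modules = 0.5` (a package choice — a
realistic polarization contrast touches some but not all processes; the
rounding is per zone so both zones always carry signal under the
defaults). The PPI generator densifies Erdős–Rényi background (p = 0.01)
within pathways (p = 0.8); the survival generator draws z ~ N(μ_m, 1)
around planted per-meta-module means with p the two-sided normal tail.

What the generator does **not** emulate: dropout and library-size noise,
batch effects, multi-component latent structure, overlapping pathway
membership, correlated noise between genes. Passing recovery tests
therefore demonstrate the correctness and calibration of the machinery
under the stated model, not robustness to real scRNA-seq artefacts.

## Cell ranking

Expression is log-transformed if needed (`log2(x+1)`) and mean-centred per
gene. For ICA, cells are the observations: a component is a latent signal
with one value per cell (the projection — this is where non-Gaussianity
lives) and a gene-space pattern (the loading). Each restart whitens the
cell-observation matrix to `n_components` dimensions (default
`min(10, cells − 1)`) by truncated SVD and runs the fixed-point iteration
with the log-cosh contrast and symmetric decorrelation from a seeded
random orthogonal start (tol 1e-4 on the largest row-direction change,
max 200 iterations). By default each restart fits on a bootstrap resample
of cells, re-whitened; restarts that stop at the iteration cap still
contribute components. The noise subspace of realistic data never settles
below tol, so demanding strict convergence of a whole restart would abort
the pipeline; discounting wandering components is instead the job of the
stability selection.

Components pooled over 20 restarts are clustered greedily at |Pearson
r| ≥ 0.85 on their cell projections. A cluster's stability index is
(mean within-cluster |r| − mean |r| to outside components) × occupancy,
where occupancy = cluster size / number of pooled restarts, capped at 1. A
singleton has within-cluster agreement 0, not 1: a component seen once has
shown no reproducibility. Both the bootstrap and the occupancy factor are
needed for the index to discriminate: with restarts alone on fixed data,
spurious optima of one noise realization recur in every run and pure
Gaussian data scores ≈ 0.85; with them, noise tops out well below the 0.5
"sufficiently stable" warning threshold while a planted component scores
≈ 0.9. Each cluster is represented by its member closest to the cluster
centroid; clusters are sorted by stability (ties by size) and IC1 is the
first.

ICA's component sign is unidentifiable, so IC1 is oriented to make its
mean loading over the anti-tumor zone non-negative (idempotent; an exact
zero is left alone). Cells are then grouped by projection sign (group 1 =
positive = anti-tumor side; exact zeros unassigned) or by quartiles
(group 2 ≤ Q1, group 1 ≥ Q3, linear-interpolation quantiles, middle cells
unassigned; degenerate boundary ties that push a group past 40% of the
cells are an error). PCA coordinates for plotting come from the same
centred matrix, components signed so the largest-magnitude gene loading is
positive.

## Module activity and group comparison

For a gene set, genes absent from the matrix are dropped, per-gene sample
variance (n − 1) is computed across **all** cells — selection must be
identical for both groups for the test to be valid — and the top
`ceil(n/2)` genes are kept (ties broken lexicographically). A cell's
module score is the mean of the selected genes; a group's score is the
mean over its cells. Groups are compared with a two-sided Welch t-test on
the per-cell scores (pooled-variance Student available via `equal_var`),
reported with the standard code *** p<0.001, ** p<0.01, * p<0.05,
· p<0.1. The same rule applies at every level; the zone score uses the
union gene set, not the mean of module scores. Map staining exports color
the higher group red and the lower green, ties neutral. The pathway
heatmap keeps pathways with more than 10 measured genes (≥ 11; measured,
not mapped, since scoring can only use measured genes).

## Survival enrichment

Survival input is a per-gene table (gene, z, p) with z < 0 = positive
association with survival. Map-level enrichment is a 1-df Pearson
goodness-of-fit of the observed (significant, non-significant) split of
the n scored map genes against the genome-wide significant fraction f
(a required input — whether f counts all genes or all scored genes is a
property of the reference study), significance threshold 0.001; cells with
zero expectation are skipped so f → 0/1 stays finite. A 2×2
map-vs-genome contingency variant is available behind `method=
"contingency"`. The per-meta-module summary averages z over all scored
member genes (not only significant ones) and counts significant genes by
sign; genes in several meta-modules contribute to each; rows sort by mean
z descending.

## Resource comparison

Overlap fractions use the map as denominator (the symmetric Jaccard index
is reported alongside); symbols are canonicalized to upper case with
whitespace stripped, with no alias resolution. Map-exclusive genes are the
map minus the union of the other resources. Module enrichment in exclusive
genes is a hypergeometric upper tail over the map universe with
Benjamini–Hochberg adjustment across sets. Literature statistics are set
arithmetic on PMIDs; the recent-paper fraction is computed only over
papers with known years and is undefined (not zero) when none are known.

## Numerical conventions and problem sizes

Statistics go through scipy/statsmodels (Welch via `ttest_ind`, χ² and
hypergeometric tails, BH adjustment) and graph distances through networkx
BFS; the test suite checks each against an independent textbook formula,
exhaustive enumeration, or a Floyd–Warshall oracle. The test and
acceptance runs use the generator defaults (540 genes × 200 cells, 10
data seeds for ICA recovery, 500 simulated modules for test calibration,
500 null tables for enrichment calibration, 100 random graphs ≤ 20 nodes
for the FUNC oracle sweep) — sizes at which every stochastic check has
comfortable Monte-Carlo margins while the whole suite runs in well under a
minute of compute for these stages.

## Known limitations

* The stability index is a heuristic; its 0.5 warning threshold is a
  convention, and components of genuinely intermediate reproducibility
  land near it.
* Representatives of distinct low-stability noise clusters can correlate
  (they straddle the 0.85 clustering threshold); decorrelation is only
  guaranteed between the top stable components.
* Recovery accuracy of the latent ordering is bounded by the latent's
  within-mode jitter; with the default bimodal latent the attainable
  |Spearman ρ| is ≈ 0.99 even for an oracle estimator, and IC1 typically
  reaches 0.90–0.95.
* The REF/FUNC weightings are declared conventions, not reconstructions of
  the published maps' scores.
* No gene-identifier alias mapping: resource comparisons assume a shared
  symbol namespace.
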