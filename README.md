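# immunemap

Analysis machinery for hierarchical signalling-map resources of the innate
immune response in cancer — for computational biologists who want to use a
curated map not as a picture but as a set of quantitative instruments:
gene-set exports, reaction confidence scores, single-cell polarization
ranking, module activity testing and survival-signature enrichment.

The package models a map as a four-level hierarchy — two polarization
**zones** (anti-tumor / pro-tumor) → biological processes (**meta-modules**)
→ functional **modules** → signalling **pathways** over gene symbols — and
implements, on top of it:

* **GMT interchange and tagging** — `MODULE:`/`PATHWAY:`/`MAP:` annotation
  tags, hierarchy validation (containers partition containers; a gene may
  sit in many pathways), GMT read/write, per-module content summaries.
* **Reaction confidence** — REF = min(5, ⌊Σ wᵢ⌋) over annotating
  publications (experimental 1.0, review/other-cell-type 0.5); FUNC bins
  the mean shortest-path distance d̄ between a reaction's proteins in a PPI
  graph (d̄ ≤ 1 → 5 … > 4 → 1, undefined → 0).
* **ICA cell ranking** — FastICA (log-cosh contrast, symmetric
  decorrelation, SVD whitening) repeated over bootstrap restarts; pooled
  components are clustered by |Pearson r| of their per-cell projections and
  scored with a stability index; the most stable component (IC1), oriented
  against the anti-tumor zone, ranks the cells, which are split by
  projection sign or by outer quartiles.
* **Module activity** — score of a gene set in a cell = mean of the set's
  top ⌈n/2⌉ most variant genes; groups compared with a two-sided Welch
  t-test, coded *** p<0.001, ** p<0.01, * p<0.05, · p<0.1; map-staining and
  pathway-heatmap exports.
* **Survival enrichment** — per-gene survival z-scores (z < 0 = positive
  association with survival): χ²(1 df) test of the map's significant-gene
  fraction against the genome-wide fraction, and per-meta-module mean-z /
  sign-count summaries.
* **Resource comparison** — overlap fractions, map-exclusive genes,
  hypergeometric module enrichment with BH correction, literature recency.

Every external input is replaced by generators with planted ground truth
(`immunemap.simulate`), so recovery, calibration and power are measurable.
See `docs/methods.md` for the full model description.

## Worked example

`examples/` contains one short script per capability. Ranking 200 simulated
cells along the planted anti-tumor ↔ pro-tumor gradient
(`python examples/03_rank_cells_by_ica.py`) prints:

```
components: 97 clusters from 20 restarts
top stability indices: [0.906 0.526 0.416]
|Spearman rho| between IC1 and the planted gradient: 0.915
sign-split agreement with planted groups: 100.0%
quartile split keeps 50 + 50 extreme cells of 200
PC1 range: [-21.9  19.8]
```

Only one component is reproducible across bootstrap restarts (stability
0.91 vs 0.53 for the runner-up): that component recovers the planted
polarization ordering almost perfectly, and splitting cells by its sign
reproduces the planted anti-tumor and pro-tumor groups exactly. Scoring the
map on those groups (`python examples/04_module_activity_scores.py`) then
flags exactly the planted active modules and gives group 1 the higher
anti-tumor zone score:

```
Zone polarization of the two cell groups:
      name  mean_group1  mean_group2        t   p code
Anti-tumor        0.955       -1.056  146.175 0.0  ***
 Pro-tumor       -0.949        1.049 -136.694 0.0  ***

modules flagged ***: 6 (planted active: 6)
recovered = True
```

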