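# emtscreen

Pan-cancer discovery of epithelial/mesenchymal-state gene signatures from
expression compendia, with the downstream clinical statistics used to
evaluate such signatures: z-score signature scoring, correlation-distance
k-means patient stratification, Kaplan–Meier/log-rank survival comparison,
ROC-based biomarker dichotomization, and fold-change / chi-square clinical
associations.

## Who this is for

Carcinoma cells undergoing epithelial–mesenchymal transition (EMT) lose
epithelial markers such as E-cadherin (*CDH1*) and gain mesenchymal markers
such as Vimentin (*VIM*). Finding genes that track this switch *in tumors*
is harder than it sounds, because bulk tumor RNA mixes cancer cells with
stromal cells, and stromal cells express mesenchymal genes at 10–100× the
level of cancer cells. This package implements a dual-screen strategy that
confronts exactly that problem, for computational biologists who want to

- run the screens on their own (already normalized) cell-line and tumor
  expression matrices, or
- study the screens' behavior quantitatively on synthetic cohorts where the
  true gene roles, EMT states, tumor purities and outcome links are planted
  and known.

## The method

**Cell-line screen.** Cell lines are classified by their linear-scale
anchor ratio: epithelial-like if CDH1/VIM > 10, mesenchymal-like if
VIM/CDH1 > 10, ambiguous otherwise (dropped). Per cancer entity, every gene
is tested between the two groups with a two-sample pooled-variance
Student's t-test on log2 values; genes with p < 0.05 are flagged by the
sign of their log2 fold change. The screen's signature is the set of genes
flagged identically in **every** entity.

**Tumor screen.** Per entity, every gene's Spearman correlation with both
anchors is computed across tumors. A gene is epithelial-state if
r(gene, CDH1) > 0.1 and r(gene, VIM) < −0.1, mesenchymal-state under the
mirrored rule, again intersected across all entities.

**Shared signature.** The class-wise intersection of the two screens. The
asymmetry built into bulk data — stromal expression inflates mesenchymal
genes only — makes the shared mesenchymal list systematically shorter than
the epithelial one; the synthetic-data generator reproduces this mechanism
and the package's tests measure it.

**Downstream.** Samples are scored by the mean of per-gene z-scores over
the signature; patients are split into epithelial/mesenchymal groups by
k-means (k = 2, distance 1 − Pearson correlation, ≤ 50 Lloyd iterations,
best of 10 restarts) on their z-scored signature profiles; groups are
compared by Kaplan–Meier curves with the log-rank test; individual markers
are associated with metastasis (M0/M1), nodal status (N0/N+), molecular
subtype (Kruskal–Wallis) or ordinal IHC scores (chi-square), and
dichotomized by a Youden-J ROC sweep.

## Worked example

Run the full discovery flow on a simulated study — 5 cell-line entities
with 20+20 lines each, 3 tumor cohorts of 300 tumors, 50+50 planted
markers, 20 entity-specific confounders and 900 null genes, with stromal
contamination active (purity 0.5–0.95, stromal factors 10–100×):

```sh
emtscreen run --simulate --seed 1 --out-dir out/
# shared signature: 51 epithelial / 46 mesenchymal genes; report at out/report.json
```

The report (`out/report.json`) shows what happened at each stage: all 200
lines classified (20 epithelial-like + 20 mesenchymal-like per entity); the
per-entity t-test flags 76–85 genes per class; the all-entity intersection
keeps 51 epithelial and 51 mesenchymal genes (CCLE-style screen), the
tumor screen keeps 51 and 46; the shared signature is 51 epithelial (all
50 planted markers plus the CDH1 anchor — recovery 1.0) and 46 mesenchymal
genes (recovery 0.90: stromal composition noise costs five planted
mesenchymal markers, the mechanism behind the screens' concordance gap).
No entity-specific and no null gene survives. The k-means mesenchymal
group (468 of 900 tumors) shows worse overall survival, log-rank
p = 3.2 × 10⁻⁷, consistent with the planted hazard ratio of 2 per unit
EMT score.

Individual stages are exposed both as library functions
(`simulate_cell_lines`, `classify_cell_lines`, `correlation_screen`,
`intersect_screens`, `score_signature`, `kmeans_stratify`, `km_estimate`,
`logrank_test`, `roc_cutoff`, …) and as CLI subcommands (`simulate`,
`screen cell-lines`, `screen tumors`, `score`, `stratify`, `survival`,
`associate`, `cutoff`).

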