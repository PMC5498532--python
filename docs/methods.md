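# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Discovery screens

### Cell-line screen

The anchor-ratio rule operates on linear-scale expression: a line is
epithelial-like when CDH1/VIM exceeds `ratio_threshold` (default 10),
mesenchymal-like when VIM/CDH1 does, and ambiguous otherwise. The
inequalities are strict — a ratio of exactly 10 is ambiguous — and
ambiguous lines are excluded from testing rather than forced into a class,
because the two published definitions are non-exhaustive. Log2 input is
exponentiated before forming the ratio. A zero VIM value with positive
CDH1 yields an infinite ratio and an epithelial-like call.

"Student's t-test" is read literally as the pooled-variance two-sample
test (`scipy.stats.ttest_ind`, `equal_var=True`); Welch's form is
available behind the `welch` config switch. Tests run on log2 values, two
tailed, at raw α = 0.05 with **no** multiple-testing correction: the
all-entity intersection is the procedure's de-facto false-positive
control (a null gene passing one entity's screen at rate α/2 in a fixed
direction passes all five at ≈ (α/2)⁵ ≈ 10⁻⁸). Degenerate genes are
defined away explicitly: both groups constant and equal → t = 0, p = 1;
constant and unequal → t = ±∞, p = 0. Entities with fewer than two lines
in either state are skipped with a warning.

### Tumor screen

Spearman correlation (average ranks on ties) of every gene with both
anchors, per entity, with strict thresholds r > 0.1 / r < −0.1. The
correlation is rank-based, so the matrix's declared scale is immaterial
(asserted by a test rather than assumed). Genes constant within an entity
have undefined correlation, are unclassified there, and therefore fail the
all-entity intersection. Anchors are not excluded from their own screen:
CDH1 correlates 1 with itself and, when the anchors anti-correlate,
lands in the epithelial list — matching the published shared list, which
retains both anchors. No p-value is attached to r; the rule is purely
threshold-based. A per-entity sample floor (default 10) guards against
meaningless correlations; the reference analyses used hundreds of tumors
per cohort.

### Intersections and provenance

Both screens intersect across **all** analyzed entities
(`require_all_entities`). The shared signature is the class-wise
intersection of the two screens' signatures. Provenance records the
per-entity evidence (fold change and p, or the two correlations) for every
retained gene and survives the signature's TSV round trip via a JSON
sidecar.

## Synthetic data generator

The generator is first-class, tested code: it defines the study conditions
under which every end-to-end claim in the test suite is measured.

### Cell lines

Per gene, a baseline log2 expression is drawn once, uniform over [4, 10],
and shared between the cell-line and tumor generators. Each entity
contributes `lines_per_state_per_entity` lines per state. Epithelial
markers (and CDH1) gain `effect_size` (default 2.0) log2 units in
epithelial-state lines; mesenchymal markers (and VIM) the mirror image;
entity-specific genes shift only in their designated entity; null genes
never shift. Gaussian noise (sd 0.5 log2) is added per cell.

Two deliberate anchor choices make the ratio rule exhaustive, as the
benchmark requires: CDH1 and VIM share a single baseline draw (with
independent baselines, a 6-log2-unit baseline gap could swamp any planted
shift), and the anchor separation is log2(ratio_threshold) + 8·noise_sd
(≈ 7.3 log2 units at defaults), putting per-line misclassification below
10⁻⁸.

### Bulk tumors

Each tumor draws a latent EMT score e ~ U(0, 1) and a purity
ρ ~ U(0.5, 0.95). The bulk linear value is ρ·cancer + (1 − ρ)·stroma with
multiplicative log-normal noise (sd 0.5 in log2). The cancer-cell profile
responds to e: epithelial-class genes by 2^(effect·(1−e)),
mesenchymal-class by 2^(effect·e), nulls flat.

The stromal profile encodes the asymmetry that motivates the dual-screen
design, and its structure is the package's key modeling decision:

- **Mesenchymal markers**: baseline · s_g · c_{g,t}, where s_g ~ U(10, 100)
  is the gene's stromal over-expression (fixed property of stromal cells,
  1–2 orders of magnitude) and c_{g,t} is a per-tumor stromal-composition
  multiplier, log-uniform over [1/6, 6]. The composition term models the
  fact that most mesenchymal genes are expressed by particular stromal
  subpopulations (fibroblasts, endothelium, immune infiltrate) whose
  proportions vary between tumors.
- **VIM** is treated as pan-stromal — expressed uniformly by all stromal
  cell types — so its stromal term tracks total stromal content (1 − ρ)
  without composition noise. This is what makes VIM usable as a bulk
  anchor at all.
- **Epithelial-class genes** are essentially absent from stroma
  (baseline × 0.01): the epithelial program is carcinoma-restricted.
- **Null and entity-specific genes** sit at baseline in both
  compartments, so purity cancels out of their bulk values and their
  correlation with VIM stays centered at zero — the tumor screen remains
  well-posed under contamination.

Under this model, contaminated cohorts reproduce the concordance gap: the
shared epithelial list recovers essentially all planted epithelial markers
while composition noise knocks a seed-dependent 10–40 % of mesenchymal
markers out of the tumor screen; fixing purity at 1 removes the gap
exactly. Alternative readings that were prototyped and rejected — a
stroma factor constant across tumors, or redrawn independently per tumor
for every gene including VIM — corrupt the VIM anchor so badly that
epithelial recovery collapses (to ~0.6 and ~0.25 respectively), which no
screen built on these thresholds could survive.

### Outcomes

Overall and relapse-free survival are independent exponentials with hazard
`baseline_hazard · hazard_ratio_mes^e` (defaults 0.05 and 2.0) and
independent exponential censoring whose rate is solved numerically so the
expected censored fraction equals `censor_rate` (default 0.25). M1 and N+
status follow logistic links in e (defaults −2 + 3e and −1 + 2.5e).
Pseudo-subtype labels are quartile bins of e with 10 % label noise, and an
ordinal 0–3 immunohistochemistry-like score decreases with e; both exist
so the association statistics have realistic consumers in synthetic runs.

All draws descend from one integer seed through named
`SeedSequence` sub-streams, so stages are independently regenerable and
every output is bit-reproducible.

### What the generator does not emulate

Marginal distributions of real RSEM/RMA data, library-size and batch
effects, gene–gene co-expression beyond the planted factors, correlation
between purity and EMT state (deliberately independent here, which makes
survival recovery *harder* than in real cohorts — see Limitations), and
any coupling between OS and RFS. Passing tests demonstrate the
procedure's correctness and its behavior under the planted mechanism, not
performance on real cohorts.

## Scoring and stratification

A signature score is the per-sample mean of per-gene z-scores (population
sd) on log2 scale; constant genes are dropped and counted. Scores are
invariant under per-gene positive affine transforms, and the cohort mean
is 0 whenever nothing was dropped.

k-means uses d(x, c) = 1 − r(x, c) on z-scored signature-gene profiles,
plain-mean centroid updates, assignment-fixpoint or 50-iteration stopping,
and the best of 10 seed-derived restarts by total within-cluster distance.
Distance ties go to the lower-indexed centroid; an emptied cluster is
re-seeded at the sample farthest from its centroid. The cluster with the
higher mean epithelial score (or, failing that, the lower mesenchymal
score) is labelled the epithelial group, so the labels are data-derived,
not initialization-derived.

Clustering uses the epithelial and mesenchymal lists jointly by default
(`genes="both"`; the single-class alternatives are exposed). On planted
data a single-class profile is a constant shift plus noise, which Pearson
centering removes — one of several reasons the joint default is the only
robust choice here.

## Clinical statistics

Kaplan–Meier estimation and the two-group log-rank test are delegated to
`lifelines` and re-exposed in small result types; both are verified
against hand-formula implementations (product-limit over distinct event
times; O/E with hypergeometric variance) to 10⁻¹⁰ on randomized instances,
and the log-rank test's type-I error is calibrated by simulation. The
log-rank variance uses the standard hypergeometric form, no strata, no
continuity correction.

The ROC cutoff sweeps midpoints between adjacent distinct values and
maximizes Youden's J; ties break toward the more balanced
sensitivity/specificity pair, then the lower cutoff. Because the
downstream use is survival dichotomization, an alternative criterion is
provided that minimizes the log-rank p over candidate splits leaving at
least 10 % of samples on each side.

Fold-change associations report group means with the numerator and
denominator stated explicitly in the result (the printed direction of
such ratios is easy to misread, so the package never leaves it implicit),
plus a pooled t-test. The chi-square for ordinal-score tables is Pearson's
without continuity correction (expected counts below 5 warn, not fail);
subtype summaries use Kruskal–Wallis, chosen as a conservative omnibus
test for box-plot-style group comparisons.

## Numerical choices

Scale conversions: 2^x for log2→linear; log2(x + 1) for linear→log2 (the
pseudocount guards RSEM-style zeros). Duplicate gene rows collapse by
mean at read time; genes with missing values are dropped (complete-case),
since imputation would inject structure into per-gene screens. Gene
identifiers are opaque, case-sensitive strings. z-scores use population
(ddof 0) standard deviations. All thresholds are strict inequalities
as printed.

## Known limitations

- The purity–EMT independence in the generator makes the stratified
  survival comparison conservative: bulk mesenchymal profiles carry a
  coherent purity factor, the correlation-distance k-means partly splits
  on it (group EMT-score separation ≈ 0.37 rather than the ≈ 0.5 of a
  clean split), and at a hazard ratio of 2 per unit EMT score with 900
  tumors the log-rank comparison of the two k-means groups reaches
  p < 0.05 in roughly three-quarters of seeds, not all of them. Real
  cohorts, where stromal content is itself prognostic, should do better.
- No Cox regression or multivariable adjustment; associations are
  marginal by design.
- The screens consume already-normalized matrices; no normalization,
  batch correction or identifier mapping is attempted.
- Benchmark problem sizes (5 entities × 40 lines, 3 cohorts × 300 tumors,
  ~1000 genes, 20-seed grids, 2000-replicate calibration) were chosen so
  the full suite runs in minutes on one CPU while keeping every planted
  effect measurable at the stated thresholds.
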