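# Methods

## The analysis model

`vesselmark` treats marker discovery as a pooled two-group comparison over a
heterogeneous collection of microarray samples. The working assumptions are:

* inputs are already probe-level-normalized, log2-scale intensities per
  platform (e.g. GC-RMA output); the package performs no probe-level
  normalization;
* platform effects are, to first order, additive per gene on the log2
  scale, so gene-wise median subtraction and SD division computed on the
  combined matrix renders samples comparable across platforms;
* the biological contrast of interest (BEC vs LEC) is a mean shift per
  gene, so a per-gene Welch t-test plus a fold-change threshold is the
  appropriate call, with no covariate structure;
* studies are compared by the exact identity of their reported gene
  symbols; no alias resolution is attempted, since published lists are
  compared as printed.

### Harmonization

The merge takes the union of canonical gene ids across platforms; a gene a
platform does not carry is missing (structurally) for all of that
platform's samples, and several probes mapping to one gene are collapsed by
their per-sample mean (a symmetric choice; `max` or `first` would privilege
one probe). The missingness filter requires a gene to be observed in at
least 40 % of all samples — the threshold is inclusive, and "observed" is
evaluated after merging, so both structural absence and random dropout
count against a gene. Standardization uses the median (robust to the heavy
tails of pooled array data) and the n−1 SD; genes with fewer than two
observed values or zero variance are dropped with a logged reason rather
than producing undefined scores. Standardization is a fixed point: applying
it twice equals applying it once.

### Differential expression

Welch's t statistic `t = (x̄_a − x̄_b) / √(s²_a/n_a + s²_b/n_b)` with
Satterthwaite degrees of freedom is computed per gene on observed values
only. Degenerate genes are handled explicitly: fewer than two observations
in a group, or two exactly constant groups at different levels, make the
gene *untestable* (flagged, excluded from the FDR input, never
significant); two identical constant groups give `t = 0, p = 1`.

The multiple-testing correction is robust FDR estimation: `π̂0 = min(1,
2·p̄)` — under a uniform null `E[2·p̄] = 1`, while true effects pull `p̄`
down and π̂0 estimates the null fraction — followed by the step-up
construction `q_(i) = min_{j≥i} π̂0·m·p_(j)/j`, clipped at 1. Ties in p
share a q-value by construction. Setting `pi0=1.0` recovers
Benjamini–Hochberg exactly, which the tests use as an independent
cross-check against statsmodels.

Fold change is the difference of group means on the log2 matrix, so the
2-fold rule is `|Δ| ≥ 1`. Because the median/SD-standardized values are
dimensionless, fold changes are computed on the merged-but-unstandardized
log2 matrix; the pipeline runs the test on that same matrix, and both
matrices are returned by `harmonize` so either choice is available. Both
thresholds are inclusive.

### Marker-set comparison

`venn` computes the exact disjoint partition: gene *g* belongs to the
region labeled by precisely the set of studies whose lists contain *g*.
Region labels are canonical sorted tuples, so the partition is independent
of input order; reports order regions by label cardinality (descending)
then lexicographically. `study_total` reconstructs a study's list size as
the sum of its region sizes.

The packaged fixtures transcribe three published BEC and LEC marker lists
(the pooled analysis plus two single-laboratory studies). Compound printed
labels denoting multiple genes on one probe (e.g. "LAMC1, LAMB2") are split
into separate symbols. The two single-study columns were printed truncated
after their top 20 genes, so those studies' *totals* computed from the
fixtures undercount their published totals; the pooled study's lists are
complete, and all intersection regions involving the pooled study are
exact. Operations needing complete single-study lists must treat the
fixtures as lower bounds.

### Embedding

Distances are Euclidean over genes; the default `complete_genes` policy
uses only genes observed in every sample, which keeps the distance matrix
exactly Euclidean. The alternative `pairwise_complete` policy computes each
pair over mutually observed genes rescaled by `√(n_total/n_observed)`; it
uses more data but is only approximately Euclidean and can produce negative
MDS eigenvalues, whose dimensions are zeroed and reported. Classical
(Torgerson) MDS was chosen over stress-minimizing variants because it is
deterministic — an eigendecomposition, no initialization or convergence
tolerance — and exact for Euclidean inputs of rank ≤ k. MDS is run on the
merged log2 matrix (not the standardized one), matching how such plots are
built from normalized intensities, and by default on the single-platform
sample subset so platform offsets do not masquerade as biology.

`cluster_separation` summarizes the embedding: per-class centroids, each
class's hull radius (maximum member-to-centroid distance; undefined and
flagged for singleton classes), and for each cell-line sample its distances
to the BEC/LEC/CONTROL centroids plus a flag for lying outside both primary
hull radii.

## The synthetic-data generator

The generator emulates the pooled study design, not any particular GEO
series. Per gene, a baseline `b_g ~ N(baseline_mean, baseline_sd_mean²)` is
shared by all classes; each of the `n_marker_bec` (`n_marker_lec`) planted
markers gets `±effect_log2/2` in the BEC (LEC) group means, symmetric so
both call directions are exercised. Cell-line means are
`hybrid_mix·BEC + (1−hybrid_mix)·LEC` plus `drift_log2` on a line-specific
drift gene set disjoint from the markers; control tissue gets an
independent per-gene shift `N(0, control_shift_sd²)`. Each platform adds a
per-gene offset `N(0, platform_offset_sd²)`, carries only a
`gene_coverage` fraction of the genes (structural missingness), and drops
retained cells MCAR at `missing_rate`. Observations add
`N(0, noise_sd²)`. One integer seed drives everything; identical configs
are bitwise-reproducible, and an omitted seed is an error.

Defaults (per-platform counts in `default_pooled_study_config`): 47 primary
samples — 33 BEC + 14 LEC — split as GPL570: 14 BEC + 10 LEC (the
24-sample dataset A, also members of dataset B), GPL571: 10 BEC + 2 LEC,
GPL5188: 9 BEC + 2 LEC; the published design fixes the GPL570 block and the
totals, and the remainder across the two smaller platforms is this
package's choice. Four replicates per cell line and three controls sit on
GPL570 outside both datasets. Quantities the source material does not state
were fixed once at values typical for log2 microarray data: baseline mean 7
(SD 1.5), residual noise SD 0.5, platform offset SD 0.5, 2 % dropout,
coverage 1.0/0.65/0.85 (the middle platform emulating a smaller array),
`effect_log2 = 2` (4-fold planted markers), 100 markers per class, 50 drift
genes per line at +2, `hybrid_mix = 0.5`, control shift SD 1.5.

What the generator does **not** emulate: correlated genes (co-expression
modules), intensity-dependent variance, MNAR missingness, probe-level
artifacts, or lab-specific batch structure within a platform. Passing tests
therefore demonstrate the pipeline's correctness under additive platform
effects and independent noise — they do not certify performance on real
pooled GEO data, where correlation and non-additive batch effects reduce
effective sample size.

## Numerical choices and degenerate inputs

* Missing token in expression TSVs is exactly `NA`; empty cells are format
  errors (explicitness over guessing).
* Median of an even number of values is the midpoint of the two central
  values; SD uses n−1 throughout.
* q-values use a stable sort, so tied p-values share a q deterministically.
* Distances clamp tiny negative squared values (floating-point) to zero;
  MDS symmetrizes B before the eigendecomposition.
* Thresholds (40 % observed, fold change ≥ 2, q ≤ 0.05) are inclusive at
  the boundary.
* Negative sMFI is reported with a `below_control` flag, never clamped.
* Percentages are rounded to two decimals in reports only; full precision
  is kept internally.

## Problem sizes

The test suite and the acceptance script run the null-calibration study at
200 replicate datasets of 2000 genes (14 vs 10 samples) and the recovery
study at the default 2000-gene configuration — sizes at which the
Monte-Carlo error of the checked quantities is well below the asserted
margins while the whole suite completes in seconds.

## Known limitations

* The 40 % filter and standardization assume the combined matrix is
  assembled once; incremental addition of platforms requires re-running
  harmonization from scratch.
* `pairwise_complete` distances are not guaranteed Euclidean; interpret
  negative-eigenvalue mass as a diagnostic.
* Study totals computed from the truncated single-study fixtures undercount
  those studies' published list sizes (see above).
* The Welch test is unmoderated; with very few samples per class, variance
  estimates are noisy and empirical-Bayes moderation (out of scope here)
  would be more powerful.
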