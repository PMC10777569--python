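# Methods

This note documents the models, defaults, and numerical choices behind
`rloopsc`, and what the synthetic-data experiments do and do not show.

## Preprocessing

Cells expressing fewer than 300 genes (strict) or with a mitochondrial
count fraction above 8% (strict, genes matched by the configurable
`^MT-` prefix) are removed first; genes detected in fewer than 3 of the
*retained* cells are removed second. The order is fixed so that gene
detection counts always refer to surviving cells, and a second application
of the filter removes nothing. Normalization is
`ln(1 + 10^4 · count / cell_total)`; scaling produces per-gene centered and
z-scored layers with values clipped at ±10 and zero-variance genes set
to 0. Variable genes are ranked by standardized variance: a lowess fit
(span 0.3) of log10 variance on log10 mean predicts each gene's expected
SD, counts are standardized by it, clipped at √n_cells, and the variance of
the result is the ranking score.

## Coexpression modules

Over a regulator gene list the package builds a signed weighted network,
`a_ij = ((1 + cor_ij)/2)^β`, with β chosen as the smallest power whose
connectivity distribution fits scale-free topology (log10 frequency vs
log10 mean connectivity over 10 equal-width bins, R² ≥ 0.85 with negative
slope; if no power qualifies the best-fitting power is returned with a
warning). Constant genes contribute zero correlation. Topological overlap
is `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`.

Module detection clusters `1 − TOM` by average linkage and applies the
simpler "tree" variant of dynamic tree cutting: a static cut at 0.99 of the
dendrogram height range, then recursive branch splitting while both
children hold at least `min_module_size` (default 10) genes; smaller
terminal pieces are unassigned ("grey"). Over-splitting is absorbed by the
merge step: module eigengenes (unit-norm first principal component of the
module's standardized expression, sign-oriented toward the module mean) are
iteratively merged while any pair has eigengene dissimilarity `1 − cor`
below 0.25. This trades the hybrid variant's PAM refinement for
determinism and transparency; on block-structured data the two agree.

Module–trait association is a Pearson correlation of each eigengene with
each numeric-coded covariate (binary 0/1, ordered stages 1..4; missing
values pairwise-deleted; constant traits reported as missing), with a
two-sided t-test p-value. The score gene set is the union of genes in
modules with p < 0.05 for at least one designated trait.

Note that cleanly modular data is *not* scale-free: symmetric planted
blocks produce bimodal connectivity, and no power may satisfy the R²
criterion. The fallback (best-fitting power) is exercised deliberately in
the tests; module recovery does not depend on the criterion being met.

## R-loop scoring

Documented in the README. Implementation details: bins are equal-frequency
with ties broken by gene index; a control draw excludes the set gene itself
whenever its bin has other members; draws are uniform with replacement
across samplings and fully determined by the seed. Besides the Monte-Carlo
estimator (default `n_samplings=1000`), `n_samplings=None` computes the
exact expectation over all control assignments, which is what the
enumeration-oracle tests compare against. `n_bins=25` follows common
bin-matched control-scoring practice; both knobs are recorded in the
output sidecar. The subtraction direction (center minus random) makes
higher scores mean higher regulator-set expression.

Properties that hold by construction and are tested: scores are invariant
to adding a per-gene constant, equivariant under scaling, exactly zero on a
constant matrix, and centered (mean ≈ 0, uniform rank-sum p) for random
gene sets on null data. Median-split ties go to "low" so the rule is
deterministic.

The two-group contrast is a two-sided Wilcoxon rank-sum test: exact for
samples of ≤ 20 per group without ties, exact by enumeration for small
tied samples (total n ≤ 14), normal approximation with tie correction
otherwise.

## CNV malignancy calling

Genes are ordered by genomic coordinate; relative expression (normalized
minus the reference-cell mean per gene) is clipped at ±1, smoothed per
chromosome with a centered 101-gene moving average (truncated at edges),
and re-centered per cell at its median window. The per-cell CNV burden is
the quadratic sum of window values. A cell is called malignant when its
CNV score exceeds the reference mean plus k·SD (k = 2) *and* its epithelial
marker-set score (same engine as the R-loop score) exceeds the all-cell
median. Window length, clip bound, k and the conjunction rule are
configurable; all are common expression-CNV practice rather than uniquely
determined choices. Because the per-cell median re-centering shifts every
window of a cell by a clip-dependent constant, clip monotonicity holds in
aggregate (mean |value|) but not for every single entry.

With the default simulation (150-gene single-copy gain, NB dispersion 0.5)
the quadratic-sum score separates malignant from reference cells with
AUC ≈ 0.97 and the k = 2 rule keeps the reference false-positive rate
around 1–2%; malignant recall is ≈ 0.81–0.87, limited by the conservative
mean + 2·SD threshold on a right-skewed reference distribution.

## Ligand–receptor testing

For each ordered (sender, receiver) type pair the statistic is
`(mean ligand expression in senders + mean receptor expression in
receivers)/2` on the normalized layer. The null permutes cell-type labels
across cells; `p = (1 + #{perm ≥ observed}) / (n_perm + 1)` (add-one keeps
p > 0). A pair is significant when p < 0.05 and at least 10% of cells on
each side express the gene. Multi-subunit complexes are not modeled; the
pair list is a required input. The add-one estimator makes the test very
slightly conservative (rejection probability 10/201 ≈ 0.0497 at
n_perm = 200), which the type-I experiments reflect.

## Enrichment

ssGSEA: per observation, genes are ranked by expression (average ranks for
ties; descending order with index tie-break), and the ES is the sum over
the ranked list of the difference between the in-set ECDF weighted by
rank^0.25 and the unweighted out-of-set ECDF. Scores are normalized by the
global max − min of the ES matrix, bounding them in [−1, 1]. One engine
serves both the GSVA-style and ssGSEA-style use cases, since downstream
group contrasts are the endpoint either way; the kernel-density estimation
step of GSVA proper is intentionally not reproduced. Contrasts are
Wilcoxon per set with Benjamini–Hochberg adjustment across sets; direction
is the sign of the median ES difference.

## Survival

Kaplan–Meier estimates carry Greenwood variance; the log-rank test is the
standard two-group O−E / hypergeometric-variance form. The Cox model is fit
by Newton–Raphson on the Breslow partial likelihood (ties are measure-zero
in the simulations; an Efron fit from an independent library agrees to
1e-6 on tie-free data and is used as a cross-check in the tests). Monotone
likelihood and non-convergence raise explicit errors. The HR-vs-score
curve fits a Cox model on a natural cubic spline basis of the score
(df = 4 columns, knots at score quantiles) and reports
`ln HR(s) − ln HR(median)` with pointwise Wald bands; the median is always
a grid point, so the curve is exactly zero there. Fixed-df natural splines
replace penalized-spline selection; the curve is meant to be read
qualitatively (where it crosses the reference line), not as a smoothness-
optimal estimate.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with every plant labeled in a `SyntheticTruth`:

* **Counts**: negative binomial with Var = μ + 0.5·μ² (moderate droplet-seq
  overdispersion), per-gene lognormal(σ=0.5) baseline spread around a mean
  of 2, per-cell lognormal(σ=0.3) library factors.
* **Modules**: 4 blocks of 30 regulator genes, each driven by a per-cell
  N(0,1) factor with loading 0.5 log2 per SD (a moderate transcriptional
  program) and correlated 0.6 with an emitted numeric trait (named
  mutation / stage / origin / smoking).
* **Score groups**: half the cells ("low") have all regulator genes scaled
  by 2^−1 — a twofold shift, recovered by the median split with accuracy
  ≈ 0.93 at 2000 cells.
* **Malignancy**: 15% of cells, drawn from the epithelial type, carry a
  2× gain over 150 contiguous genes on a regulator-free chromosome (1000
  genes over 5 pseudo-chromosomes, 1 kb each, 0-based half-open).
* **Epithelial markers**: 10 genes elevated 4× in the epithelial lineage.
* **Ligand–receptor plants**: designated genes elevated ~2.8× in their
  sender/receiver types.
* **Mitochondria**: a 13-gene `MT-` block; per-cell mito fraction
  Beta(2,30) (mean 6.25% — so the 8% cut also removes a realistic tail of
  ordinary cells), with 5% "dying" cells at Beta(8,10) that the cut removes
  essentially completely.
* **Survival**: exponential event times with the hazard multiplied by `hr`
  (default 2) in the low group; independent uniform censoring with
  probability `censor_rate`.

Not simulated: doublets, ambient RNA, batch effects, UMI saturation,
realistic gene-length or GC biases, subclonal CNV hierarchies. Passing
tests therefore demonstrate correctness of the algorithms and their
calibration under a clean generative model, not robustness to those
artifacts.

## Problem sizes

The test suite and acceptance script run on deliberately modest sizes
(hundreds to 2000 cells, 200–1000 genes, 50–500 replicate seeds per
calibration experiment), chosen so the full statistical battery stays
fast while keeping Monte-Carlo error well inside the asserted margins.
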