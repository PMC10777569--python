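# rloopsc

Single-cell and bulk transcriptomic analysis of the **R-loop state** of
tumors. R-loops — three-stranded RNA:DNA hybrid structures formed during
transcription — are implicated in genomic instability and cancer
progression, but they are not directly observable in RNA-seq. This package
characterizes them indirectly through the expression of *R-loop regulator
genes*: it selects trait-associated regulator modules from a signed
coexpression network, summarizes them into a per-cell (or per-sample)
**R-loop score**, stratifies observations into high/low subgroups at the
median, and connects that stratification to malignancy, cell–cell
communication, pathway enrichment, and survival.

Intended users: computational biologists analyzing tumor scRNA-seq or bulk
cohorts who want a tested, scriptable implementation of this scoring
workflow, together with a synthetic-data generator that plants recoverable
ground truth for every stage.

## The score

For a gene set *S* and observation *c* with log-normalized expression
*x<sub>gc</sub>*:

1. genes are partitioned into `n_bins` equal-frequency bins of their mean
   expression across observations;
2. *S*<sub>center</sub>(*c*) = mean over *g* ∈ *S* of
   (*x<sub>gc</sub>* − mean<sub>c′</sub> *x<sub>gc′</sub>*);
3. *S*<sub>random</sub>(*c*) = the same quantity averaged over
   `n_samplings` random draws of one expression-matched control gene (from
   the same bin) per set gene;
4. **score = *S*<sub>center</sub> − *S*<sub>random</sub>**.

The bin-matched background removes the trivial effect of overall expression
level, so a positive score means the set is expressed above matched
expectation in that cell. Observations are split into `high`/`low` at the
median score.

Around this core the package provides: QC/normalization (`preprocess`),
signed-WGCNA-style module detection with scale-free soft-thresholding and
eigengene–trait selection (`network`), inferCNV-style malignancy calling by
a quadratic-sum CNV score plus an epithelial marker score (`cnv`),
CellphoneDB-style ligand–receptor permutation testing (`interactions`),
ssGSEA enrichment with BH-adjusted Wilcoxon contrasts (`enrichment`),
Kaplan–Meier / log-rank / Cox survival analysis including an
ln HR-vs-score spline curve (`survival`), and the synthetic generator
(`simulate`).

## Worked example

Simulate a tumor-like dataset (planted high/low subpopulations, malignant
subclone, mitochondrial block), QC it, score the planted regulator set, and
test survival of the score subgroups:

```sh
rloopsc simulate --out sim --seed 7
# wrote 1000 cells x 1000 genes to sim
rloopsc qc --data sim --out qcd
# retained 708/1000 cells, 1000/1000 genes
rloopsc score --data qcd --geneset regulators.txt --seed 1 --out scores.tsv
# scored 708 observations
rloopsc survive --table surv.tsv --out sv
# log-rank chi2=73.175 p=1.19e-17; HR(low vs high) = 2.199 [1.828, 2.644]
```

(`regulators.txt` lists the planted module genes from
`sim/truth_genes.tsv`; `surv.tsv` was drawn with
`generate_survival(subgroup, hr=2.0, censor_rate=0.3, seed=2)`.)

The QC step removes the ~29% of cells failing the <300-detected-genes or
>8%-mitochondrial rules (including essentially all planted "dying" cells).
The median-split labels recover the planted groups with accuracy 0.955 on
this run, and the low-score group shows the planted twofold hazard
(HR 2.20, 95% CI 1.83–2.64, true value 2).

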