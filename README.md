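# jacbic

Graph-based biclustering of brain expression data with a cilium-gene
survival risk score.

Gliomas are transcriptionally heterogeneous: a co-regulated gene program
may be active in only a subset of tumors, and a normal-brain program may
be confined to a few anatomical regions. Ordinary clustering, which
forces every gene and every sample into exactly one exclusive group,
cannot represent this. `jacbic` implements a *biclustering* pipeline for
bulk (GTEx/TCGA-style log RSEM/TPM) and single-cell (UMI count) brain
expression data, annotates the resulting biclusters with phenotype
enrichments, and builds a 12-gene cilium expression risk score that
stratifies glioma overall survival. A synthetic-data module generates
inputs with the statistical structure the analysis assumes, so the whole
pipeline runs and is tested without any external downloads.

## The method

**Percentile-set Jaccard biclustering.** For each gene *g*, the top
(or bottom) percentile set Sₚ(g) is the ⌈p·N⌉ samples in which *g* is
most highly (lowly) expressed. Two genes are proximal when their sets
overlap strongly, measured by the Jaccard index

    J(a, b) = |Sₚ(a) ∩ Sₚ(b)| / |Sₚ(a) ∪ Sₚ(b)|.

Gene pairs with J ≥ j_min become edges of an undirected gene graph
(parameters are chosen so the graph stays below 500,000 edges); the
connected components are candidate biclusters, each paired with the
samples that recur in at least half of its member genes' percentile
sets, and filtered by minimum gene/sample counts. Named presets carry
the standard parameterizations for GTEx+TCGA high (p = 3 %, J ≥ 0.33,
≥31 genes, ≥100 samples), GTEx+TCGA low, TCGA-only, LGG-only and
REMBRANDT analyses.

**Single-cell adaptation.** Genes with zero UMI counts in more than
97.5 % of cells are removed, counts X_cg are transformed to analytic
Pearson residuals under a negative-binomial null with θ = 100,

    Z_cg = (X_cg − μ_cg) / √(μ_cg + μ²_cg/θ),   μ_cg = (Σ_i X_ig / Σ_ij X_ij) · Σ_j X_cj,

and the residual matrix is biclustered with p = 2.5 %, J ≥ 0.2. A
rank-based per-cell signature score summarizes a bicluster's gene set.

**Enrichment.** Each bicluster is tested against every phenotype level
(cohort, brain region, tumor subtype, IDH1/2 / 1p19q status) with the
one-sided hypergeometric test, Benjamini–Hochberg corrected across the
whole family.

**Cilium risk score.** LASSO Cox regression (elastic-net mixing α = 1,
penalty by cross-validated partial likelihood) over candidate cilium
genes plus clinical covariates selects the prognostic features; each
selected gene is refit univariately (Breslow ties, Newton–Raphson) and
the univariate coefficients β_g define the linear score
score(s) = Σ_g β_g·x_gs. The package ships the reference 12-gene
coefficient set (LRGUK 0.49, NSUN7 0.49, LRRC27 −1.50, SPAG17 0.25,
EFHB −0.31, IFT27 −0.87, DZIP1L 0.68, FOLR1 0.33, RGS22 0.31,
TEX9 −0.15, GALNT3 0.46, GLB1L 0.84). Scored samples are split at the
median or into top/bottom quartiles and compared with Kaplan–Meier
curves and the log-rank test.

## Worked example

The bundled demo simulates a 300-gene × 400-sample compendium with one
planted 40 × 60 co-upregulated block whose first three genes also drive
an exponential proportional-hazards survival model, then runs every
stage:

```bash
jacbic run --demo --out demo_run
```

```
INFO simulate: 300 genes x 400 samples, 1 planted block(s)
INFO bicluster: 1 bicluster(s)
INFO enrich: 2 significant pair(s) at FDR<0.01
INFO risk: 6 gene(s) in score
INFO stratify: log-rank chi2=179.364 p=6.67e-41
run complete -> demo_run
```

The single reported bicluster is the planted block; its top enrichment
is the region label shared by the planted samples
(`region=region_0`, q ≈ 5 × 10⁻⁷²); the LASSO keeps six of the block's
genes; and the median split of the resulting risk score separates
survival with log-rank χ² = 179.4 (p ≈ 7 × 10⁻⁴¹) — the planted
high-hazard samples land in the high-score group. `demo_run/` holds the
simulated inputs, `biclusters.json`, `enrichment.tsv`,
`risk_model.json`, `risk_scores.tsv` and `stratification.json`; rerunning
with the same config and seed reproduces every file byte for byte.

The same stages are available individually (`jacbic simulate`,
`jacbic bicluster --preset gtex-tcga-high`, `jacbic sc-bicluster`,
`jacbic enrich`, `jacbic risk fit|score|stratify`) and as library
functions.

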