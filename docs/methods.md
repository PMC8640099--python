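# Methods

This note documents the models, conventions and design choices behind
`jacbic`, in the order the pipeline runs them.

## Percentile-set Jaccard biclustering

A bicluster is a gene set that is coordinately high (or low)
specifically within a sample set; membership is neither exclusive nor
exhaustive. The engine works on a *percentile-set index*: for cutoff
p ∈ (0, 1] and direction `high`, gene *g*'s set is the ⌈p·N⌉ samples
with the largest expression of *g* (direction `low` takes the
smallest). Two conventions are fixed and deterministic:

* **Set size ⌈p·N⌉.** Ceiling rather than floor guarantees non-empty
  sets at small p (3 % of 100 samples is exactly 3).
* **Boundary ties break by input sample order.** A stable sort makes the
  output identical across runs and platforms; a gene constant across
  samples simply takes the first ⌈p·N⌉ samples in canonical order.

Edges connect gene pairs with Jaccard index **≥ j_min**; one inclusive
convention is used for both the bulk (0.33–0.45) and single-cell (0.2)
thresholds. The all-pairs computation uses an integer
membership-matrix product, so it is exactly the brute-force result
(verified by a property test and in the acceptance script). If the
graph reaches `max_edges` (default 500,000) the run aborts with an
instruction to raise j_min or lower p — a graph that dense means the
percentile sets are too large to be discriminative.

**Extraction.** Candidate biclusters are the connected components of
the gene graph. A component's sample set is every sample appearing in
at least `sample_frequency_threshold` (default 0.5) of its member
genes' percentile sets; candidates under `min_genes`/`min_samples` are
dropped, and output is ordered by descending gene count with
lexicographic tie-breaks. Connected components are the simplest
deterministic rule consistent with iterative graph examination; a
seed-and-grow variant from single high-overlap edges would fragment
components further and is a known divergence risk when comparing
against published bicluster counts. The fraction-based (rather than
fixed-count) sample rule keeps the definition scale-free across
component sizes; both the threshold and the rule are exposed as
parameters.

Monotonicity properties (raising j_min never adds edges; raising the
size minima never adds biclusters) and the high/low symmetry
(direction `low` on the negated matrix reproduces direction `high`
exactly) are enforced by tests.

## Synthetic bulk data

`gen_bulk` draws background entries Normal(μ_g, σ) with gene baselines
μ_g ~ Uniform(2, 8) — log₂ RSEM-like units — and noise σ = 1 by
default, then shifts each planted gene × sample block by ±δ. Planted
blocks use δ = 3 = 3σ in tests: a separation at which the top-percentile
sets of block genes coincide almost surely, which is the regime the
bulk analyses assume (differential expression between brain regions is
large relative to within-region noise). Annotations emulate a mixed
compendium: 65 % normals carrying a region label aligned with the
planted block (`region_k`), 35 % tumors alternating LGG/GBM with grade
and IDH status. What this generator does *not* emulate: correlated
background (co-expression outside planted blocks), batch effects, or
heavy-tailed expression — so passing recovery tests show the engine
finds planted rectangular structure at realistic effect sizes, not that
real-data bicluster counts are reproduced.

## Single-cell model

`gen_umi` draws counts NB(mean m_cg, dispersion θ); the mean factorizes
into a cell depth (log-uniform over 1,000–10,000, matching heavy-tailed
UMI depth without extra parameters) and a log-normal gene abundance
(σ = 1.5). The planted program multiplies the rates of its genes by 8
inside the program cells only, and the program cells all carry a single
donor label spread over three tumor-core sites — the composition the
single-cell analysis is designed to detect (a donor-private tumor
program in multi-region sampling). θ = 100 by default; θ = ∞ gives the
Poisson limit, verified by a moment check.

The analysis path is: zero-fraction filter → Pearson residuals →
biclustering. The filter removes genes with zero counts in strictly
more than 97.5 % of cells — the boundary case (exactly 97.5 %) is
retained — because a gene must be detectable in at least one full 2.5 %
percentile set to ever form an edge. Residuals use the analytic
expectation μ_cg = (gene share) × (cell total), which conserves both
margins exactly, and the NB denominator √(μ + μ²/θ) with θ = 100.
Residuals are **not clipped**; clipping at √n is common in the
residual-normalization literature but changes percentile sets only for
extreme cells, and the unclipped form is the simpler contract. The
high-variance shortlist (variance > mean + 1 SD across genes) is
computed for reporting/embedding use but does **not** pre-filter the
bicluster graph by default; both behaviors are available
(`restrict_to_shortlist`), since restricting changes which programs are
discoverable.

The per-cell signature score is the set-mean of per-gene ranks, centred
to population mean zero. It is a deliberately simple monotone summary —
invariant under any per-gene monotone transform — used to ask one
question: do the cells of a bicluster express its gene set more highly
than other cells? It is not a kernel-ECDF enrichment score and is
validated only for that monotone agreement.

## Enrichment testing

Over-representation uses the one-sided upper-tail hypergeometric
probability P(K ≥ k) — the standard choice for enrichment, equivalent
to one-sided Fisher's exact. The odds ratio is reported from the 2×2
table with a Haldane 0.5 correction only when a cell is zero, and the
correction never touches the p-value. Benjamini–Hochberg correction
spans the **full** bicluster × category-level family in one run — the
conservative choice when the intended family is unstated — and
significance defaults to q < 0.01. The Mann–Whitney U test used for
purity-style comparisons computes an exact two-sided p by full labeling
enumeration when n₁+n₂ ≤ 12 (exact even under ties, where textbook
tables fail) and the tie-corrected normal approximation otherwise.

## Survival model and risk score

`gen_survival` uses an exponential baseline hazard: event time ~
Exponential(rate · exp(Σβx)) with independent exponential censoring.
Exponential rather than Weibull is the default because its closed forms
(median = ln 2 / rate) make oracle checks exact; the proportional-hazards
structure is what the model fitting assumes either way. Defaults
(baseline 10⁻³ events/day ≈ 2-year median, censoring 2 × 10⁻⁴/day
≈ 17 % censored) mirror glioma overall-survival follow-up scales.

Fitting is two-stage:

1. **Selection** by L1-penalized Cox (α = 1, pure LASSO) over
   standardized gene expressions plus clinical covariates (grade
   encoded II/III/IV → 2/3/4, IDH-wild-type indicator, age in years),
   coefficients reported on the original scale. The penalty is chosen
   by 10-fold cross-validated partial-likelihood deviance at the
   **1-SE point** (sparsest λ within one standard error of the
   minimum). The 1-SE rule is the default because the score's purpose
   is a *small, stable* gene signature: at the CV minimum the lasso
   habitually keeps a tail of noise features (measured here: ~4–16
   false features alongside 3 true ones at n = 500), while the 1-SE
   point recovers exactly the planted support across seeds. `"min"` is
   available as an option.
2. **Coefficients** by univariate Cox refits of each selected gene:
   Newton–Raphson on the Breslow partial likelihood to |Δβ| < 10⁻⁸,
   with monotone likelihood reported as an error rather than clipped.
   Breslow (not Efron) tie handling is used throughout — including the
   cross-validation deviance — because its likelihood has a simple
   closed form that the grid-search oracle can maximize independently;
   the difference is negligible at the tie densities of survival data
   in days.

The score is the gene-only linear combination Σ β_g x_gs; clinical
covariates are adjustment factors in the selection model, never score
components, so the score can be evaluated within clinical strata (e.g.
the IDH-wild-type subset). Stratification splits at the median (ties to
the lower-risk group) or contrasts the top vs bottom quartile
(linear-interpolation quantiles; middle half excluded), and groups are
compared with Kaplan–Meier estimates and the two-group log-rank test.

No cross-platform rescaling is applied when scoring a cohort measured
on a different expression scale than the coefficients were trained on;
a per-gene z-scoring flag would be the natural preprocessing but is a
claim about the data, not the model, so it is left to the caller.

## Problem sizes and numerical conventions

Simulation-based tests and the acceptance script use 200 × 300 bulk
matrices (40 × 60 planted blocks, δ = 3σ, 20 seeds), 3,000 cells × 500
genes with a 50-gene program in 300 cells at rate ×8, and n = 400
survival cohorts with hazard ratio 2 per signature SD (20 seeds) —
sizes at which the planted effects are comfortably inside the
detectable regime yet the full suite runs in under a minute. Variances
use the n−1 denominator throughout. Genes with zero total count get
residual 0 by convention. Quantiles are linear-interpolation empirical
quantiles. All randomness flows through `numpy.random.default_rng`
seeded explicitly; identical seeds give bitwise-identical outputs.

## Known limitations

* Bicluster extraction by connected components can chain two planted
  programs into one bicluster if a bridge gene connects them; lowering
  p or raising j_min separates them.
* The enrichment family treats category levels as independent tests;
  mutually exclusive levels of one category are therefore mildly
  conservative under BH.
* The LASSO stage assumes linear log-hazard in expression; threshold
  effects would dilute selection.
* The synthetic generators plant rectangular, constant-shift structure;
  gradient or nested programs are out of scope.
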