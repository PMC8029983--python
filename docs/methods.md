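# Methods

## Problem and model

`panomix` re-creates, as a reusable pipeline, a pan-cancer style multi-omics
integration of paired tumor/normal cohorts: the central object is a per-gene,
per-cancer **consensus differential-expression status**

```
s_platform ∈ {-1, -0.5, 0.5, 1}     |s| = 1  ⇔  BH FDR < 0.05 on that platform
S = s_array + s_seq   if sgn(s_array) = sgn(s_seq)
S = 0                 otherwise
```

so S ∈ {-2, -1.5, -1, 0, 1, 1.5, 2}. |S| = 2 means both platforms call the
gene significantly in the same direction; S = 0 marks platform disagreement
and the gene is treated as not reproducibly altered. The sign of the
microarray status comes from the pooled-variance Student t statistic, the
sign of the RNA-seq status from the log2 fold change of normalized group
means. A statistic of exactly 0 leaves the direction undefined; such genes
are flagged and excluded from integration rather than given an arbitrary
sign.

Around this score the pipeline implements the standard companion analyses:
gene-level methylation consistency calls, mutation/CNV frequency summaries
with expression-consistency annotation, survival stratification, progression
contrasts, and correlation-driven pathway enrichment.

## Statistical components

**Microarray DE.** Classic two-sample Student t with pooled variance (not
Welch), two-sided, BH-adjusted across all genes in the matrix. The gene
panel of interest is looked up afterwards; the adjustment universe is never
restricted to the panel.

**RNA-seq DE.** An exact negative-binomial test on library-equalized
pseudo-counts. Counts are TMM-normalized; each sample is scaled to the
geometric-mean effective library size and rounded. A common dispersion φ
(variance μ + φμ²) is estimated by the method of moments on the scaled
counts (median of per-gene, within-group estimates, clipped at 0). Group
sums are then NB with size n/φ, and the test conditions on each gene's total
count, summing the probabilities of all outcomes no more probable than the
observed split (in the φ → 0 limit this is the exact binomial split test).
This is an approximation to edgeR's quantile-adjusted exact test: no
tagwise/trended shrinkage, and library equalization is done by plain
rescaling rather than quantile adjustment. All-zero genes are skipped and
reported, not tested.

**TMM.** Per-sample factors from the doubly trimmed (30% on M, 5% on A),
precision-weighted mean of gene-wise log-ratios against a reference sample
(the one whose 75th count-fraction percentile is closest to the cohort
mean); genes with a zero in either sample are excluded; factors are rescaled
to geometric mean 1. Note one numerical subtlety the tests document: the M
values are exactly invariant to a sample's sequencing depth, but the
delta-method precision weights are not, so scaling one sample's counts by a
constant reproduces its factor only to ≈1%, as in the reference
implementation of the method.

**Batch adjustment.** Reduced to per-gene, per-batch mean centering with the
grand mean restored, applied to log-CPM after TMM. The upstream description
of the emulated workflow is ambiguous about order (batch removal is
mentioned before normalization); we normalize first and adjust second, and
record that choice in the run manifest. Single-sample batches are passed
through with a warning.

**Methylation.** Sites missing in ≥ 50% of samples are dropped; remaining
missing betas are imputed with the site's minimum observed value (so
imputation can never raise a site's minimum or leave [0, 1]). Per-site
differential methylation is the Wilcoxon rank-sum test (exact for small
tie-free samples, tie-corrected normal approximation otherwise), BH across
sites, direction from the difference of group medians — medians, not means,
to stay consistent with the rank-based test. The gene-level rule is read
literally: a gene is hyper-/hypomethylated only if *every* one of its CpG
sites is significant in that one direction; significant sites in both
directions exclude the gene; any non-significant site yields "none". The
site-level significance threshold is BH FDR < 0.05, matching the global
significance convention (the emulated workflow names the test but not a
site-level threshold).

**Consistency annotation.** The dominant CNV direction is whichever of
amplification/deletion has the higher sample frequency (ties → no call); it
is consistent with expression when its sign matches sgn(S), its frequency
reaches `min_cnv_freq` (default 10%, configurable — the emulated analysis
marks such pairs without stating a threshold, so ours is an explicit
stand-in), and S ≠ 0. Methylation is consistent when it opposes expression
(hyper with S < 0, hypo with S > 0). Mutation frequency counts a sample once
regardless of mutation multiplicity.

**Survival.** Kaplan-Meier, k-group log-rank and Cox proportional hazards
are delegated to lifelines; ties use the Efron approximation (more accurate
than Breslow for day-resolution ties). Univariate Cox uses continuous
(standardized log-CPM) expression; KM/log-rank uses the median split with
low = values ≤ median (the tie rule is fixed and documented for
reproducibility). The multivariate model adjusts for AFP dichotomized at a
configurable cutoff (default 20 ng/mL), tumor size (cm, continuous) and TNM
stage (ordinal 1-4); these encodings are recorded in the manifest because
they are genuinely open choices. The mutation x expression stratification
forms {mut, wt} x {high, low}, reports the overall 4-group log-rank plus the
two within-stratum 2-group tests and a Student t comparison of expression
between carriers; any test touching an empty subgroup is skipped with a
warning. Non-convergent or degenerate Cox fits raise errors instead of
returning silently unstable estimates.

**Progression.** Metastatic = N+ or M+; non-metastatic = N0 and M0; NX/MX or
missing are excluded. Metastasis DE reuses the pooled t machinery with a
minimum group size of 10 (small metastatic groups are skipped with a
warning, mirroring the exclusion of cohorts with ~8 metastatic samples).
Stage testing is one-way fixed-effects ANOVA with Tukey-Kramer pairwise
comparisons (studentized range, unequal n) plus a pooled early (I-II) vs
late (III-IV) Student t contrast — the pooled contrast is our documented
choice of test for that comparison. Stage comparisons use the same log scale
as DE testing.

**Enrichment.** Pearson correlation against the anchor gene with the t
transform p-value; the positive/negative sets are selected at *raw*
p < 0.05 (deliberately unadjusted — only the enrichment step controls FDR).
Pathway enrichment is the upper-tail hypergeometric P(X ≥ k), BH across
pathways, significant at FDR < 0.05. The default universe is the matrix
genes annotated to at least one pathway (configurable to all matrix genes);
cross-dataset "common" pathways are those significant in every dataset,
separately for positive and negative sets. miRNA consensus keeps miRNAs
present in ≥ 2 of the 3 target lists; miRNA DE is Student's t on the
log-scale miRNA matrix.

## Synthetic cohorts

The generator (`panomix.simulate`) is first-class, tested code and the
pipeline's no-download data surface. It emulates:

- **Expression, two platforms.** Microarray log2 intensities are
  Normal(baseline ± effect/2, sd = 1.0) with baselines U(4, 12); RNA-seq
  counts are Gamma-Poisson with dispersion φ = 0.1, mean abundance
  log-uniform on (5, 500) counts per million reads, and library sizes
  log-uniform on (0.5, 1.5) × 10⁶ so TMM is exercised nontrivially. Default
  planted-effect conditions: 10% of genes DE at |log2 FC| = 2, 5% of planted
  genes discordant between platforms (exercising the S = 0 branch). Each
  platform gets its own sample set, as in real paired designs.
- **Methylation.** Beta values are inverse-logit of Normal variates
  (sd = 0.8 on the logit scale), 2-6 CpGs per gene, planted genes shift all
  CpGs by 1.5 logit units in one direction, "mixed" genes shift alternate
  CpGs in opposite directions, and 5% of entries are masked missing.
- **Survival.** Weibull baseline (shape 1.2, scale 1000 days) with linear
  predictor Σ β_g · z(expression). Censoring: with probability equal to the
  censoring rate (default 0.3) a subject is censored uniformly on (0, T) —
  this yields exactly the configured censoring fraction with uniform
  censoring conditional on the event time. Stage is categorical
  (0.30/0.30/0.25/0.15), and named genes can carry a monotone per-stage
  expression trend.
- **Alterations.** Per-gene Bernoulli mutations (default 2% per sample,
  per-gene overrides available) emitted as MAF-minimal rows, with a fraction
  of extra Silent rows to exercise the non-synonymous filter; discrete CNV
  calls with configured deletion/amplification probabilities (deep events
  are a fifth of each).
- **miRNA.** Three target lists with independent 0.5 membership; planted
  regulator miRNAs are forced into ≥ 2 lists, overexpressed in tumors, and
  anticorrelated (strength 0.8) with the anchor target gene.
- **Pathways.** A synthetic GMT over the cohort's genes with a few pathways
  drawn mostly from the planted anchor-correlation blocks, so the enrichment
  stage has recoverable signal.

Every operation draws from its own named substream of the config seed, so
full-cohort generation is a pure function of (config, seed) and any single
layer is reproducible in isolation.

What the generator does *not* emulate: real 450K probe annotation or
genome coordinates, probe-type (Infinium I/II) effects, real pathway
memberships, driver-vs-passenger mutation structure, correlated clinical
covariates, or between-cohort heterogeneity beyond independent seeds.
Passing recovery tests therefore demonstrates that the statistical machinery
is correctly implemented and calibrated under its own model assumptions —
not that those assumptions hold for any particular public cohort.

## Numerical choices and degenerate inputs

- BH adjustment propagates NaN p-values (untested genes) without letting
  them influence the adjustment of the rest.
- The NB exact test's two-sided rule sums all outcomes with conditional
  probability ≤ that of the observed split (with a 1e-10 relative guard
  against ties in floating point).
- Cox convergence follows lifelines' Newton-Raphson with its standard
  stopping rule; separation/monotone-likelihood surfaces as an error.
- Constant sites/genes: Wilcoxon returns p = 1 with no direction; the t test
  flags an undefined statistic; correlation drops zero-variance genes and
  reports them.
- Ties at the median go to the "low" group, making the split deterministic.
- Alteration frequencies are percentages of a fixed per-cancer sample
  universe passed explicitly, so missing profiling reduces the denominator
  only when the caller says so.

## Problem sizes in the test-suite

The suite's simulation sizes are chosen as the smallest cohorts at which the
planted conditions are comfortably identifiable: null calibration uses 2,000
genes at n = 20/20 per platform; recovery uses 500 genes at n = 30/30
(expression and methylation) and n = 300 tumors for the hazard-ratio
recovery; the log-rank uniformity check uses 2,000 label permutations, and
the permutation oracle for the log-rank p uses 10⁵ permutations at n = 30.
The chi-square log-rank p agrees with the permutation oracle to ≈0.01 at
that n; the residual gap is the small-sample chi-square approximation, not
Monte-Carlo noise.

## Known limitations

- The NB test uses a single common dispersion; genes with strongly atypical
  dispersion are tested at the common value (no empirical-Bayes shrinkage).
- Batch adjustment removes location effects only; scale or interaction batch
  effects pass through.
- The "all CpG sites differential" gene rule is strict by design; a single
  underpowered site yields "none". A relaxation flag exists but is off by
  default.
- Survival tooling offers no time-varying covariates or proportionality
  diagnostics; outputs are step-function tables, not plots.
- The consistency annotation's frequency threshold is an explicit stand-in
  for a visual convention in the emulated analysis and should be treated as
  a tunable, not an estimate.
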