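# Methods

## Scope and data model

`awasig` analyses a probe × sample matrix of log2 expression intensities
with an optional same-shaped matrix of detection-call p-values (the
per-probe, per-sample evidence that a transcript is expressed above
array background), plus a per-sample annotation (binary case status,
Framingham risk score in percent, age, optional covariates). The native
interchange format is plain TSV/CSV; GEO Series-Matrix text files are
parsed directly (only the data table and the sample-accession header are
used). Duplicate probe or sample ids, non-finite values and detection
values outside [0, 1] are rejected at construction.

## Preprocessing

* `log2_transform(x, offset)` — elementwise log2(x + offset); refuses
  non-positive arguments and names the offending probe/sample.
* `quantile_normalize` — every column is mapped onto the across-sample
  mean of order statistics; ties receive the mean of the reference
  quantiles they span. The operation is idempotent (to 1e-9) and
  rank-preserving within columns.
* `filter_probes` — a probe is retained iff its coefficient of variation
  (SD/mean, sample SD with ddof = 1) is at least `cv_exclude_below`
  (default 0.03) **and**, when a detection matrix is present, its
  detection p-value is below `detection_alpha` (default 0.01) in at
  least `min_detected_samples` samples. The default
  `min_detected_samples = 61` encodes "detected in more than half of a
  119-sample cohort"; it is a plain config field, not derived from the
  sample count, so other cohort sizes must set it explicitly. A probe
  with (near-)zero mean has no defined CV and is removed with reason
  `degenerate`. CV is computed on whatever scale the caller passes in;
  whether the filter should see raw or log intensities is genuinely
  ambiguous in practice, so the pipeline exposes `cv_on_log_scale`
  rather than asserting one order.

## Differential expression and FDR

Per-probe two-group comparisons use the Welch t statistic by default
(group variances in this design are not credibly equal; a pooled option
exists). The log2 fold change is the case-mean minus control-mean.
Zero-variance probes are tested against a 1e-12 variance floor and
flagged rather than dropped. `t_from_summary` applies the same formulas
to printed mean ± SD summaries so tabulated cohort characteristics can
be re-tested without raw data.

**q-values.** π₀(λ) = #{p > λ} / (m(1 − λ)) is evaluated on
λ ∈ {0, 0.05, …, 0.90}, smoothed by a natural cubic smoothing spline
with 3 effective degrees of freedom, and read off at λ = 0.90, clipped
to (0, 1]. The spline is the textbook Reinsch construction
((I + αK)f = y with K the second-derivative penalty); α is found by
bisection on the smoother trace. scipy offers no df-parameterized
smoothing spline, so this ~30-line solver is part of the package. For
fewer than 10 p-values the fixed-λ estimate at λ = 0.5 is used.
q-values are the π̂₀-scaled step-up quantities
q(p₍ᵢ₎) = min_{j≥i} π̂₀ m p₍ⱼ₎ / j; with π₀ fixed at 1 they reduce
exactly to Benjamini–Hochberg (tested against a brute-force oracle).
`estimate_de_fraction` returns 1 − π̂₀.

**Permutation FDR.** The variance-stabilized statistic is
d = (mean₁ − mean₀) / (SE_pooled + s₀). The fudge factor s₀ is chosen
among the 0th–100th (step 5) percentiles of the SE distribution to
minimize the coefficient of variation of the median absolute deviation
of d across up to 100 equal-occupancy SE bins. Label permutations (full
enumeration when the number of distinct labelings does not exceed the
requested count, otherwise sampled) give, for every observed |d| used as
a cutoff, the median null exceedance count; the FDR estimate is
π̂₀,perm × median false calls / calls, capped at 1, with π̂₀,perm the
fraction of observed d inside the null quartiles (capped at 1).
Per-probe permutation p-values use the add-one correction (b+1)/(B+1).

## Multiple-random-validation subtype discovery

Each repeat r draws a fresh stratified fold plan from a random stream
derived as `SeedSequence([rng_seed, r])` (stable, parallelizable).
Stratification deals the shuffled cases and then the shuffled controls
round-robin with a continuing pointer, guaranteeing fold sizes and
per-fold case counts that each differ by at most one. Within each
training set (the other 9 of 10 folds) probes are ranked by |Welch t|
(ties broken by probe id), the top k = 50 are standardized by training
mean/SD, and an SVM (RBF kernel, cost 1, γ = 1/k — the defaults of the
classical SVM implementation this procedure was built around; a linear
kernel is configurable) is trained on the training folds and applied to
the held-out fold. Feature selection, standardization and fitting see
training data only; each sample receives exactly one vote per repeat. A
sample is AWA iff its vote count strictly exceeds `vote_threshold`
(default R/2): a count exactly at threshold is *not* AWA. `sweep_k`
re-runs the vote over a k-grid (reduced repeat count by default) and
reports the k with the largest assignment-vs-phenotype odds ratio. The
default is a single k; votes are not pooled across k values.

## Association statistics

The subtype call × case status 2×2 table yields the cross-product odds
ratio with a Wald 95% CI; sensitivity tp/(tp+fn) and specificity
tn/(tn+fp); the default p-value is a Pearson chi-square (Fisher exact
when any expected cell is below 5, Yates correction optional). A zero
cell is an error unless the Haldane–Anscombe +0.5 correction is
requested. `adjusted_logistic` fits case ~ subtype + covariates by
maximum likelihood and reports exp(β_subtype) with Wald CI; constant
covariate columns are dropped (so a degenerate covariate matrix
reproduces the crude OR exactly, a nested-model identity tested to
1e-6), and a diverging coefficient (|β| > 15 or non-finite SE) is
reported as separation instead of a silent huge estimate. FRS enters
untransformed, as a continuous percentage. Counts reconstructed from
printed percentages use round(pct × n), exposed as an explicit helper.

## Clustering

Probes are mean-centered; distances are 1 − Pearson r over probes or
samples (zero-variance items dropped with a warning); trees are
unweighted average linkage (UPGMA) built by scipy, whose merge heights
are verified against hand-computed oracles in the tests. `cut_tree`
returns the partition with exactly n branches, renumbered in dendrogram
leaf order. `branch_enrichment` reports per-branch phenotype prevalence
and an overall chi-square (2×2 for two branches, b×2 otherwise). Sample
clustering uses the same probe-centered matrix as gene clustering.

## Cross-study concordance

Two platforms are joined on gene symbols from user-supplied
probe → symbol tables; genes with several probes on one platform are
collapsed to the probe with the highest mean expression (requires the
expression matrix; `first` is the fallback rule). The second study is a
paired baseline/post design: per-probe within-subject mean log2
difference with a paired t test. Concordance restricts (by default) to
genes with p < α in both studies, reports their count, a hypergeometric
tail p for the overlap given each study's call counts, and the Pearson
correlation of the two fold-change vectors (undefined below 3 genes).
Whether the correlation should be computed over the dual-significant
subset or all mapped genes is analysis-dependent; both modes exist and
`restrict=True` is the default.

## Synthetic cohorts

`CohortSpec` defaults define the target regime: 48 cases / 71 controls,
2,057 probes, latent subtype Z with P(Z=1|case) = 0.60 and
P(Z=0|control) = 0.76 (implying a crude odds ratio of
(0.6/0.4)/(0.24/0.76) = 4.75), 20% of probes shifted between Z strata by
N(0, 0.5²) log2 effects resampled away from zero at |δ| ≥ 0.1, four
equal contiguous probe blocks driven by per-sample latent factors with
within-block correlation 0.6 (the third block re-uses the first block's
factor with negative loadings, emulating a pair of anticorrelated gene
clusters), total per-measurement noise SD 0.7, detection p-values from a
two-component model (U(0, 0.001) for expressed pairs, U(0, 1) for a 5%
background fraction), and covariates drawn per group (FRS truncated
normal at 0 — note truncation raises the realized means above the
nominal 5.8/2.6; age normal). Identical seeds give byte-identical
cohorts.

The **null** variant severs everything: zero effects, no factor
loadings (probes mutually exchangeable — required for per-dataset
p-value-fraction calibration, which with cohort-wide factors would have
only ~4 effective degrees of freedom), and Z an independent fair coin.

The **paired-stimulus** variant generates a small (default 8-subject)
baseline/post study whose per-probe shifts correlate with a supplied (or
freshly drawn) cohort effect vector at `cross_corr` for a `shared`
fraction of probes, with independent same-marginal shifts elsewhere;
measurement noise SD 0.2 and subject effects SD 0.3. With estimation
noise on both sides, a planted correlation of 0.6 is recovered at
r ≈ 0.50–0.56 over 2,000 genes (analytic attenuation ≈ 0.51).

### What the generator does not emulate

Array physics (dye/spatial artifacts, batch structure), race or
medication covariates, within-subtype heterogeneity beyond the factor
blocks, and realistic detection-call error models. Passing tests on
these cohorts demonstrate the machinery's statistical behaviour under
the planted model, not performance on real arrays.

## Problem sizes, determinism, numerics

The test-suite and acceptance-script simulation sizes (200 voting
repeats, 20–50 seeds for distributional checks, 10,000-probe null
calibrations) were chosen as the smallest sizes at which the checked
quantities stabilize. All stochastic steps take explicit seeds; repeat
streams derive from `SeedSequence([seed, repeat])`. Variance floors
(1e-12), the q-value clip to [0, 1], the strict vote threshold, and the
probe-id tie-break in gene ranking are the deliberate degenerate-input
rules; quantile-normalization ties average the spanned quantiles.

## Known limitations

* The voting procedure trains on case/control labels, which are a noisy
  surrogate of the latent subtype (sensitivity 0.60 / specificity 0.76
  dilutes per-probe contrasts by ×0.36). Under the default generator
  regime the assignment agrees with the planted subtype for ~82–95% of
  samples; residual misclassification attenuates the
  assignment-vs-phenotype odds ratio below the generator's closed-form
  4.75, typically into the 2.5–4.5 range, and at the cohort's size
  (n = 119) the odds ratio of even a perfect assignment fluctuates
  between roughly 1.5 and 9 across generator seeds.
* At null, cross-validated voting is not exactly calibrated: the
  assignment degenerates to a quasi-deterministic random split of the
  cohort, and when the SVM's majority-class bias makes the AWA side
  small, Haldane-corrected odds ratios can be extreme; with n = 119 the
  null odds ratio is heavy-tailed well beyond [0.5, 2].
* π̂₀ and the permutation FDR assume largely exchangeable probes;
  strongly factor-structured data (the signal cohort's blocks) widens
  the sampling variability of both.
* The adjusted logistic model offers no penalized fallback; separation
  is reported, not resolved.
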