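# awasig

Blood-transcriptome molecular-subtype discovery for case-control studies
of subclinical atherosclerosis (and, generically, any binary phenotype).

Peripheral-blood expression profiles carry a signal of atherosclerotic
burden that single-probe tests capture only weakly: in a cohort of ~119
women at low-to-intermediate Framingham risk (48 with subclinical
atherosclerosis, 71 without), per-probe t tests give a moderately
enriched p-value histogram but high false-discovery rates. `awasig`
implements the analysis strategy built for that situation:

1. **Preprocess** — quantile-normalize probe × sample log2 intensities
   and filter to analysis-ready probes (coefficient of variation
   ≥ 0.03 and detection-call p < 0.01 in more than half the samples).
2. **Differential expression** — per-probe Welch/pooled t tests with two
   FDR estimators: q-values with spline-smoothed π̂₀ (the estimated
   proportion of truly null probes; 1 − π̂₀ is the estimated fraction of
   differentially expressed probes), and a permutation procedure around
   the variance-stabilized statistic d = Δmean / (SE + s₀).
3. **Subtype discovery** — a multiple-random-validation vote: the cohort
   is split into 10 stratified folds; within each training set probes are
   ranked by |t| and the top k = 50 feed an RBF support-vector machine
   that classifies the held-out fold; the whole procedure is repeated R
   times (default 1,000) and a sample is called **AWA**
   (associated-with-atherosclerosis profile) iff it collects a strict
   majority (> R/2) of case-like votes.
4. **Association** — 2×2 odds ratio with Wald CI, sensitivity and
   specificity, chi-square/Fisher tests, and a covariate-adjusted
   logistic regression (`case ~ AWA + FRS`).
5. **Clustering** — average-linkage trees on 1 − Pearson-r distances,
   branch cutting, and branch-phenotype enrichment.
6. **Concordance** — cross-platform gene-symbol mapping and Pearson
   correlation of per-gene log2 fold changes against a paired
   baseline/post-stimulus study, with a hypergeometric overlap test.
7. **Synthetic cohorts** — a generator planting a latent subtype Z linked
   to case status by (sensitivity, specificity), a chosen fraction of
   Z-shifted probes, block-correlated probe groups, detection p-values
   and Table-1-style covariates, so the whole pipeline is testable
   without any data download.

## Worked example

```python
import numpy as np
from awasig import (AnalysisConfig, CohortSpec, generate_cohort,
                    quantile_normalize, filter_probes, welch_t, storey_qvalue,
                    multiple_random_validation, assign_subtypes,
                    crosstab, odds_ratio, adjusted_logistic)

spec = CohortSpec()                      # 48 cases / 71 controls, 2,057 probes
matrix, annotation, truth = generate_cohort(spec, seed=1)
labels = annotation["case_status"].to_numpy()

cfg = AnalysisConfig(min_detected_samples=61, rng_seed=1)
filtered, report = filter_probes(quantile_normalize(matrix), cfg)
print(report.n_retained)                 # 2057 analysis-ready probes

de = welch_t(filtered, labels)
q, pi0 = storey_qvalue(de.table["p"].to_numpy())
print(round((de.table["p"] < 0.05).mean(), 3))   # 0.07  (fraction p < 0.05)
print(round(1 - pi0.pi0, 3))                     # 0.073 (estimated DE fraction)

votes = multiple_random_validation(filtered, labels, cfg, n_repeats=200)
assignment = assign_subtypes(votes, cfg)
res = odds_ratio(crosstab(assignment, labels), correction="haldane")
print(round(res.odds_ratio, 2))          # 3.57
print(round(100 * res.sensitivity), round(100 * res.specificity))  # 58 72

adj = adjusted_logistic(assignment, labels, annotation[["frs"]].to_numpy())
print(round(adj.odds_ratio, 2))          # 4.14  (FRS-adjusted)

z = truth.subtype.to_numpy()
print(round((assignment["awa"].to_numpy() == z).mean(), 3))  # 0.958
```

The vote recovers the planted subtype for ~96% of samples on this seed,
and its association with case status (odds ratio ≈ 3.6 crude, ≈ 4.1
FRS-adjusted) sits in the regime the generator's
sensitivity-0.60/specificity-0.76 linkage implies (closed-form crude
odds ratio 4.75, attenuated by residual misclassification).

A command-line interface mirrors the library:

```bash
awasig simulate --seed 7 --out-prefix sim/
awasig preprocess --expr sim/expr.tsv --detection sim/detection.tsv --out filtered.tsv
awasig de --expr filtered.tsv --ann sim/ann.csv --out de.tsv
awasig subtype --expr filtered.tsv --ann sim/ann.csv --seed 7 --repeats 200 --out-prefix run/
awasig assoc --assignment run/assignment.tsv --ann sim/ann.csv --adjust frs --out assoc.json
```

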