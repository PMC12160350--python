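# cslv — chromosomal-scale length variation risk scoring

`cslv` builds germline cancer risk scores from SNP-array intensity data
using **chromosomal-scale length variation (CSLV)** features. It is
aimed at statistical-genetics researchers who have marker-level log R
ratio (LRR) data — the log of observed over expected probe intensity,
≈ 0 at two copies, negative under deletion, positive under duplication —
and want a copy-number-aware alternative to SNP-based polygenic risk
scores that works at modest cohort sizes.

## The statistic

Partition each autosome *c* (length *L_c*) into *k* equal base-pair
segments and average the LRR over the markers in each segment:

```
CSLV_{c,i} = mean{ LRR_m : marker m in segment i of chromosome c },  i = 1..k
```

The result is a nominal relative "length" for each chromosome region: a
22·k-dimensional summary of a genome's large-scale copy-number content
(88 features at the standard k = 4, 22 at k = 1). Averaging across
hundreds-to-thousands of markers suppresses per-marker noise while
retaining the structural signal. A classifier over these features is
the risk score; its quality is measured by the AUC (the Mann-Whitney
probability that a random case outscores a random control, ties counted
½) and, clinically, by quintile odds ratios

```
OR_q = (a_q / b_q) / (A / B)
```

with a_q/b_q the cases/controls in score quintile q and A/B the test-set
totals, Wald CI on log OR.

The package covers the full experimental loop: TSV IO for manifests,
LRR matrices (wide or Illumina-final-report long format) and phenotype
tables; segmentation and feature extraction; age-matched 40:60
case:control undersampling and label-stratified 80/20 splits; a model
zoo (gradient boosting, random forest, logistic regression, stacked
ensemble) evaluated with 5-fold CV and repeated runs; quintile
stratification; cross-population transfer grids and permutation
feature importance; and a seeded synthetic-cohort simulator with known
CNV ground truth for validating every step.

## Worked example

```python
from cslv import *

build = default_build()                       # 22 GRCh38 autosomes
L = build.length("3")
region = EffectRegion("3", 1, L // 4,         # deletion burden in chr3 q1
                      case_probability=0.5, control_probability=0.1,
                      lrr_shift=-0.5)
config = SimulationConfig(seed=1, n_cases=400, n_controls=1200,
                          markers_per_chrom=200, effect_regions=(region,))
manifest, lrr, cohort, truth = simulate_cohort(config)

features = compute_cslv(lrr, build_segments(build, manifest, k=4))
split = SplitSpec(seed=1)
matched = undersample_matched(cohort, split)   # all cases + age-matched controls
train, test = split_train_test(matched, split)
result = fit(features, train, ModelSpec(algorithm="gradient_boosting", seed=1))
print(evaluate(result, features, test))
```

Running this (it is `examples/02_train_and_evaluate.py`) prints

```
matched cohort: 1000 (400 cases), train 800 / test 200
cross-validation AUC: 0.648 (folds: [0.703, 0.638, 0.654, 0.644, 0.602])
test AUC: 0.733 (95% bootstrap CI 0.651-0.803)
```

i.e. the model recovers the planted deletion-burden difference well
above chance (AUC 0.5). Stratifying the same test scores into quintiles
(`examples/03_quintile_stratification.py`, a slightly larger cohort)
gives

```
quintile  n_cases  n_controls  odds_ratio   ci
5              40          20        3.00   (1.67, 5.38)
1              17          43        0.59   (0.32, 1.09)
top-vs-bottom quintile fold ratio: 5.1
```

— the top-scoring 20% has three times the population's case odds, and
5-fold the odds of the bottom quintile. `examples/04_transfer_across_groups.py`
shows the transfer grid: with group-specific risk regions the
within-group AUC stays high while cross-group AUC collapses to ~0.5.

A thin CLI wraps the same functions
(`cslv simulate|validate|features|cohort|train|stratify|transfer|run`);
see `cslv --help`.

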