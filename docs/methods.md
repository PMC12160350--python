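# Methods

## The CSLV transform

A genotyping array reports, per marker, the log R ratio (LRR): the log
of observed over expected probe intensity, centred at 0 for two copies.
CSLV summarises a genome by the mean LRR over each of *k* equal
base-pair segments per autosome (22·k features; 88 at the default
k = 4). The mean is the plain arithmetic mean of non-missing values —
no winsorising, GC-wave correction or probe filtering — on the view
that averaging over many markers already suppresses marker-level noise,
and that the target signal is large-scale copy-number burden rather
than local polymorphism.

Design choices that were genuinely open, and how they were fixed:

- **Equal base-pair span, not equal marker count.** The features are
  interpreted as nominal region "lengths", so segments are defined on
  the genomic coordinate frame; this also keeps segment definitions
  stable across datasets with different marker panels. An
  equal-marker-count mode exists (`build_segments(..., mode="markers")`)
  but is not the default.
- **Segment span is the assembly length**, not the first-to-last marker
  span, for the same stability reason. The default frame is the 22
  GRCh38 autosome lengths (packaged constant, user-overridable via
  TSV); sex chromosomes are excluded because their copy number is
  sex-dependent.
- **Boundaries** fall at `1 + round(i·L/k)` with round-half-up, giving
  half-open intervals that tile `[1, L+1)` with spans differing by at
  most 1 bp. A marker belongs to the interval containing its position;
  file coordinates are 1-based inclusive, internal intervals half-open.
- **Missing data.** A feature is missing for a sample when fewer than
  `min_markers` (default 1) non-missing LRR values fall in the segment.
  Real arrays carry thousands of markers per quarter-chromosome, so
  this only matters for toy panels. Model fitting imputes missing
  features with the training-fold column median.

## Cohort assembly

Case/control array datasets are heavily imbalanced, so the modelling
cohort keeps every case and undersamples controls to a 40:60
case:control ratio with age matching. The matching algorithm is greedy
nearest-age without replacement: cases are visited in seed-randomised
order and each draws its quota (alternating 2 and 1 at the default
ratio) of nearest-age unused controls, ties broken by sample id. This
is deterministic given the seed and auditable; optimal bipartite
matching was deliberately not used — the greedy scheme reproduces the
brute-force optimum on small instances (tested) and its residual
suboptimality is irrelevant next to sampling noise at cohort scale.
The train/test split is label-stratified, `round(0.2·n)` per class,
and errors out when a class has fewer than 5 members because the
downstream default is 5-fold cross-validation.

## Models and evaluation

The model zoo is fixed: scikit-learn histogram gradient boosting,
random forest (200 trees), L2 logistic regression on standardised
features, and a stacked ensemble (logistic meta-learner over the
members' out-of-fold predicted probabilities). An AutoML search was
deliberately replaced by this fixed zoo: the evaluation contract —
5-fold stratified CV on the 80% split, AUC on the untouched 20%,
repeated runs reported as mean ± sample sd — is what the science rests
on, and a fixed zoo makes it exactly reproducible. Deep learning is
excluded from the zoo. `time_budget_s` (default 900 s) is an advisory
cap echoed into reports; at the problem sizes here every member trains
in seconds.

AUC is computed by midrank (Mann-Whitney with ties credited ½), with a
stratified percentile bootstrap CI (2000 resamples, cases and controls
resampled separately); the bootstrap was chosen because no analytic CI
is exact under ties and arbitrary score distributions.

## Quintile stratification

Test samples are ranked by score descending (ties by sample id) and cut
into five bins whose sizes differ by at most one, larger bins assigned
to higher quintiles first. The odds ratio compares each quintile's case
odds with the *whole test population's* odds, `OR_q = (a_q/b_q)/(A/B)`;
the quintile-versus-complement variant is available via
`method="rest"`. The CI is Wald on log OR with
`se = sqrt(1/a + 1/b + 1/A + 1/B)` and Haldane–Anscombe +0.5 on all
four cells when any is zero. Under the population definition the
control-weighted ORs satisfy `Σ_q (b_q/B)·OR_q = 1` exactly, which the
tests assert to 1e-12. `cslv.published` ships a published reference
quintile table (2,015-sample test set) used purely for arithmetic
consistency checks; as documented there, its printed OR column is not
reproducible from its own printed counts by any standard 2×2 formula,
so this package exposes its formula explicitly and never claims to
match that column — the top-vs-bottom fold ratio (≈ 8.9, "nine times")
is taken from the printed column itself.

## Transfer across population groups

For each training group the pipeline assembles the matched cohort
*within* the group, splits 80/20, trains, and evaluates on the group's
own holdout, on every other named group in full (as-is by default;
optionally matched), on "other" (samples belonging to no named group)
and on "mixed" (everything outside the training group plus the
holdout — training samples never leak into a test pool). Repeating over
seeds gives mean ± sd AUC per cell. Feature attribution is permutation
importance on the held-out set (mean AUC drop over 10 shuffles of one
column); SHAP-style attribution is left as an optional integration, not
a core dependency — permutation importance is model-agnostic and works
for the stacked ensemble, which tree-specific explainers do not.

## The simulator

`simulate_cohort` emulates, at desk scale, the structure of an array
intensity dataset: marker LRR = per-sample baseline shift
(N(0, σ_sample), default 0.02) + shifts of covering CNV events +
independent marker noise (N(0, σ_marker), default 0.15 — a typical
per-probe array noise level). Markers are placed uniformly per
chromosome (default 500/chromosome ≈ a 1:165 downsample of a modern
array). Background CNVs arrive Poisson(2 events/genome), exponential
lengths (mean 5 Mb, large enough to move a quarter-chromosome mean),
deletion/duplication shifts −0.5/+0.3 with equal probability — standard
array-intensity magnitudes for single-copy changes. Designated *effect
regions* carry Bernoulli CNV carriage with class-specific (and
optionally group-specific) probabilities; they are the only mechanism
by which cases and controls differ, so the null model is exact by
construction. Ages are truncated Gaussians (cases N(62, 10), controls
N(55, 12), floor 18 — breast-cancer-like age structure that gives the
matcher real work). One global seed spawns independent substreams for
manifest, samples, events and noise, so the marker panel is invariant
to the sample count.

What the simulator does *not* model: LD structure, allele frequencies,
genotype calling, GC waves, batch effects, probe-quality variation.
Passing tests therefore demonstrate that the machinery is correct and
calibrated under a clean additive noise model, not that real data meet
the model's assumptions.

## Verification scenarios and problem sizes

The acceptance checks (tests and `scripts/acceptance.py`) use:

- **Null calibration**: 2,000 samples (800 cases), 500 markers per
  chromosome, no effect regions, five seeds; mean held-out AUC must sit
  in [0.45, 0.55] and all five quintile OR CIs must cover 1.0 in at
  least 4 of 5 seeds (five simultaneous 95% intervals are checked, so
  occasional single-seed misses are expected).
- **Signal recovery**: 3,000 samples, one effect region covering
  exactly segment 2 of chromosome 1 with a deterministic +0.017 LRR
  shift in cases, σ_sample = 0 and no background CNVs so the
  informative feature is Gaussian per class with sd σ_marker/√m and the
  best achievable AUC is exactly Φ(δ/(σ_f√2)) ≈ 0.80; the mean test
  AUC over five runs must land within 0.05 below that bound without
  exceeding it, and the affected segment must rank first in permutation
  importance. Baseline noise is switched off here because shared
  baseline variation is partially removable from other chromosomes'
  features, which would let a model beat the single-feature bound.
- **Resolution**: three quarter-segment effect regions (carriage 0.4 vs
  0.1, shift −0.4), 1,400 samples, five seeds; mean test AUC at k = 4
  must be at least that at k = 1, because whole-chromosome averaging
  dilutes sub-chromosomal signal 4-fold.
- **Transfer**: two equal groups, 1,900 samples; disjoint group-specific
  regions must give within-group > cross-group AUC (Welch test,
  α = 0.05, 5 runs per cell), and shared regions must close the gap.

These sizes were chosen as the smallest at which the expected effects
are comfortably resolved by the Monte-Carlo error of five repeated
runs; the whole verification suite completes in a few minutes on one
CPU.

## Known limitations

- The quintile OR definition follows the population-reference form; no
  absolute-risk calibration is attempted.
- Greedy age matching is 1:k nearest-age, not caliper- or
  propensity-based.
- The simulator's additive Gaussian noise cannot generate the heavy
  tails, waves and batch structure of real array intensities; findings
  about model *rankings* on simulated data need not carry over to real
  cohorts.
- CNV segmentation/calling (CBS, HMMs), BAF integration and probe
  weighting are out of scope by design.
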