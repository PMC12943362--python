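# Methods

`pfasmet` re-implements, as a tested pipeline over synthetic data, the
statistical workflow of an extreme-group untargeted serum metabolomics study
of PFAS exposure: a large source cohort is ranked by total serum PFAS, the
two 41-subject tails are profiled by LC-HRMS, and the feature matrix is
carried through quality control, pretreatment, differential analysis,
exposure association, panel construction, and pathway over-representation.
This note records the models, the defaults and their rationale, and the
numerical choices where the design was genuinely open.

## Censored exposure model

Serum PFAS concentrations are modeled per compound as lognormal and
left-censored at the limit of detection (LOD) and limit of quantification
(LOQ). When at least 30% of a compound's measurements are above the limit
(between-LOD-LOQ values count toward that fraction by default; a
quantified-only variant is exposed via `rule="loq"`), the censored-lognormal
parameters are estimated by maximum likelihood: observed values contribute
the lognormal density, below-LOD values the CDF mass on (0, LOD), and
between-values the mass on (LOD, LOQ). Optimization is Nelder-Mead on
(mu, log sigma) started from the log-moments of the observed values, with
sigma clamped to [1e-6, 10]; a non-convergent fit falls back to the
log-moment estimates with a warning. Censored entries are then replaced by
single random draws from the fitted distribution truncated to their
censoring interval (inverse-CDF sampling), additionally bounded above by ten
times the largest observed value as the plausibility bound. Compounds below
the 30% rule are left unimputed and their censored entries treated as
missing.

Subject totals use the simpler substitution rule the study design calls
for — values below LOQ replaced by LOQ/2 before summation — and the
extreme groups are the lowest and highest `n_per_group` subjects by total,
selected by rank with ties broken by subject id. Rank selection reproduces
an exact 41 + 41 split from 517 subjects unambiguously, which an
interpolated percentile cutoff does not.

Group comparability uses the Yates-corrected chi-square and the phi
coefficient for sex, the two-sided Mann-Whitney U for age/BMI/total, and
Cliff's delta for age and BMI with the consistent-variance estimator and
Cliff's asymmetric confidence interval (which respects the [-1, 1] range);
blood collection time gets a Welch t-test and Cohen's d.

## Synthetic data generator

The generator is the package's study surface: every downstream stage is
validated against its known ground truth. It emulates

- **Exposure**: a subject-level lognormal exposure factor (log-sd 1.2)
  multiplying 13 compound-specific lognormals whose medians are dominated by
  PFOS, with LOD/LOQ at 0.1/0.2 ng/mL. These defaults give a strong tail
  contrast (low-group median a few ng/mL, high-group median >100 ng/mL) and
  spread the compounds across the censoring spectrum so that both arms of
  the 30% rule are exercised.
- **Feature intensities**: lognormal per feature, baseline log-mean
  N(log 1e5, 1), biological log-sd uniform on [0.3, 0.8] — the lower end
  matches within-group median RSDs around 30% reported for serum profiling,
  the upper end reflects the heavier-tailed lipid features.
- **Planted effects**: a configurable feature subset shifted between groups
  on the log scale by d x sigma (Cohen's d scale); effect sizes default to
  U(0.8, 1.2). Because groups derive from the exposure factor, planted
  shifts correlate with total PFAS, exercising the Spearman stage.
- **Run structure**: randomized sample order, a pooled-QC injection every
  10 samples (technical noise set so the QC RSD hits a 10% target; the
  pooled level includes each group's share of the planted shift), and 8
  extraction blanks at ~1% of the feature level flanking the run.
- **Drift**: a per-feature smooth multiplicative drift in injection order —
  either a random cubic scaled to a configured peak-to-peak amplitude
  (default 0.3) or an exactly linear monotone profile (used by the drift
  acceptance test at amplitude 1.0 = two-fold).
- **Missingness**: two mechanisms — left-censoring below the 5% intensity
  quantile of each feature's observed run (MNAR, stresses detection-limit
  behaviour) and 2% uniform random dropout (MCAR, stresses the imputer).

All randomness flows from a single seed through named `SeedSequence`
sub-streams (one per feature), so output is byte-identical under a fixed
seed. What the generator does **not** emulate: chromatographic reality
(isotopes, adducts, co-elution), multi-batch structure, platform-specific
polarity differences, or covariate-exposure confounding. Passing tests
therefore demonstrate that the statistics behave as designed under their
stated model, not that the pipeline is robust to annotation error or batch
effects.

## Quality control

Drift correction fits, per feature with at least 4 observed QC injections,
a smoothing cubic spline to QC log-intensity versus injection order. The
smoothing factor is chosen by leave-one-out cross-validation over a grid of
multiples (0.25x to 50x) of the heuristic m x var; a floor above zero
prevents interpolation through QC noise, and a spline that cannot beat the
constant (no-drift) model in LOO error is discarded outright. Accepted
corrections subtract the spline on the log scale, re-anchored at the median
QC order, and are kept only if the feature's QC RSD actually decreases —
so flat features pass through untouched. Predictions outside the QC order
range are clamped to the boundary (no cubic extrapolation into the blank
segments). Missingness is never altered.

Feature filters, applied in the order blank -> detection -> RSD -> D-ratio
(the retained set is a conjunction and order-independent; the per-criterion
counts are reported in that order): maximum sample intensity at least 10x
the mean blank, detection in at least 75% of one sample group and 70% of
QCs, QC RSD < 30%, and D-ratio (sd in QC over sd in biological samples)
< 40%. D-ratio uses standard deviations, consistent with the RSD convention
beside it. Sample outliers are samples whose detected-feature count falls
outside Tukey fences (Q1 - 1.5 IQR, Q3 + 1.5 IQR) within their group;
their values are masked for downstream stages.

## Pretreatment

Missing biological values are imputed in the missForest style: starting
from median fill, each incomplete feature is regressed on all others with a
random-forest regressor (default 100 trees, mtry = sqrt(p)), sweeping
features from least to most missing, until the normalized change in the
imputed values rises or 10 sweeps elapse. Imputed values are bounded below
by half the feature's observed minimum so detection-limited features cannot
be imputed far above their censoring point. QC injections are imputed
separately by the per-feature QC median, keeping technical replicates out
of the biological imputation model. A fast median-fill variant is exposed
as a pipeline toggle and is used by the large-replicate validation runs,
where the imputation variant does not affect the quantity under test.

Normalization is log -> PQN -> Pareto. PQN divides each sample by the
median of its feature-wise quotients against the pooled-QC median spectrum;
on the log scale this is a subtraction of the median log-quotient, which is
identical to the natural-scale formulation whenever the median is an order
statistic (odd feature count) and differs only by a geometric-versus-
arithmetic interpolation of the two central quotients otherwise. Pareto
scaling centers each feature and divides by the square root of its standard
deviation (n-1), leaving the scaled variance equal to the raw sd; constant
features map to zeros and are flagged.

## Differential analysis

The univariate screen runs on raw post-filter intensities: Shapiro-Wilk per
group routes each feature to a pooled-variance t-test (both groups pass at
0.05) or a two-sided Mann-Whitney U (exact when both groups have n <= 8 and
no ties, tie-corrected normal approximation otherwise), Benjamini-Hochberg
across features, and selection at q < 0.05 with fold change (ratio of raw
group means, high/low) above 1.2 or below 0.8.

PLS-DA is fitted on the pretreated matrix by NIPALS on the centered class
indicator; the component count (1..5) maximizes Q2 = 1 - PRESS/TSS under
stratified 10-fold cross-validation, the cross-validated predicted scores
give the model AUC, and VIP_j = sqrt(p Σ_a SSY_a (w_ja/||w_a||)^2 / Σ_a
SSY_a), whose squared mean is exactly 1. The response-permutation test
refits the model (same component count) on each of n label permutations and
uses the prediction accuracy observed during training — the stratified
cross-validated class accuracy — as its statistic, with p = (#{perm >=
observed} + 1)/(n + 1). The resubstitution accuracy cannot serve here:
with features far outnumbering samples every refit classifies its own
training set perfectly, observed and permuted alike, and the test would be
blind by construction.

The random-forest route is a hand-rolled bagger over scikit-learn decision
trees (500 trees, sqrt feature subsampling) because the out-of-bag mean
decrease in accuracy is not exposed by stock implementations: each tree is
scored on its out-of-bag samples before and after permuting one feature,
with only the features the tree actually splits on needing re-prediction.
The importance threshold is the 95th percentile of the importances from a
label-permuted forest. Final selection is the union of the univariate rule
and the multivariate rule — VIP > 1 from models whose permutation p < 0.05,
intersected (default) with the RF top importances; the intersection keeps
the expected null selection well under the VIP rule's own ~25-30% false
positive mass, while the union with the univariate route preserves
sensitivity even when a platform's permutation test is non-significant and
its VIPs are discarded.

## Biomarker panel

Candidate metabolites are scored by Spearman correlation against total PFAS
(strength labels: |r| < 0.2 very weak, 0.2-0.39 weak, 0.40-0.59 moderate,
>= 0.60 strong), OLS sensitivity regressions on log intensities (unadjusted
and adjusted for sex, age, BMI, collection time, with variance inflation
factors from auxiliary regressions), and univariate ROC — AUC via the
U/(n1 n2) rank identity with a stratified 500-resample percentile bootstrap
CI, high exposure as the positive class and the AUC reported as computed,
not folded to >= 0.5.

The panel is built by (1) agglomerative clustering of candidates at
distance 1 - |Spearman| with average linkage into k = 5 clusters — absolute
correlation groups co-regulated features regardless of sign; (2) PLS-DA
VIP ranking over 100 balanced two-thirds subsamples, a feature scoring a
selection when it ranks in the top 12; (3) within each cluster, the member
of that top set with the highest univariate AUC (ties: higher frequency,
then lexical id), falling back to the cluster's best AUC with a warning
when no member ranks. Evaluation is Monte-Carlo cross-validation of a
linear SVM (C = 1, inputs already Pareto-scaled): per iteration a balanced
2/3 train / 1/3 test split, test decision values pooled into an ROC; the
panel AUC is the mean over iterations with a percentile 95% CI across
iterations, and class-label permutation (nulls rerun the MCCV at a reduced
iteration count, default 20) gives the significance. When the permutation
p must itself be validated for uniformity, the null iteration count is
matched to the observed one so the statistic stays exchangeable.

Effect sizes use Cohen's d with the pooled (n1 + n2 - 2) standard
deviation, and power comes from the noncentral t distribution with
noncentrality delta = d sqrt(n1 n2/(n1 + n2)) and df = n1 + n2 - 2,
two-sided at alpha = 0.05; power at d = 0 equals alpha exactly.

## Pathway over-representation

Enrichment is the one-sided hypergeometric (Fisher) tail of the overlap
between selected and pathway compounds over the detectable background, BH-
corrected across pathways, sharing the BH implementation with the feature
screen. Topology impact is the fraction of a pathway graph's total exact
betweenness centrality carried by the matched compounds (undirected,
unweighted); graphs with zero total centrality return 0. No database
content is bundled: database version and background choice dominate
published pathway p-values, so the library is an explicit input (JSON), and
the analysis driver builds a labelled synthetic library instead.

## Problem sizes and numerical notes

- The validation suite runs the end-to-end recovery check at the study's
  dimensions (2000 features, 41 + 41 subjects, 30 planted effects,
  20 replicates) with the inner iteration counts scaled to the package's
  test budget: PLS permutation n = 99, 300-tree forests, and the median
  imputation variant in those replicates. The panel permutation-uniformity
  check uses 200 null repetitions at 12 MCCV iterations with 59
  permutations each; the power function is checked against 100,000-draw
  Monte-Carlo t-test rejection rates.
- The acceptance script (`scripts/acceptance.py`) re-derives its quantities
  at the same dimensions with 5 end-to-end replicates and a full pipeline
  run at 400 features with the forest imputer (25 trees), finishing in a
  few minutes on one core.
- Degenerate inputs are defined rather than left to chance: constant
  features get p = 1 / FC = 1 in the screen and zeros under Pareto; a zero
  pooled sd makes Cohen's d NaN; empty selections propagate as warnings,
  not errors; all permutation p-values are bounded below by 1/(n+1).

## Known limitations

The permutation statistic's discrimination still degrades as features
dominate samples (cross-validated accuracy has finite resolution at n =
82), making the PLS-DA gate conservative on very wide matrices. The
missForest imputer is O(features^2) per sweep and is the slowest stage at
full width. Cliff's delta confidence intervals use the normal-theory
asymmetric interval, which is approximate at very small n. The synthetic
generator's single-run, single-platform design means multi-batch anchoring
and cross-platform VIP thresholds are untested territory.
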