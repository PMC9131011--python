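# Methods

`pdbiome` implements a case-control gut-microbiome analysis for
Parkinson's disease (PD) versus household controls (HC), operating on an
ASV count table, a taxonomy table, sample metadata and an optional rooted
phylogeny. This note documents the statistical models, the tunable
parameters and their defaults, the synthetic-cohort generator, and the
numerical and design choices a maintainer would want to know about.

## Pre-processing

**Prevalence filter.** A feature is *detected* in a sample if it has at
least one read; `filter_by_prevalence(table, fraction=0.10)` keeps
features detected in at least `floor(fraction * n_samples)` samples.
`floor` (rather than `ceil` or rounding) is deliberate: with 184 samples
a 10% rule gives a threshold of 18, and ties at the threshold are kept
("at least"). There is no minimum-count variant; detection is presence.

**Rank aggregation.** ASV counts are summed over shared genus / family /
order / phylum labels. ASVs unassigned at the target rank are pooled into
a reserved `__unassigned__` feature instead of being dropped, so column
sums are conserved exactly — the CLR transform and the diversity indices
both depend on per-sample totals. Aggregation and filtering do not
commute; the pipeline filters at the ASV level first, then aggregates.

## Community ecology

Alpha diversity: Shannon entropy in nats (the vegan default), the
Gini-Simpson index 1 − Σp², with inverse Simpson 1/Σp² behind a flag, and
richness as the count of detected taxa. Beta diversity: Bray-Curtis on
raw counts (vegan's default scale; a proportion mode is available by
passing relative abundances), and unweighted / normalized-weighted
UniFrac computed through scikit-bio against the supplied rooted tree.

**PCoA** is classical metric scaling: eigendecomposition of the
Gower-centered squared-distance matrix. Negative eigenvalues (from
non-Euclidean dissimilarities) are reported unmodified but excluded from
the returned axes and from the proportion-explained denominator; no
Lingoes/Cailliez correction is applied by default. For Euclidean input
the embedded coordinates reproduce the distances to 1e-8.

**PERMANOVA** is implemented directly from the hat-matrix formulation:
with G the Gower-centered inner-product matrix and H(X) the projection
onto a design matrix, a term's sum of squares is tr(H_full G) −
tr(H_reduced G) and the pseudo-F scales it against the full-model
residual. Two modes exist: sequential (terms added in column order) and
marginal (each term against the model containing all others, the
`adonis2(by = "margin")` convention). P-values permute raw sample labels
freely: p = (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations), default
9,999 permutations, seed mandatory. For a single two-level factor an
`exact` mode enumerates every distinct label assignment, which is what
the test suite compares against a brute-force within/between
sum-of-squares oracle. Confounded designs (a term adding no rank) raise
an error naming the term.

## Differential abundance

An expected-value Monte-Carlo test in the ALDEx2 style:

1. For each sample, draw `n_mc = 128` compositions from
   Dirichlet(counts + 0.5). The 0.5 prior is the ALDEx2 default; the
   tool's published parameterisation fixes `mc.samples = 128` and the
   denominator "all features".
2. CLR-transform each instance with base-2 logs against the geometric
   mean over **all** features; each sample's CLR vector sums to zero.
3. Per instance: Welch (unequal-variance) t-test per feature between the
   two groups, Benjamini-Hochberg adjustment across features within the
   instance.
4. Report per feature the arithmetic mean of p and of adjusted p over
   instances ("expected p"), the median between-group CLR difference
   (log2 fold change, so `fold_change = sign * 2^|median difference|`),
   and an effect size: median CLR difference over the median within-group
   spread.

The volcano significance flag is `-log10(expected p) > 3` **and**
`|fold change| > 1.2`; the log base, both thresholds, and whether raw or
BH-adjusted p feeds the flag are parameters (raw is the default). Because
CLR uses base-2 logs, a "2.7-fold" difference means 2^(median CLR
difference) = 2.7.

## Association screening

Spearman correlations between clinical covariates and taxon relative
abundances (CLR input is a caller choice), pairwise-complete, with the
t approximation for p (df = n − 2). The partial variant rank-transforms
x, y and the covariates (binary string covariates such as sex are encoded
0/1 first), residualizes the ranked x and y on the ranked covariates by
least squares with intercept, and correlates the residuals; p uses
df = n − 2 − k. With zero covariates this is *exactly* the ordinary
Spearman coefficient, which the tests assert. Strength bins on |rho|:
&lt; 0.2 none, [0.2, 0.4) weak, [0.4, 0.6) moderate, ≥ 0.6 strong, binned
strictly with a borderline annotation within 0.002 of a boundary. No
multiplicity correction is applied by default; BH is available and
recorded when used.

## Prediction

**Single stage.** A random forest (500 trees by default, √p features per
split, unlimited depth — the R randomForest defaults) on relative
abundances at one rank, evaluated by leave-one-out cross-validation.
Every sample is scored by a forest trained on all other samples; AUC is
the Mann-Whitney rank statistic with ties counted one half. Per-fold
seeds derive from the master seed and the held-out sample's ID, not its
position, so results are invariant to input row order (rows are also
sorted canonically before folding). An RBF support-vector machine runs
through the identical harness as a comparator, scored by its decision
function.

**Two stage.** Stage 1 fits a decision stump on one macronutrient:
exhaustive search over midpoints between consecutive distinct values,
maximizing information gain (Shannon entropy, bits) on the PD/HC labels.
Thresholds leaving fewer than 25% of samples on either side are
inadmissible — the split exists to define two sub-cohorts each large
enough to train a classifier, and without the control noise-driven tail
splits carve off strata too small to model. Stage 2 trains one forest
per sub-cohort; each held-out sample is scored by its stratum's model
and all n scores pool into a single ROC/AUC, with sensitivity and
specificity reported at the Youden-optimal point. A size-weighted mean
of per-stratum AUCs is reported alongside as the alternative pooling.

By default the stump is refit inside every training fold so the held-out
sample never influences its own partition. A reporting mode
(`refit_split_in_fold=False`) fits the stump once on the full cohort —
this reproduces published full-cohort split nodes but leaks the held-out
label into the partition, and emits a warning saying so. Training strata
with fewer than 5 members (or one class) fall back to a whole-fold model
for that sample; fallbacks are counted in the result. A constant
partition variable reduces the procedure exactly to the single-stage
harness. `survey_macronutrients` repeats the two-stage fit for each
candidate nutrient (grams/day and %-energy variants both qualify) plus
the single-stage baseline and ranks by AUC.

%-energy variables use 16.7 kJ/g for protein and carbohydrate and
37.7 kJ/g for fat.

**What stratification costs.** Under a genuinely global effect the
partition gives each stage-2 forest roughly half the training data. When
the signal is strong the half-cohort models saturate and the pooled AUC
matches the single model to within noise (the tests demonstrate ≤ 0.05 at
a planted log2 effect of 2.5); at weak-to-moderate signal the halving
costs a real 0.05–0.10 AUC. The two-stage model is therefore only
preferable when the microbiome signal actually differs between nutrient
strata — which is exactly the hypothesis it encodes.

## Cohort summary statistics

`cohort_stats` recomputes two-sample statistics from printed summaries:
the pooled-variance t (df = n₁+n₂−2, sign = group1 − group2) from
(mean, SD, n) pairs, and the 2×2 Pearson chi-square without continuity
correction from (percentage, n) pairs, reconstructing integer counts by
nearest-integer rounding of pct × n. A Welch/Satterthwaite variant
annotates continuous rows whose printed statistic the pooled form misses.
A row "matches" only if the recomputed statistic rounded to one decimal
equals the printed value; rows that match under neither t-variant are
reported as discrepancies and never force-fit. In the bundled 103-vs-81
cohort table, ten rows verify exactly and are the package's desk-scale
regression surface; known non-reproducing rows (Bristol stool score,
total cholesterol, Beck depression, daily caffeine cups) stay flagged.

## Synthetic cohort generator

The generator emulates the inputs the pipeline consumes, not raw reads.
One `numpy.random.Generator` seeded from the config drives everything,
consumed in a fixed order (taxonomy, tree, baselines, planted taxa,
metadata, counts), so equal configs give bit-identical cohorts.

**Counts.** Baseline log relative abundances are Normal(0, 1.5²) per
ASV. Each sample adds Normal(0, 0.8²) log-jitter (biological
between-sample variation), applies its group/stratum effect, and the
composition is drawn from a Dirichlet with concentration 1000 on the
resulting proportions before a multinomial at a log-normal library size
(mean 50,000, CV 0.4). Most overdispersion therefore lives in the
logistic-normal layer. This split matters: pushing the overdispersion
into a low-concentration Dirichlet amplifies a planted log2 shift by the
digamma nonlinearity (measured ~1.8× at concentration 40), whereas this
parameterisation transmits planted effects onto the CLR scale
approximately 1:1 (measured 2.0–2.3 for a planted 2.0), which is what
the recovery tests assume. Planted taxa are drawn from the upper half of
baseline abundance so signals are detectable at realistic depth.

**Taxonomy and tree.** A nested random hierarchy scaled from 627 ASVs
carrying 9 phyla / 31 orders / 48 families / 138 genera, with a ~3%
genus-unassigned tail; a random binary rooted tree with exponential(0.1)
branch lengths over the ASVs.

**Metadata.** Age, BMI, clinical scores per group as Normals with the
cohort's published means/SDs (PD: age 67.1 ± 12.2, CCS 7.2 ± 4.7, …;
HC: 62.4 ± 15.6, 3.1 ± 2.9, …); macronutrients as log-normals matched to
the published arithmetic moments (right-skewed intake data); sex as
Bernoulli with per-group rates (balanced by default, imbalance available
to mirror the real cohort); UPDRS-III and levodopa-equivalent dose only
for PD. Total energy is the macronutrient energy plus a ~5%
non-macronutrient residual, and %-energy columns derive from it.

**Planted effects.** Without `stratum_effect`, PD samples get a
`+effect_log2` shift on one planted set. With `stratum_effect`, two
disjoint sets act in *opposed* directions per stratum — set A is
overrepresented in PD below the nutrient threshold and underrepresented
above it, set B the reverse — and group prevalence shifts across the
boundary: P(high stratum | PD) = `stratum_label_coupling` (default 0.7),
with the nutrient drawn from the group log-normal truncated to the
assigned side. Both ingredients are necessary, not decorative: with
merely disjoint same-direction sets a single forest learns both sets and
never trails the two-stage model, and without the label-prevalence change
at the boundary no information-gain stump can recover the threshold.
The default threshold (240 g/day carbohydrate) sits near the cohort
median so both strata are populated. `truth` records the planted sets,
directions are fixed by convention (low-set up in the low stratum), the
threshold and the coupling.

**What the generator does not emulate:** read-level noise and denoising
artefacts, longitudinal structure, taxon-taxon ecological correlation
beyond compositional closure, covariate-microbiome confounding other
than the designed nutrient coupling, and missing metadata. Passing the
recovery tests therefore shows the estimators are correct and calibrated
under the generating model — not that effects of this size are
recoverable in any particular real cohort.

## Problem sizes in the test and acceptance runs

The statistical test conditions use scaled cohorts chosen as the
smallest sizes at which the properties under test are comfortably
identifiable: differential-abundance recovery at n = 100+100 with 200
taxa and 5 planted (log2 effect 2, 128 MC instances); two-stage
superiority at n = 60+60 with 100 taxa, 8 planted per set, log2 effect
1.0 and coupling 0.7, forests of 64 trees; the global-effect control at
log2 effect 2.5; stump recovery at coupling 0.99 (a sharp boundary is an
identification requirement — changepoint error grows geometrically in
the minority-label probability); PERMANOVA calibration at n = 12 with
199 permutations over 200 replicates.

## Known limitations

- The expected-p of the Monte-Carlo test is mildly conservative under
  the null (Dirichlet noise flattens small p-values), which the
  calibration band in the tests accommodates.
- PERMANOVA permutes samples freely; no strata/blocking support.
- The stump searches one variable at a time; no multivariate stage-1.
- Pooled two-stage scores mix two forests' probability scales; when
  strata priors differ the offset itself carries nutrient information
  into the ROC. That is intended (the partition variable is part of the
  model) but means the pooled AUC is not a pure microbiome-signal
  measure; the per-stratum AUCs are reported for that purpose.
- `verify_table` reconstructs categorical counts by rounding pct × n and
  cannot disambiguate percentages computed on non-respondent-adjusted
  denominators; such rows surface as discrepancies.
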