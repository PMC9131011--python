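# pdbiome

Gut-microbiome community analysis and nutrient-stratified prediction of
Parkinson's disease (PD) from 16S ASV tables.

Cross-sectional case-control microbiome studies compare PD patients with
household controls (HC) using an amplicon sequence variant (ASV) count
table, a taxonomy assignment, rich clinical metadata and dietary intake.
`pdbiome` implements that full downstream workflow as a reusable, tested
library and CLI, for bioinformaticians and biostatisticians analysing
16S case-control cohorts:

- **Feature tables** — TSV I/O with strict validation, the 10%-detection
  prevalence filter (with 184 samples: present in ≥ 18), aggregation to
  genus/family/order/phylum with column sums conserved.
- **Community ecology** — Shannon (H = −Σpᵢ ln pᵢ), Gini-Simpson
  (1 − Σpᵢ²), richness; Bray-Curtis (1 − 2Σmin(uᵢ,vᵢ)/(Σu+Σv)),
  unweighted/weighted UniFrac against a rooted tree; PCoA; PERMANOVA
  with marginal terms, 9,999 permutations and exact enumeration for
  small designs.
- **Differential abundance** — an ALDEx2-style expected-value test:
  128 Monte-Carlo Dirichlet(counts + 0.5) instances per sample, CLR
  transform (log2, geometric mean over all features), per-instance
  Welch t with Benjamini-Hochberg, expected p over instances, and
  volcano flags at −log₁₀(p) > 3 and |fold change| > 1.2.
- **Associations** — Spearman screens between clinical covariates and
  taxa, and partial Spearman adjusting for age, sex and BMI
  (rank-residual construction), with the weak/moderate/strong bands
  used in the clinical literature.
- **Prediction** — random-forest PD classifiers scored by leave-one-out
  cross-validated AUC (Mann-Whitney statistic), and the two-stage model:
  a maximum-information-gain decision stump on a macronutrient splits
  the cohort into sub-cohorts, one forest per sub-cohort, all held-out
  scores pooled into a single ROC. A survey utility ranks candidate
  macronutrient partitions by AUC.
- **Cohort statistics** — pooled t and Pearson χ² recomputed from
  printed (mean, SD, n) and (%, n) summaries, with Welch diagnostics and
  honest flagging of rows that do not reproduce.
- **Synthetic cohorts** — a generator producing counts (log-normal
  baseline + Dirichlet-multinomial), taxonomy, tree and metadata with
  planted group effects, optionally stratum-specific (the informative
  taxa reverse direction across a nutrient threshold), so every stage is
  testable without sequencing data.

## Worked example

A synthetic cohort of 60 PD + 60 HC with a *stratum-specific* effect:
eight taxa are overrepresented in PD among low-carbohydrate consumers
and underrepresented among high consumers, eight more the reverse, with
the boundary planted at 240 g/day.

```python
from pdbiome import SimulationConfig, generate_cohort
from pdbiome.tables import filter_by_prevalence, relative_abundance
from pdbiome import ecology, diffabund, prediction

cohort = generate_cohort(SimulationConfig(
    n_group_a=60, n_group_b=60, n_asv=100, n_differential=8,
    effect_log2=1.0, stratum_effect=True, seed=42))
table = filter_by_prevalence(cohort.counts)

dm = ecology.bray_curtis(table)
res = ecology.permanova(dm, cohort.metadata[["group"]],
                        n_permutations=999, seed=42)
# -> PERMANOVA group: F = 1.13, R2 = 0.010, p = 0.301

feats = relative_abundance(table).T
labels = cohort.metadata["group"]
_, auc1 = prediction.loocv_single(feats, labels, seed=42, n_estimators=64)
two = prediction.loocv_two_stage(feats, cohort.metadata, labels,
                                 "carbohydrate_g", seed=42, n_estimators=64)
# -> single-stage LOOCV-AUC = 0.525
# -> two-stage   LOOCV-AUC = 0.775
#    (split at carbohydrate 224.2 g/day, sens 0.58, spec 0.85)
```

The numbers carry the package's central point. Pooled over the whole
cohort the group signal nearly cancels — PERMANOVA sees no community
difference (p = 0.30) and a single random forest is near chance
(AUC 0.53) — because each planted taxon moves in opposite directions in
the two nutrient strata. The two-stage model recovers the structure: its
stump lands near the planted 240 g/day boundary (224.2 g/day is within
the data spacing) and the per-stratum forests lift the pooled AUC to
0.78. With a single global effect instead (`stratum_effect=False`), the
same two models agree to within noise, so the partition costs nothing
when it is not needed.

The same pipeline runs from the shell:

```bash
pdbiome simulate --n-pd 60 --n-hc 60 --n-asv 100 --stratum-effect \
    --effect 1.0 --seed 42 --out-dir sim/
pdbiome predict --counts sim/counts.tsv --taxonomy sim/taxonomy.tsv \
    --metadata sim/metadata.tsv --rank genus --two-stage \
    --nutrient carbohydrate_g --seed 42 --out prediction.json
pdbiome pipeline run config.txt     # full multi-stage run with manifest
```

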