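# prs-gxe

Polygenic risk score construction and gene–lifestyle interaction analysis
for gestational diabetes (GDM) prevention cohorts.

Lifestyle intervention trials for GDM prevention report heterogeneous
effects, and one plausible moderator is genetic predisposition to type 2
diabetes. This package implements, as a tested and reusable pipeline, the
secondary-analysis workflow used to ask that question in a randomised
pre-/early-pregnancy lifestyle intervention cohort: build a type 2 diabetes
polygenic risk score (PRS) from a focused SNP panel, derive the glycaemic
and lifestyle phenotypes, and test whether the PRS modifies the
intervention's effect on GDM and on postpartum glycaemic abnormalities.
Because informed consents for such cohorts do not allow open archiving of
clinical data, the package includes a first-class synthetic-study generator
that reproduces the statistical structure the analysis assumes, so every
stage is testable end to end without any data download.

It is intended for biostatisticians and genetic epidemiologists who want a
transparent, scriptable implementation of this analysis pattern — or a
simulation bench for designing similar gene–environment studies.

## What it computes

**Score construction** (PLINK/PRSice conventions):

- Variant QC: exclude variants with minor allele frequency < 0.05, call
  rate < 0.9, or exact Hardy–Weinberg p < 1e-4; exclude samples missing
  > 10% of genotypes. The Hardy–Weinberg test is the exact conditional
  test on allele counts (no mid-p).
- Greedy LD clumping, p-value ordered: index p ≤ 1, r² ≥ 0.5 (Rogers–Huff
  dosage correlation), 250 kb window.
- PRS: `S_i = Σ_j β_j · d_ij`, where `d_ij` is sample *i*'s dosage of the
  GWAS effect allele at SNP *j* (allele-aligned, strand-complemented,
  palindromic SNPs excluded, missing dosages mean-imputed) and the sum runs
  over SNPs with GWAS `p < 5e-8`. Scores are z-standardized within the
  cohort.

**Phenotypes**: HOMA-IR `= G·I/22.5` and HOMA-B `= 20·I/(G − 3.5)` (G in
mmol/l, I in µU/ml, insulin converted from pmol/l at 6.0 pmol/l per µU/ml);
HbA1c % → mmol/mol by the IFCC master equation `10.929·(pct − 2.15)`; GDM
from a 75 g OGTT (0 h ≥ 5.3, 1 h ≥ 10.0, 2 h ≥ 8.6 mmol/l, any one value
diagnostic), including early- and booking-GDM flags; postpartum
IFG/IGT/T2D classification; an 18-point healthy food intake index; a
5-point lifestyle-goal success score.

**Analysis**: logistic regression

```
logit P(Y=1) = β0 + β1·PRS + β2·group + β3·PRS×group + γ·covariates
```

with Wald inference on the interaction term β3; PRS-tertile
stratification; per-tertile intervention odds ratios; ANCOVA-style
covariate-adjusted occurrence (estimated marginal means of a linear
probability model); Pearson χ² contingency tests; and a per-SNP
dosage×intervention scan.

**Simulation**: haplotype-chain LD blocks (adjacent-variant haplotype
correlation ρ gives dosage r² ≈ ρ²), GWAS weights with an exactly
controlled genome-wide-significant causal subset, and a liability-scale
cohort model with a PRS×intervention interaction (linear in the score, or
as per-tertile intervention odds ratios). OGTT and postpartum glucose
values are drawn conditionally on the sampled labels, so the phenotype
classifiers recover the planted truth exactly.

## Worked example

Simulate a study of 529 women on a 200-SNP panel, run QC, clump, score,
derive phenotypes, and fit the interaction models:

```
$ prs-gxe simulate --out-dir demo --seed 7
simulated 529 samples x 200 variants -> demo
$ prs-gxe qc --genotypes demo/genotypes.vcf --out-dir demo/qc
QC: 529->529 samples, 200->196 variants
$ prs-gxe score --genotypes demo/qc/genotypes_qc --base demo/base.tsv --out demo/scores.tsv
scored 529 samples on 50 SNPs
$ prs-gxe phenotype --cohort demo/cohort.csv --out demo/cohort_derived.csv
derived phenotypes for 529 subjects -> demo/cohort_derived.csv
$ prs-gxe analyze --cohort demo/cohort_derived.csv --scores demo/scores.tsv \
      --outcome gdm --out demo/analysis.json
interaction p = 0.005689 -> demo/analysis.json
```

Of the 200 simulated variants, 196 survive QC and the 50
genome-wide-significant ones enter the score. The analysis excludes women
whose GDM was already present at enrolment ("booking GDM"), leaving n=446
here, and finds a negative PRS×intervention coefficient (−0.56 per SD of
PRS, p = 0.0057): the intervention's benefit grows with genetic risk. The
per-tertile intervention odds ratios in `demo/analysis.json` show the
pattern concretely — low 1.63 (95% CI 0.83, 3.21), medium 1.06 (0.54,
2.06), high 0.52 (0.26, 1.02): only at high genetic risk does the
intervention point towards protection (this simulated draw, with a
generative interaction of −0.45, sits just short of per-tertile
significance at n=529).

The same stages are available as library functions (`prs_gxe.apply_qc`,
`prs_gxe.clump`, `prs_gxe.compute_prs`, `prs_gxe.fit_interaction_model`,
…), and `prs-gxe run --config run.yaml` executes the whole chain from a
single YAML file with a stage-by-stage report.

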