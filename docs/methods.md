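# Methods

## The analysis in one paragraph

The pipeline estimates whether genetic predisposition to type 2 diabetes
modifies the effect of a pregnancy lifestyle intervention. Genotypes from
a focused SNP panel pass PLINK-style quality control and greedy LD
clumping; surviving variants with genome-wide-significant external GWAS
associations (p < 5e-8) are combined into a weighted polygenic risk score
(PRS), z-standardized within the cohort. Gestational diabetes (GDM) and
12-month-postpartum glycaemic abnormality are derived from OGTT and
fasting measurements by fixed diagnostic thresholds. The central model is
a maximum-likelihood logistic regression
`outcome ~ PRS + group + PRS×group + covariates`, with Wald inference on
the interaction; the effect is then displayed as per-PRS-tertile
intervention odds ratios and covariate-adjusted occurrences. Women whose
GDM was already present at the enrolment OGTT ("booking GDM") are excluded
from intervention-effect models, since no intervention can prevent a
diagnosis that precedes it.

## Statistical components and their assumptions

**Hardy–Weinberg exact test.** The two-sided exact test conditional on
allele counts: all heterozygote counts of matching parity are enumerated
through the stable ratio recurrence, and the p-value sums the
probabilities of configurations no more probable than the observed one
(no mid-p adjustment, matching PLINK 1.9's default). A relative guard of
1e-9 on the "no more probable" comparison keeps mathematically tied
configurations together despite floating-point round-off; the test suite
pins the result to an exact integer-arithmetic enumeration to 1e-12 for
every table with up to 50 subjects.

**LD r².** Squared Pearson correlation of unphased dosages over
pairwise-complete samples (the Rogers–Huff genotype estimator). This is
deterministic and close to PLINK's haplotype-frequency estimate for data
in Hardy–Weinberg proportions, which QC enforces; phased or EM-based
estimation is deliberately out of scope. Pairs that are monomorphic in
their overlap have undefined r²; the clumper treats them as r² = 0 and
logs the event.

**Clumping.** Greedy by ascending GWAS p-value with ties broken by
position and then id, so the index set is invariant to input order (the
reference tool leaves tie order unspecified). Membership uses r² ≥
threshold (inclusive) within an inclusive ±window in base pairs,
index-to-candidate. Variants above the index p-value ceiling may join
clumps but never found them.

**Scoring.** Effect alleles are matched to the dosage-counted allele
directly, by flip (dosage → 2 − d), or after strand complementation;
palindromic A/T and C/G variants are excluded by default because their
strand cannot be resolved from alleles alone. Missing dosages are
mean-imputed with twice the cohort effect-allele frequency (the PRSice
default) so every sample is scored on the same variant set; an `omit`
policy is available. The raw score is a plain weighted sum — per-allele
averaging is a monotone transform with no effect after standardization.
Odds ratios downstream are therefore "per SD of PRS", the interpretable
scale when the external weights' unit is arbitrary.

**Interaction model.** Logistic regression fitted by Newton–Raphson
maximum likelihood (statsmodels), Wald CIs and p-values, matching standard
epidemiological software output. Non-convergence, a score-vector norm
above 1e-4, or implausibly large coefficients/standard errors (signs of
separation) raise a diagnostic error rather than returning silent
estimates. Complete-case analysis per model; no imputation of phenotypes.

**Adjusted occurrence.** The per-cell adjusted outcome proportions are
estimated marginal means of a *linear* probability model with a full
tertile×arm cell structure plus centred covariates, i.e. classical ANCOVA
applied to a binary outcome. This mirrors how such adjusted percentages
are conventionally produced in clinical reporting; it is not logistic
marginal standardization, and CIs may extend slightly outside [0, 1] in
extreme cells.

**Tertiles.** Rank-based split with sizes ⌊n/3⌋/⌈n/3⌉ and the remainder
allocated upward, so n=529 yields 176/176/177; ties broken by stable input
order.

**Contingency tests.** Pearson χ² without continuity correction,
df = k − 1. A fixture utility inverts printed "n (%)" table cells back to
per-group denominators, requiring the reconstruction to reproduce every
printed percentage at its printed precision and to sum to the printed
total.

**Diagnostic thresholds.** All cut-offs are inclusive as printed: GDM at
0 h ≥ 5.3, 1 h ≥ 10.0, 2 h ≥ 8.6 mmol/l; postpartum T2D at fasting ≥ 7.0
or 2 h ≥ 11.1 mmol/l. The printed IFG (6.1–6.9) and IGT (7.8–11.0) bands
are stated for one-decimal clinical values; they are implemented as the
contiguous half-open intervals [6.1, 7.0) and [7.8, 11.1) so that the
classification is monotone in glucose and no value falls between bands.
Prior physician-diagnosed diabetes forces an abnormal classification. A
missing measurement yields a missing diagnosis, never a negative one.
Insulin is converted at 6.0 pmol/l per µU/ml (a common clinical
convention; the factor is a configurable argument since source data rarely
state it).

## The synthetic-study generator

The generator's defaults are the study conditions the pipeline is meant
for, and they stay fixed:

| parameter | default | rationale |
|---|---|---|
| `n_samples` | 529 | cohort with complete genetic data |
| `n_blocks` × `snps_per_block` | 50 × 4 = 200 | focused genotyping panel |
| `frac_causal` | 0.25 | exactly 50 genome-wide-significant SNPs enter the score |
| `within_block_ld` | 0.7 | adjacent dosage r² ≈ 0.49, straddling the 0.5 clumping threshold |
| `maf_range` | (0.05, 0.5) | panel designed on common variants |
| `beta_sd` | 0.1 | log-OR per allele typical of T2D GWAS hits |
| `intercept_logit` | −0.05 | GDM prevalence ≈ 49% in this high-risk population |
| `beta_prs` | 0.28 | OR ≈ 1.32 per SD of PRS for GDM |
| `beta_group` | 0.0 | no overall intervention main effect |
| `beta_interaction` | −0.45 | intervention benefit concentrated at high genetic risk |
| `intercept_pp_logit` | −1.8 | ≈ 15% postpartum abnormality prevalence |
| `missing_rate` | 0.02 | realistic genotyping dropout |

LD is generated by a first-order Markov chain on haplotypes: within a
block every variant shares the block's allele frequency, and each
haplotype allele copies its left neighbour with probability ρ
(`within_block_ld`), else is redrawn. This gives adjacent-variant
haplotype correlation exactly ρ, hence dosage r² ≈ ρ², in closed form —
chosen over multivariate-normal thresholding precisely because the
expected r² is exact and testable. Blocks sit > 250 kb apart; within-block
variants < 250 kb apart, so the clumping window aligns with block
boundaries.

Covariates (age, pre-pregnancy BMI, parity, smoking, education years) are
drawn independently of genotype, reflecting the empirical finding that
genetic-risk tertiles do not differ in background characteristics; this
keeps confounding out of the null simulation by construction (effects can
be injected via `covariate_effects`). Randomisation is 50/50, and
pre-pregnancy vs early-pregnancy recruitment is 50/50 (arm sizes within
tertiles are not published; 50/50 is the design allocation). Among
simulated GDM cases, 60% surface at the first-trimester OGTT (booking, for
early-pregnancy recruits) and the rest in the second trimester, with no
further OGTT after a diagnosis — mirroring the trial protocol.

OGTT triples, postpartum fasting/2 h glucose, and physician-diagnosis
flags are drawn *conditionally on the sampled outcome labels*, truncated
at the diagnostic thresholds, so the phenotype classifiers round-trip the
planted truth exactly — giving the classifier tests a known ground truth.
Visit-level fasting glucose and HbA1c rise linearly in the true score
(≈ 0.04 mmol/l and 0.03 %-points per SD), and fasting insulin is derived
from a HOMA-B value declining at 8 points per SD, matching the direction
and order of magnitude of the reported associations.

The interaction enters the liability either linearly
(`beta_group + beta_interaction·s`) or, via `tertile_group_log_or`, as a
step function of the true-score tertile. The step mode exists because a
"no effect, no effect, OR 0.4" pattern — the qualitative headline the
end-to-end calibration targets — is not representable by a linear
interaction.

One master seed feeds named substreams (genotypes, weights, arm,
covariates, outcome, OGTT, markers, diet, postpartum, missingness), so
adding a generator never perturbs the draws of another, and identical
configs reproduce studies bit-for-bit.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: population structure and relatedness,
imputation uncertainty, X-chromosome dosage, Hardy–Weinberg violations,
genotyping batch effects, informative visit non-attendance, measurement
error correlated across visits, and real LD beyond the first-order block
model. Calibration results (CI coverage, type-I error) are statements
about the inference machinery under the assumed generative model, not
about robustness to these complications.

## Problem sizes and numerical choices

Simulation calibrations run at n = 2000 with a reduced 24-SNP panel
(8 blocks × 3 SNPs, 6 causal): the panel size only affects score
measurement error, which is already negligible at 6 causal SNPs, while
n = 2000 gives the interaction test enough power for meaningful coverage
and type-I statements. Coverage uses 200 replicates, type-I error 200,
and the full-pipeline headline check 100. Replicates that fail to fit
(separation) count against the claimed property rather than being
redrawn. The exact-test oracle sweep is exhaustive for all 23,425
genotype tables with ≤ 50 subjects; the clumping oracle comparison uses
randomized panels of ≤ 12 variants where brute force is tractable.

Tie-breaking and tolerance choices: clumping ties on p broken by
(position, id); HWE tie guard 1e-9 relative; logistic convergence
declared only with score norm < 1e-4; z-standardization uses the n−1
denominator. Degenerate inputs raise typed errors (`ValidationError` /
`ComputationError` subclasses) rather than returning sentinel values, and
the CLI maps the two families to exit codes 2 and 3.

## Known limitations

- The ANCOVA-style adjusted occurrence is a linear model on a binary
  outcome (faithful to conventional reporting practice, not to modern
  marginal-standardization practice).
- Insulin-secretion inference rests on fasting HOMA indices only; no
  OGTT-curve disposition indices are computed.
- Clumping uses the cohort's own genotypes as the LD reference; no
  external reference panel is supported.
- The per-SNP interaction scan applies no multiple-testing correction (by
  design, mirroring its exploratory role).
- Whether published per-PRS-unit odds ratios are per raw score unit or
  per SD is ambiguous in the source material; this package standardizes
  and reports per SD, so absolute coefficient magnitudes are not
  comparable to reports using raw-unit scores.
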