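# Methods

This note records the modelling choices behind `grspipe`: what each stage
computes, which parameters matter, how the synthetic cohorts are
calibrated, and what the tests do and do not demonstrate about real data.

## Scores and weights

The unweighted score is the risk-allele count over the panel; the weighted
score multiplies each dosage by `wβ_i = ln(OR_i)`, the log pooled per-allele
odds ratio. The weight definition deserves a remark: published descriptions
of weighted scores sometimes leave the weighting function implicit. We use
log odds ratios — not raw odds ratios — because a sum of log odds ratios is
the natural additive scale for multiplicative risks, and because typical
reported weighted-score means for panels like this one (≈1.3–1.5 over ~15
carried risk alleles) are consistent with summed log-ORs and not with
summed ORs (which would exceed 15).

Pooling across studies uses DerSimonian–Laird: fixed-effect weights
`w_i = 1/se_i²`, heterogeneity `Q = Σw_i(θ_i − θ̄)²`,
`τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`, and random-effects weights
`1/(se_i² + τ²)`. With one study, or identical studies, pooling passes the
input through. An unweighted mean of ORs is available
(`pool_study_table(..., method="mean")`) because "average effect size" in
published panel tables is occasionally a plain mean; DerSimonian–Laird is
the default. Published ORs with 95% CIs convert to log-scale SEs as
`(ln hi − ln lo)/(2·1.959964)`.

Scores are only defined for complete cases: individuals missing any
genotype or phenotype field are excluded up front rather than rescaled
(no `M/observed` correction), matching the study design the pipeline
models. The weighted score is additionally run through the two-step
transform before regression (below); distribution summaries use the raw
score.

## QC statistics

- **Hardy–Weinberg**: 1-df χ² of observed genotype counts against
  `(np̂², 2np̂q̂, nq̂²)` at the sample allele frequency, no continuity
  correction, missing genotypes excluded per SNP. Monomorphic sites are
  flagged rather than tested.
- **Between-population frequency comparison**: a 2×2 allele-count table
  (2 alleles per genotype) tested with the same 1-df χ²; Fisher's exact
  test is available behind a flag. Allele counts rather than genotype
  counts keep the test consistent with reporting frequencies as allele
  percentages.
- **Pairwise LD**: two-locus haplotype frequencies by EM over the
  double-heterozygote phase ambiguity; `D = p_AB − p_A p_B`, `D′ = |D|/Dmax`
  with the standard frequency bound for the sign of D, `r² = D²/(p_A q_A
  p_B q_B)`, and LOD as the log10 likelihood ratio of the EM solution
  against linkage equilibrium. Convergence: max haplotype-frequency change
  < 1e-10 or 1000 iterations. The linkage-equilibrium starting point is a
  stationary point of the EM map whenever the data are dominated by double
  heterozygotes (a saddle), so the estimator adds two symmetric cis- and
  trans-leaning restarts and keeps the best-likelihood solution; the test
  suite verifies the result attains the global (grid-scanned) maximum
  likelihood on every polymorphic dataset with n ≤ 6.

## Association layer

Glycemic classification from fasting glucose (mmol/L): diabetes at
FG ≥ 7.0 or antidiabetic treatment; prediabetes at 5.6 ≤ FG < 7.0
untreated. The lower boundary is inclusive, following the consensus
metabolic-syndrome definition; a strict `> 5.6` variant is available via a
flag. The binary outcome pools prediabetes and diabetes.

Skewed covariates (age, BMI, HDL-C, TG, and the weighted score) pass
through a two-step transform when the Shapiro–Wilk test rejects normality
at α = 0.05: fractional ranks `(rank − 0.5)/n` with ties sharing mean
ranks, then standard-normal quantiles rescaled to the original sample mean
and SD. The transform is strictly rank-preserving and leaves the first two
moments unchanged to 1e-9. Fasting glucose as the outcome stays on its
measurement scale.

Models are ordinary least squares (FG) and maximum-likelihood logistic
regression (dysglycemia), with Wald 95% intervals and p-values; logistic
output is exponentiated to the odds-ratio scale. Sex is coded female = 1
(male reference); ethnicity Roma = 1 (General reference). The full grid is
{GRS, wGRS} × {FG, status} × {each population separately, combined with
ethnicity} = 12 models. Group comparisons of score distributions use the
pooled-variance (Student's) t-test. Rank-deficient designs and separated
logistic fits raise errors naming the problem rather than returning
unstable estimates.

## Power

Power is defined for the two-sided 1-df Wald test of the per-allele effect
in a single-SNP logistic model on a cross-sectional binary outcome. The
analytic route solves the model intercept so the marginal prevalence equals
the configured case fraction, derives the expected case/control allele
frequencies under HWE, and uses the standard log-odds-ratio variance from
expected allele counts as the non-centrality denominator; an
expected-Fisher-information variant is provided and agrees closely. The
Monte-Carlo route simulates complete datasets and fits the logistic model
(vectorised Newton iterations), returning the rejection fraction with a
shrunk-proportion binomial SE so the SE stays positive at 0 or 100%
rejections. The suite checks the two routes agree within two simulation
SEs over an (OR, frequency, n) grid and that the null calibrates to α.

Published per-SNP power figures for panels like this one depend on
reference-population allele frequencies and software settings that are
rarely printed; the module therefore defines power for its own explicit
test and makes no attempt to match externally printed power columns.

## Synthetic cohorts

The generator draws, per population: genotypes independently per SNP under
HWE at configured effect-allele frequencies (no LD — an optional two-SNP LD
block exists solely to exercise the LD estimator); sex as Bernoulli; age
and BMI as truncated normals; HDL-C and TG as log-normals matched to the
configured mean/SD; and fasting glucose as

```
FG = intercept + Σ β_i·G_i + b_f·female + b_a·age + b_b·BMI + b_h·HDL
     + b_t·TG + ethnicity_shift + N(0, σ)
```

with the binary outcome then derived through the glycemic thresholds, so a
single generative model feeds both the continuous and binary analyses.
Treatment is flagged with probability 0.3 among individuals with FG ≥ 7.
Genotype and phenotype missingness are injected completely at random.

Per-allele FG effects default to `β_i = c·ln(OR_i)` with a single scale
`c = 0.52`, calibrated once (at large n) so the implied per-allele
dysglycemia odds ratio of the strongest panel SNP matches its pooled value
(≈1.40); `c` is recorded in the presets. The shared intercept (2.051) sets
the General-like mean FG to 4.82 mmol/L given the covariate model
`(b_f, b_a, b_b, b_h, b_t) = (−0.26, 0.032, 0.042, −0.387, 0.061)` and
residual SD 0.75. Missingness rates (0.008/0.02325 General-like,
0.004/0.01684 Roma-like per genotype cell / numeric phenotype field) are
calibrated so the complete-case filter keeps ≈1394 of 1783 and ≈1008 of
1170 enrolled individuals.

Two calibration tensions are worth recording. First, real fasting glucose
is strongly right-skewed by the diabetic tail; a Gaussian residual cannot
reproduce both the published FG standard deviations (≈1.7–1.9 mmol/L) and
the published elevated-FG prevalences at the same time. We chose a residual
SD that keeps the General-like prevalence realistic (~19%) and accept that
the simulated FG SD is smaller than the published one. Second, both presets
share one intercept so that the combined-population regression recovers the
configured `ethnicity_shift` (0.918 mmol/L — the adjusted, not the raw,
between-population contrast) as its ethnicity coefficient; under Gaussian
residuals this pushes the simulated Roma-like elevated-FG prevalence above
the published raw figure. Passing tests therefore demonstrate estimator
correctness against generator truth, not distributional realism of the FG
tail.

For recovery testing the generator has two auxiliary modes: uniform
per-allele effects (`genetic_effects: uniform`), which make the unweighted
score the correctly specified predictor with a known coefficient, and a
direct logistic `status_model`, which draws the binary outcome from a
logistic model in the weighted score and covariates (encoding case status
through the FG thresholds so the standard classification recovers it
exactly). These give the linear and logistic estimators well-defined truths
for coverage checks; the threshold mechanism remains the default, and FG
values produced in `status_model` mode are placeholders, not analysable
outcomes.

## Problem sizes and numerical choices

The acceptance-level checks run at the study's own scale: contingency-table
reconstructions at n = 1394/1008; single-SNP odds-ratio recovery at
n = 200,000; confidence-interval coverage over 200 replicates of the full
chain (1783 + 1170 enrolled per replicate); EM-vs-brute-force on all ~4700
polymorphic two-locus datasets with n ≤ 6; Monte-Carlo power with 800
replicates per grid cell. Statistical assertions use pre-specified bands
(typically 3 standard errors, coverage ≥ 90% for nominal 95% intervals).

Ties in the transform take mean ranks; EM tolerance is 1e-10; the logistic
fitter flags |coefficient| > 30 as separation; dosage validation accepts
only {0, 1, 2, missing}; strand-ambiguous VCF sites (A/T, C/G) are rejected
rather than oriented by guesswork.

## Known limitations

- No imputation, no liftover, no PLINK binary formats; dosage tables and
  VCF 4.x only.
- No haplotype-block detection or multi-locus phasing; LD is pairwise.
- The generator does not model drift, admixture, founder effects or
  consanguinity; population structure enters only through allele
  frequencies and the ethnicity shift.
- No gene–gene or gene–environment interactions, and no multiple-testing
  correction across the model grid (none is applied in the study design the
  pipeline models).
- Published cohort-level score means and per-SNP test p-values are not
  exactly reconstructible from published frequency tables alone (per-SNP
  denominators are unknown); validation is against generator truth instead.
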