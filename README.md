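# grspipe

A genetic risk score (GRS) pipeline for SNP-panel studies that compare the
inherited susceptibility of two populations — built around the classic
epidemiological question of whether a higher disease burden in a minority
population (here: dysglycemia and type 2 diabetes in the Roma population of
Hungary, compared with the general Hungarian population) is carried by known
risk alleles or by environment and lifestyle.

The package is aimed at genetic epidemiologists who have a small panel of
well-replicated susceptibility SNPs with published per-allele odds ratios
and genotype + phenotype tables for two study groups, and who want the whole
analysis — QC, scoring, adjusted association models, power — in one tested,
scriptable toolchain. A bundled synthetic-cohort generator reproduces the
statistical structure of the study populations so every stage can be
exercised and validated without access to individual-level data.

## The model

For individual *j* with effect-allele dosages `G_ij ∈ {0,1,2}` over a panel
of *I* SNPs:

- **Unweighted score** — `GRS_j = Σ_i G_ij`, the risk-allele count.
- **Weighted score** — `wGRS_j = Σ_i wβ_i · G_ij` with `wβ_i = ln(OR_i)`,
  the log of SNP *i*'s pooled per-allele odds ratio. Pooling across
  published studies uses DerSimonian–Laird random-effects meta-analysis
  (`τ² = max(0, (Q − (k−1)) / (S₁ − S₂/S₁))`).

Around the scores, the pipeline provides:

- per-SNP QC: effect-allele frequencies, Hardy–Weinberg χ² (1 df), a
  between-population allele-count χ² test, and pairwise LD (D′, r², LOD)
  with haplotype frequencies estimated by EM over the double-heterozygote
  phase ambiguity;
- glycemic classification from fasting glucose (FG): prediabetes at
  5.6–6.9 mmol/L, diabetes at FG ≥ 7.0 mmol/L or treatment, and the pooled
  binary "dysglycemia" outcome;
- adjusted association models — OLS for FG, maximum-likelihood logistic
  regression for dysglycemia — with covariates sex, age, BMI, HDL-C and TG,
  skewed covariates passed through a Shapiro–Wilk-gated two-step
  rank-based inverse-normal transform, fitted per population and combined
  with an ethnicity covariate (12-model grid);
- per-SNP power for the 1-df Wald test of the log-additive allele effect,
  analytically and by Monte-Carlo simulation.

The bundled panel is the 16-SNP type 2 diabetes susceptibility set
(TCF7L2 rs7903146, CDKN2A/B rs10811661, CDKAL1 rs10946398, …) with pooled
odds ratios between 1.03 and 1.40.

## Worked example

Run the whole workflow on the two bundled population presets:

```sh
grspipe all --config run.yaml --seed 1
```

with `run.yaml`:

```yaml
general: {preset: general_like}
roma: {preset: roma_like}
output_dir: demo
```

The run simulates 1783 + 1170 individuals, applies the complete-case filter
(keeping 1358 + 1018 at this seed), and writes QC, weight, score,
association and power tables plus `report.md` and `manifest.json`. The
score summary:

```
population score    n      mean       sd      min       max
   General   grs 1358 16.774669 2.498496 8.000000 24.000000
   General  wgrs 1358  1.464748 0.315150 0.632119  2.478500
      Roma   grs 1018 16.727898 2.445397 9.000000 25.000000
      Roma  wgrs 1018  1.436200 0.305907 0.554968  2.508469
```

Mean GRS is close to its theoretical value `2·Σp_i` for each frequency set,
and the General population carries slightly more risk alleles than the Roma
population, mirroring the configured allele frequencies. The key rows of
the combined-population models (`demo/associations.tsv`):

```
        outcome score term  estimate   ci_low  ci_high             p
fasting_glucose   grs  grs  0.047645 0.035182 0.060107  9.180858e-14
fasting_glucose   grs roma  0.884958 0.821120 0.948796 7.356562e-142
    t2dm_status  wgrs wgrs  2.648464 1.901984 3.687918  8.125509e-09
```

Each extra risk allele raises FG by ~0.048 mmol/L after adjustment; the
ethnicity coefficient (0.885, truth 0.918 in the generator) captures the
simulated environmental FG shift; and a unit of wGRS multiplies the odds of
dysglycemia by ~2.6. Per-stage subcommands (`simulate`, `qc`, `weights`,
`score`, `associate`, `power`) expose the same steps on files.

## Layout

```
src/grspipe/
  panel.py             SNP panel definition + bundled 16-SNP panel
  cohort_io.py         VCF/dosage-table/phenotype readers, complete-case filter
  qc_popgen.py         allele frequencies, HWE, frequency comparison, EM-LD
  effect_weights.py    OR→log-OR conversion, DerSimonian–Laird pooling, weights
  risk_scores.py       GRS / wGRS scoring and summaries
  association.py       glycemic classification, transform, t-test, model grid
  power_calc.py        analytic + Monte-Carlo per-SNP power
  synthetic_cohort.py  two-population generator with bundled presets
  pipeline.py, cli.py  orchestration, report, manifest, CLI
docs/methods.md        modelling assumptions, calibration and limitations
```
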