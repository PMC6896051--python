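# Hungarian-general-like population preset for the bundled 16-SNP panel.
# Effect-allele frequencies and covariate distributions follow the study's
# published cohort characteristics; the fasting-glucose model intercept and
# the per-allele scale (beta_scale) are calibrated so the simulated cohort
# reproduces the published mean fasting glucose (4.82 mmol/L) and an
# rs7903146 dysglycemia odds ratio near its pooled value (1.40).
# Missingness rates are calibrated so ~1394 of 1783 enrolled individuals
# survive the complete-case filter.
label: General
n: 1783
frequencies:
  rs7903146: 0.2945
  rs10811661: 0.8278
  rs10946398: 0.3136
  rs1111875: 0.5882
  rs5219: 0.3558
  rs11671664: 0.1141
  rs780094: 0.7364
  rs1387153: 0.2938
  rs340874: 0.4760
  rs10830963: 0.2905
  rs2191349: 0.5793
  rs174550: 0.7037
  rs10885122: 0.8867
  rs11071657: 0.6406
  rs7034200: 0.4462
  rs560887: 0.8693
female_prop: 0.5287
age: {mean: 44.17, sd: 12.10, min: 20.0}
bmi: {mean: 27.43, sd: 5.39, min: 13.0}
hdl: {mean: 1.42, sd: 0.46}
tg: {mean: 1.64, sd: 1.68}
fg_intercept: 2.051
genetic_effects: log_or
beta_scale: 0.52
coefficients: {female: -0.26, age: 0.032, bmi: 0.042, hdl: -0.387, tg: 0.061}
ethnicity_shift: 0.0
residual_sd: 0.75
treatment_prob_high_fg: 0.3
missing_genotype_rate: 0.008
missing_phenotype_rate: 0.02325
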