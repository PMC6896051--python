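"""Two-population synthetic cohort generator.

Emulates the statistical structure the analysis assumes: per-SNP genotypes
drawn independently under Hardy-Weinberg equilibrium at configured
effect-allele frequencies (no LD by default), covariates from normal or
log-normal distributions, and fasting glucose from a linear model with a
per-allele genetic term, covariate terms, an ethnicity shift and Gaussian
noise. Dysglycemia status then follows from the fasting-glucose thresholds,
so one generative model feeds both the continuous and the binary analyses.

A separate ``status_model`` mode draws the binary outcome directly from a
logistic model in the weighted score and covariates; it exists to give the
binary-outcome estimators a correctly specified truth for recovery testing
and is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort_io import Cohort, GenotypeMatrix
from .panel import SnpPanel, load_default_panel

PRESETS = ("general_like", "roma_like")


@dataclass(frozen=True)
class NormalSpec:
    mean: float
    sd: float
    min: Optional[float] = None


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to draw one population, reproducibly."""

    label: str
    n: int
    frequencies: dict[str, float]
    female_prop: float
    age: NormalSpec
    bmi: NormalSpec
    hdl: NormalSpec  # log-normal, parameterised by mean/sd on the raw scale
    tg: NormalSpec   # log-normal
    fg_intercept: float
    genetic_effects: str = "log_or"  # per-allele beta_i = beta_scale * ln(OR_i)
    beta_scale: float = 0.0
    uniform_beta: float = 0.0        # used when genetic_effects == "uniform"
    coefficients: dict[str, float] = field(
        default_factory=lambda: {"female": 0.0, "age": 0.0, "bmi": 0.0,
                                 "hdl": 0.0, "tg": 0.0}
    )
    ethnicity_shift: float = 0.0
    residual_sd: float = 1.0
    treatment_prob_high_fg: float = 0.3
    missing_genotype_rate: float = 0.0
    missing_phenotype_rate: float = 0.0
    status_model: Optional[dict[str, float]] = None
    ld_block: Optional[dict] = None  # {"rsid_i","rsid_j","dprime"} test hook

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        for rsid, p in self.frequencies.items():
            if not 0 < p < 1:
                raise ValueError(f"{rsid}: frequency must be in (0,1), got {p}")
        if not self.residual_sd > 0:
            raise ValueError("residual_sd must be positive")
        if not 0 <= self.female_prop <= 1:
            raise ValueError("female_prop must be in [0,1]")
        for rate in (self.missing_genotype_rate, self.missing_phenotype_rate):
            if not 0 <= rate < 1:
                raise ValueError("missingness rates must be in [0,1)")
        if self.genetic_effects not in ("log_or", "uniform"):
            raise ValueError("genetic_effects must be 'log_or' or 'uniform'")

    def per_allele_betas(self, panel: SnpPanel) -> np.ndarray:
        if self.genetic_effects == "uniform":
            return np.full(len(panel), self.uniform_beta)
        return self.beta_scale * np.log(panel.pooled_ors)

    @classmethod
    def from_dict(cls, raw: dict) -> "GeneratorConfig":
        raw = dict(raw)
        for key in ("age", "bmi", "hdl", "tg"):
            raw[key] = NormalSpec(**raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_preset(name: str) -> GeneratorConfig:
    """Load a bundled population preset (``general_like`` or ``roma_like``)."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {PRESETS}")
    ref = resources.files("grspipe.data").joinpath(f"presets/{name}.yaml")
    with ref.open() as fh:
        return GeneratorConfig.from_dict(yaml.safe_load(fh))


def _truncated_normal(spec: NormalSpec, size: int, rng) -> np.ndarray:
    if spec.min is None:
        return rng.normal(spec.mean, spec.sd, size)
    a = (spec.min - spec.mean) / spec.sd
    return stats.truncnorm.rvs(a, np.inf, loc=spec.mean, scale=spec.sd,
                               size=size, random_state=rng)


def _lognormal(spec: NormalSpec, size: int, rng) -> np.ndarray:
    sigma2 = np.log1p(spec.sd**2 / spec.mean**2)
    mu = np.log(spec.mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _draw_ld_pair(pA: float, pB: float, dprime: float, n: int, rng) -> tuple:
    """Draw two loci jointly with the requested |D'| (positive D)."""
    dmax = min(pA * (1 - pB), (1 - pA) * pB)
    d = dprime * dmax
    haps = np.array(
        [pA * pB + d, pA * (1 - pB) - d, (1 - pA) * pB - d,
         (1 - pA) * (1 - pB) + d]
    )
    draws = rng.choice(4, size=(n, 2), p=haps)
    gi = np.isin(draws, (0, 1)).sum(axis=1)  # haplotypes carrying allele A
    gj = np.isin(draws, (0, 2)).sum(axis=1)  # haplotypes carrying allele B
    return gi.astype(float), gj.astype(float)


def generate_cohort(
    config: GeneratorConfig,
    panel: Optional[SnpPanel] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Cohort:
    """Draw one population; fully reproducible from the seed."""
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or an explicit Generator) is mandatory")
        rng = np.random.default_rng(seed)
    panel = panel or load_default_panel()
    missing_freq = [r for r in panel.rsids if r not in config.frequencies]
    if missing_freq:
        raise ValueError(f"no frequency configured for: {missing_freq}")
    n = config.n
    freqs = np.array([config.frequencies[r] for r in panel.rsids])
    dosages = rng.binomial(2, freqs, size=(n, len(panel))).astype(float)
    if config.ld_block is not None:
        i = panel.index_of(config.ld_block["rsid_i"])
        j = panel.index_of(config.ld_block["rsid_j"])
        dosages[:, i], dosages[:, j] = _draw_ld_pair(
            freqs[i], freqs[j], float(config.ld_block["dprime"]), n, rng
        )

    female = (rng.random(n) < config.female_prop).astype(int)
    age = _truncated_normal(config.age, n, rng)
    bmi = _truncated_normal(config.bmi, n, rng)
    hdl = _lognormal(config.hdl, n, rng)
    tg = _lognormal(config.tg, n, rng)

    betas = config.per_allele_betas(panel)
    coefs = config.coefficients
    linpred = (
        config.fg_intercept
        + dosages @ betas
        + coefs.get("female", 0.0) * female
        + coefs.get("age", 0.0) * age
        + coefs.get("bmi", 0.0) * bmi
        + coefs.get("hdl", 0.0) * hdl
        + coefs.get("tg", 0.0) * tg
        + config.ethnicity_shift
    )
    fg = linpred + rng.normal(0, config.residual_sd, n)
    fg = np.maximum(fg, 0.1)  # physiological floor; crossings are ~1e-4 rare

    if config.status_model is None:
        on_treatment = (fg >= 7.0) & (rng.random(n) < config.treatment_prob_high_fg)
    else:
        # direct logistic outcome: status encoded exactly through the
        # fasting-glucose thresholds so the standard classification
        # recovers it (cases sit in the elevated range, controls below)
        sm_ = config.status_model
        weights = np.log(panel.pooled_ors)
        wgrs = dosages @ weights
        eta = (
            sm_.get("intercept", 0.0)
            + sm_.get("wgrs", 0.0) * wgrs
            + sm_.get("female", 0.0) * female
            + sm_.get("age", 0.0) * age
            + sm_.get("bmi", 0.0) * bmi
            + sm_.get("hdl", 0.0) * hdl
            + sm_.get("tg", 0.0) * tg
        )
        status = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
        fg = np.where(status, rng.uniform(5.7, 9.0, n), rng.uniform(3.8, 5.5, n))
        on_treatment = np.zeros(n, dtype=bool)

    if config.missing_genotype_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_genotype_rate
        dosages[mask] = np.nan

    pheno = pd.DataFrame(
        {
            "sample_id": [f"{config.label}_{i:05d}" for i in range(n)],
            "sex": np.where(female == 1, "female", "male"),
            "age": age,
            "bmi": bmi,
            "hdl": hdl,
            "tg": tg,
            "fasting_glucose": fg,
            "on_treatment": on_treatment,
            "population": config.label,
        }
    )
    if config.missing_phenotype_rate > 0:
        for col in ("age", "bmi", "hdl", "tg", "fasting_glucose"):
            mask = rng.random(n) < config.missing_phenotype_rate
            pheno.loc[mask, col] = np.nan

    gm = GenotypeMatrix(
        dosages=dosages, sample_ids=pheno["sample_id"].tolist(), panel=panel
    )
    return Cohort(genotypes=gm, phenotypes=pheno, label=config.label)


def generate_two_populations(
    config_general: GeneratorConfig,
    config_roma: GeneratorConfig,
    seed: int,
    panel: Optional[SnpPanel] = None,
) -> tuple[Cohort, Cohort]:
    """Two independent cohorts on a shared panel, deterministic given seed."""
    if config_general.label == config_roma.label:
        raise ValueError("populations must have distinct labels")
    panel = panel or load_default_panel()
    ss = np.random.SeedSequence(seed)
    child_a, child_b = ss.spawn(2)
    cohort_a = generate_cohort(config_general, panel, rng=np.random.default_rng(child_a))
    cohort_b = generate_cohort(config_roma, panel, rng=np.random.default_rng(child_b))
    return cohort_a, cohort_b
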