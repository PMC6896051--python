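"""Glycemic classification, normality handling, and association models.

Implements the study's statistical layer: fasting-glucose based glycemic
status (normal / prediabetes / T2DM), the two-step rank-based inverse-normal
transform for skewed covariates with a Shapiro-Wilk gate, the pooled-variance
t-test for score comparisons, and adjusted linear (fasting glucose) and
logistic (dysglycemia status) regression models, separately per population
and combined with an ethnicity covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort_io import Cohort
from .risk_scores import ScoreTable

#: fasting-glucose thresholds, mmol/L
PREDM_LOWER = 5.6
T2DM_LOWER = 7.0

#: covariates screened by the normality gate before model fitting
GATED_VARIABLES = ("age", "hdl", "bmi", "tg", "wgrs")


@dataclass(frozen=True)
class GlycemicStatus:
    category: Literal["normal", "prediabetes", "t2dm"]
    binary_outcome: bool


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the association grid."""

    outcome: Literal["fasting_glucose", "t2dm_status"]
    score: Literal["grs", "wgrs"]
    include_ethnicity: bool = False
    covariates: tuple[str, ...] = ("female", "age", "bmi", "hdl", "tg")
    transform: bool = True  # gate skewed covariates through the two-step transform
    alpha: float = 0.05

    @property
    def predictors(self) -> list[str]:
        cols = [self.score, *self.covariates]
        if self.include_ethnicity:
            cols.append("roma")
        return cols


@dataclass(frozen=True)
class AssociationResult:
    """Coefficient table for one fitted model.

    ``table`` columns: term, estimate, ci_low, ci_high, p. For logistic
    models the estimate and CI are exponentiated (odds-ratio scale).
    """

    spec: ModelSpec
    cohort: str
    n: int
    table: pd.DataFrame
    family: Literal["linear", "logistic"]
    meta: dict = field(default_factory=dict)

    def coefficient(self, term: str) -> pd.Series:
        rows = self.table[self.table["term"] == term]
        if rows.empty:
            raise KeyError(f"term {term!r} not in model")
        return rows.iloc[0]


def classify_glycemic_status(fg: float, on_treatment: bool,
                             inclusive_lower: bool = True) -> GlycemicStatus:
    """Classify one individual from fasting glucose (mmol/L) and treatment.

    T2DM: FG >= 7.0 mmol/L or on antidiabetic treatment. Prediabetes:
    FG in [5.6, 7.0) untreated (set ``inclusive_lower=False`` for a strict
    > 5.6 boundary). The study's binary outcome pools prediabetes and T2DM.
    """
    if not fg > 0:
        raise ValueError(f"fasting glucose must be positive, got {fg}")
    if on_treatment or fg >= T2DM_LOWER:
        category = "t2dm"
    elif fg >= PREDM_LOWER if inclusive_lower else fg > PREDM_LOWER:
        category = "prediabetes"
    else:
        category = "normal"
    return GlycemicStatus(category=category, binary_outcome=category != "normal")


def two_step_transform(values) -> np.ndarray:
    """Two-step rank-based normalisation.

    Step 1: fractional ranks (rank - 0.5)/n with ties sharing mean ranks.
    Step 2: standard-normal quantiles of those ranks, rescaled back to the
    input's sample mean and SD. Strictly rank-preserving up to ties.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D vector with n >= 3")
    if not np.isfinite(x).all():
        raise ValueError("missing values not allowed")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("no variance: cannot transform a constant vector")
    pr = (stats.rankdata(x, method="average") - 0.5) / x.size
    z = stats.norm.ppf(pr)
    return z / z.std(ddof=1) * sd + x.mean()


def shapiro_wilk_gate(values, alpha: float = 0.05) -> bool:
    """True when the Shapiro-Wilk test rejects normality at ``alpha``
    (i.e. the variable should be transformed before modelling)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if x.std(ddof=1) == 0:
        raise ValueError("constant vector")
    return bool(stats.shapiro(x).pvalue < alpha)


def two_sample_t(a, b) -> dict:
    """Two-sided Student's (pooled-variance) t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(res.statistic):
        raise ValueError("zero pooled variance")
    return {
        "t": float(res.statistic),
        "df": float(a.size + b.size - 2),
        "p": float(res.pvalue),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sd_a": float(a.std(ddof=1)),
        "sd_b": float(b.std(ddof=1)),
    }


def build_model_frame(
    cohorts: Sequence[Cohort],
    scores: ScoreTable,
    reference_population: str = "General",
) -> pd.DataFrame:
    """Assemble the analysis table: outcomes, scores and coded covariates.

    Sex is coded female = 1 (male reference); ethnicity roma = 1 with the
    reference population at 0. The binary outcome is dysglycemia
    (prediabetes or T2DM).
    """
    pieces = []
    for cohort in cohorts:
        ph = cohort.phenotypes
        status = [
            classify_glycemic_status(fg, bool(tr)).binary_outcome
            for fg, tr in zip(ph["fasting_glucose"], ph["on_treatment"])
        ]
        pieces.append(
            pd.DataFrame(
                {
                    "sample_id": ph["sample_id"],
                    "population": cohort.label,
                    "fasting_glucose": ph["fasting_glucose"].to_numpy(float),
                    "t2dm_status": np.asarray(status, dtype=int),
                    "female": (ph["sex"] == "female").astype(int).to_numpy(),
                    "age": ph["age"].to_numpy(float),
                    "bmi": ph["bmi"].to_numpy(float),
                    "hdl": ph["hdl"].to_numpy(float),
                    "tg": ph["tg"].to_numpy(float),
                }
            )
        )
    frame = pd.concat(pieces, ignore_index=True)
    frame = frame.merge(
        scores.scores[["sample_id", "population", "grs", "wgrs"]],
        on=["sample_id", "population"],
        how="left",
        validate="one_to_one",
    )
    if frame[["grs", "wgrs"]].isna().any().any():
        raise ValueError("some cohort samples are missing scores")
    frame["roma"] = (frame["population"] != reference_population).astype(int)
    return frame


def _apply_normality_gate(frame: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    out = frame.copy()
    for col in GATED_VARIABLES:
        if col in spec.predictors and shapiro_wilk_gate(out[col], spec.alpha):
            out[col] = two_step_transform(out[col].to_numpy())
    return out


def _design(frame: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    X = frame[spec.predictors].astype(float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()]))
    if rank < X.shape[1] + 1:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; near-collinear columns: {worst}")
    return sm.add_constant(X)


def fit_linear(spec: ModelSpec, data: pd.DataFrame, cohort: str = "") -> AssociationResult:
    """OLS of fasting glucose on a score plus covariates (Wald inference)."""
    if spec.outcome != "fasting_glucose":
        raise ValueError("fit_linear requires the continuous outcome")
    frame = _apply_normality_gate(data, spec) if spec.transform else data
    X = _design(frame, spec)
    if len(frame) <= X.shape[1]:
        raise ValueError("more predictors than observations")
    fit = sm.OLS(frame[spec.outcome].astype(float), X).fit()
    ci = fit.conf_int()
    table = pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    return AssociationResult(
        spec=spec, cohort=cohort, n=len(frame), table=table, family="linear",
        meta={"r2": float(fit.rsquared)},
    )


def fit_logistic(spec: ModelSpec, data: pd.DataFrame, cohort: str = "") -> AssociationResult:
    """ML logistic regression of dysglycemia status; odds-ratio scale output."""
    if spec.outcome != "t2dm_status":
        raise ValueError("fit_logistic requires the binary outcome")
    frame = _apply_normality_gate(data, spec) if spec.transform else data
    y = frame[spec.outcome].astype(int)
    if y.nunique() < 2:
        raise ValueError("outcome has a single class")
    X = _design(frame, spec)
    fit = sm.Logit(y, X).fit(disp=0)
    if not np.isfinite(fit.bse).all() or np.abs(fit.params).max() > 30:
        raise ValueError("separation detected: coefficients diverged")
    ci = fit.conf_int()
    table = pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": np.exp(fit.params.to_numpy()),
            "ci_low": np.exp(ci[0].to_numpy()),
            "ci_high": np.exp(ci[1].to_numpy()),
            "p": fit.pvalues.to_numpy(),
        }
    )
    return AssociationResult(
        spec=spec, cohort=cohort, n=len(frame), table=table, family="logistic",
        meta={"llf": float(fit.llf)},
    )


def run_association_suite(
    general: Cohort,
    roma: Cohort,
    scores: ScoreTable,
    reference_population: Optional[str] = None,
    transform: bool = True,
) -> list[AssociationResult]:
    """The full 12-model grid: {GRS, wGRS} x {FG, status} x {each population,
    combined with ethnicity}."""
    ref = reference_population or general.label
    frames = {
        general.label: build_model_frame([general], scores, ref),
        roma.label: build_model_frame([roma], scores, ref),
        "combined": build_model_frame([general, roma], scores, ref),
    }
    results = []
    for score in ("grs", "wgrs"):
        for outcome, fitter in (
            ("fasting_glucose", fit_linear),
            ("t2dm_status", fit_logistic),
        ):
            for name, frame in frames.items():
                spec = ModelSpec(
                    outcome=outcome,
                    score=score,
                    include_ethnicity=(name == "combined"),
                    transform=transform,
                )
                results.append(fitter(spec, frame, cohort=name))
    return results


def association_grid_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Tidy long-format table over all fitted models."""
    rows = []
    for res in results:
        for row in res.table.itertuples(index=False):
            rows.append(
                {
                    "cohort": res.cohort,
                    "outcome": res.spec.outcome,
                    "score": res.spec.score,
                    "family": res.family,
                    "n": res.n,
                    "term": row.term,
                    "estimate": row.estimate,
                    "ci_low": row.ci_low,
                    "ci_high": row.ci_high,
                    "p": row.p,
                }
            )
    return pd.DataFrame(rows)
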