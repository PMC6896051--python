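"""Pooling published per-SNP effect estimates and deriving wGRS weights.

Per-study odds ratios are pooled on the log scale with the
DerSimonian-Laird random-effects estimator; the weighted-score weight of a
SNP is the natural log of its pooled odds ratio. An unweighted mean of the
published ORs is available as an alternative pooling rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import SnpPanel, StudyEffect

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class PooledEffect:
    rsid: str
    pooled_ln_or: float
    pooled_se: float
    tau2: float
    q: float
    k: int

    @property
    def pooled_or(self) -> float:
        return math.exp(self.pooled_ln_or)


@dataclass(frozen=True)
class WeightSet:
    """Per-SNP wGRS weights, ordered as the panel."""

    panel: SnpPanel
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.panel),):
            raise ValueError("one weight per panel SNP required")
        if not np.isfinite(w).all():
            raise ValueError("weights must be finite")
        object.__setattr__(self, "weights", w)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.panel.rsids,
                "pooled_or": np.exp(self.weights),
                "weight": self.weights,
            }
        )


def lnor_from_ci(or_value: float, ci_low: float, ci_high: float) -> StudyEffect:
    """Convert a published OR with 95% CI to a log-odds estimate and SE.

    se = (ln hi - ln lo) / (2 * 1.959964); a degenerate CI (zero width) is
    rejected because it carries no usable precision.
    """
    if not (0 < ci_low <= or_value <= ci_high):
        raise ValueError(
            f"need 0 < ci_low <= OR <= ci_high, got ({or_value}, {ci_low}, {ci_high})"
        )
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * Z_95)
    if se <= 0:
        raise ValueError("confidence interval has zero width")
    return StudyEffect(ln_or=math.log(or_value), se=se)


def dersimonian_laird(studies: Sequence[StudyEffect], rsid: str = "") -> PooledEffect:
    """DerSimonian-Laird random-effects pooling of log odds ratios.

    Moment estimator: tau2 = max(0, (Q - (k-1)) / (S1 - S2/S1)) with
    fixed-effect weights w_i = 1/se_i^2; the pooled estimate then uses
    weights 1/(se_i^2 + tau2).
    """
    if len(studies) == 0:
        raise ValueError("at least one study required")
    theta = np.array([s.ln_or for s in studies])
    se = np.array([s.se for s in studies])
    w = 1.0 / se**2
    theta_fe = float((w * theta).sum() / w.sum())
    q = float((w * (theta - theta_fe) ** 2).sum())
    k = len(studies)
    if k == 1:
        tau2 = 0.0
    else:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / denom)
    w_re = 1.0 / (se**2 + tau2)
    pooled = float((w_re * theta).sum() / w_re.sum())
    pooled_se = float(math.sqrt(1.0 / w_re.sum()))
    return PooledEffect(rsid, pooled, pooled_se, tau2, q, k)


def mean_or_pooling(studies: Sequence[StudyEffect], rsid: str = "") -> PooledEffect:
    """Unweighted arithmetic mean of the published ORs (alternative rule)."""
    if len(studies) == 0:
        raise ValueError("at least one study required")
    ors = np.exp([s.ln_or for s in studies])
    mean_or = float(np.mean(ors))
    return PooledEffect(rsid, math.log(mean_or), math.nan, math.nan,
                        math.nan, len(studies))


def pool_study_table(
    table: pd.DataFrame, method: str = "dersimonian-laird"
) -> list[PooledEffect]:
    """Pool a long-format study table (rsid + or/ci_low/ci_high or ln_or/se)."""
    pooler = {"dersimonian-laird": dersimonian_laird, "mean": mean_or_pooling}[method]
    or_col = "or" if "or" in table.columns else "or_value"
    out = []
    for rsid, grp in table.groupby("rsid", sort=False):
        if {"ln_or", "se"} <= set(grp.columns) and grp["ln_or"].notna().all():
            studies = [
                StudyEffect(lo, se) for lo, se in zip(grp["ln_or"], grp["se"])
            ]
        else:
            studies = [
                lnor_from_ci(o, lo, hi)
                for o, lo, hi in zip(grp[or_col], grp["ci_low"], grp["ci_high"])
            ]
        out.append(pooler(studies, rsid=str(rsid)))
    return out


def derive_weights(
    panel: SnpPanel, pooled: Sequence[PooledEffect] | None = None
) -> WeightSet:
    """wGRS weights: the natural log of each SNP's pooled odds ratio.

    With no pooled effects supplied, the panel's shipped pooled ORs are used
    directly; otherwise each panel SNP must have exactly one pooled effect.
    """
    if pooled is None:
        ors = np.array(panel.pooled_ors)
    else:
        by_rsid = {p.rsid: p for p in pooled}
        missing = [r for r in panel.rsids if r not in by_rsid]
        if missing:
            raise ValueError(f"no pooled effect for panel SNPs: {missing}")
        ors = np.exp([by_rsid[r].pooled_ln_or for r in panel.rsids])
    if (ors <= 0).any():
        raise ValueError("pooled ORs must be positive")
    return WeightSet(panel=panel, weights=np.log(ors))
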