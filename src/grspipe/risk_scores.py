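"""Unweighted and weighted genetic risk scores.

GRS sums the per-SNP risk-allele dosages (0/1/2) over the panel; wGRS sums
the same dosages weighted by the log pooled odds ratio of each SNP. Both are
defined only for complete cases — missing dosages are an error here, not a
value to impute around.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import Cohort
from .effect_weights import WeightSet


@dataclass(frozen=True)
class ScoreTable:
    """Per-individual scores plus cohort summaries."""

    scores: pd.DataFrame  # sample_id, grs, wgrs, population
    panel_size: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for pop, grp in self.scores.groupby("population", sort=False):
            for col in ("grs", "wgrs"):
                rows.append(
                    {
                        "population": pop,
                        "score": col,
                        "n": len(grp),
                        "mean": grp[col].mean(),
                        "sd": grp[col].std(ddof=1),
                        "min": grp[col].min(),
                        "max": grp[col].max(),
                    }
                )
        return pd.DataFrame(rows)

    def histogram(self) -> pd.DataFrame:
        """Integer-GRS counts per population (distribution-plot data)."""
        rows = []
        for pop, grp in self.scores.groupby("population", sort=False):
            counts = grp["grs"].astype(int).value_counts().sort_index()
            for value, count in counts.items():
                rows.append({"population": pop, "grs": value, "count": int(count)})
        return pd.DataFrame(rows)


def _check_complete(dosages: np.ndarray) -> np.ndarray:
    d = np.asarray(dosages, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError(
            "missing dosages: scores are defined for complete cases only "
            "(run complete_case_filter first)"
        )
    return d


def grs(dosages) -> int:
    """Unweighted count score: the number of risk alleles carried."""
    return int(_check_complete(dosages).sum())


def wgrs(dosages, weights: WeightSet) -> float:
    """Weighted score: risk-allele dosages weighted by ln(pooled OR)."""
    d = _check_complete(dosages)
    if d.shape != weights.weights.shape:
        raise ValueError(
            f"dosage length {d.shape} does not match weight length "
            f"{weights.weights.shape}"
        )
    return float(d @ weights.weights)


def score_cohort(cohort: Cohort, weights: WeightSet) -> ScoreTable:
    """Score every individual in a complete-case cohort."""
    if cohort.n_samples == 0:
        raise ValueError("empty cohort")
    d = _check_complete(cohort.genotypes.dosages)
    table = pd.DataFrame(
        {
            "sample_id": cohort.genotypes.sample_ids,
            "grs": d.sum(axis=1).astype(int),
            "wgrs": d @ weights.weights,
            "population": cohort.label,
        }
    )
    return ScoreTable(scores=table, panel_size=len(cohort.panel))


def score_cohorts(cohorts: list[Cohort], weights: WeightSet) -> ScoreTable:
    tables = [score_cohort(c, weights) for c in cohorts]
    return ScoreTable(
        scores=pd.concat([t.scores for t in tables], ignore_index=True),
        panel_size=tables[0].panel_size,
    )
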