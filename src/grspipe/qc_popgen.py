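"""Per-SNP and pairwise genotype QC.

Covers effect-allele frequencies, the Hardy-Weinberg chi-square test,
between-cohort allele-frequency comparison on 2x2 allele-count tables, and
pairwise linkage disequilibrium (D, D', r2, LOD) with two-locus haplotype
frequencies estimated by EM over the double-heterozygote phase ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Cohort

__all__ = [
    "HweResult",
    "FreqComparison",
    "LdResult",
    "allele_frequency",
    "hwe_chi_square",
    "compare_allele_frequencies",
    "ld_pairwise",
    "qc_report",
]


@dataclass(frozen=True)
class HweResult:
    rsid: str
    obs: tuple[int, int, int]  # (hom effect, het, hom other)
    chi2: float
    p: float
    monomorphic: bool = False


@dataclass(frozen=True)
class FreqComparison:
    rsid: str
    freq_a: float
    freq_b: float
    counts_2x2: np.ndarray  # rows: cohorts; cols: (effect, other) allele counts
    chi2: float
    p: float


@dataclass(frozen=True)
class LdResult:
    rsid_i: str
    rsid_j: str
    hap_freqs: tuple[float, float, float, float]  # (AB, Ab, aB, ab)
    D: float
    Dprime: float
    r2: float
    lod: float
    n: int
    degenerate: bool = False


def allele_frequency(dosages) -> float:
    """Effect-allele frequency from 0/1/2 dosages (missing excluded)."""
    d = np.asarray(dosages, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no non-missing dosages")
    return float(d.sum() / (2 * d.size))


def hwe_chi_square(counts, rsid: str = "") -> HweResult:
    """1-df chi-square test of Hardy-Weinberg proportions.

    ``counts`` = (n_AA, n_Aa, n_aa) with A the effect allele. Expected counts
    are taken at the sample allele frequency; no continuity correction.
    Monomorphic sites are flagged and returned with chi2 = 0, p = 1.
    """
    n_aa_hom, n_het, n_oo_hom = (int(c) for c in counts)
    if min(n_aa_hom, n_het, n_oo_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom + n_het + n_oo_hom
    if n == 0:
        raise ValueError("no genotypes")
    p = (2 * n_aa_hom + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return HweResult(rsid, (n_aa_hom, n_het, n_oo_hom), 0.0, 1.0, True)
    q = 1 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa_hom, n_het, n_oo_hom], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HweResult(
        rsid, (n_aa_hom, n_het, n_oo_hom), chi2, float(stats.chi2.sf(chi2, 1))
    )


def hwe_for_dosages(dosages, rsid: str = "") -> HweResult:
    d = np.asarray(dosages, dtype=float)
    d = d[np.isfinite(d)]
    counts = (int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum()))
    return hwe_chi_square(counts, rsid=rsid)


def compare_allele_counts(
    rsid: str,
    effect_a: int,
    total_a: int,
    effect_b: int,
    total_b: int,
    method: str = "chi2",
) -> FreqComparison:
    """Compare two cohorts' effect-allele counts (totals are allele counts, 2n)."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("each cohort needs at least one allele")
    table = np.array(
        [[effect_a, total_a - effect_a], [effect_b, total_b - effect_b]],
        dtype=float,
    )
    if method == "fisher":
        p = float(stats.fisher_exact(table)[1])
        chi2 = math.nan
    else:
        if table.sum(axis=0).min() == 0:
            chi2, p = 0.0, 1.0  # allele absent everywhere: no difference testable
        else:
            res = stats.chi2_contingency(table, correction=False)
            chi2, p = float(res.statistic), float(res.pvalue)
    return FreqComparison(
        rsid=rsid,
        freq_a=effect_a / total_a,
        freq_b=effect_b / total_b,
        counts_2x2=table,
        chi2=chi2,
        p=p,
    )


def compare_allele_frequencies(
    cohort_a: Cohort, cohort_b: Cohort, rsid: str, method: str = "chi2"
) -> FreqComparison:
    """Between-cohort allele-frequency test on the 2x2 allele-count table.

    Counts alleles (2 per non-missing genotype) rather than genotypes; the
    1-df chi-square is applied without continuity correction. Fisher's exact
    test is available via ``method="fisher"``.
    """
    out = []
    for cohort in (cohort_a, cohort_b):
        d = cohort.genotypes.column(rsid)
        d = d[np.isfinite(d)]
        if d.size == 0:
            raise ValueError(f"{cohort.label}: no genotypes for {rsid}")
        out.append((int(d.sum()), 2 * d.size))
    (ea, ta), (eb, tb) = out
    return compare_allele_counts(rsid, ea, ta, eb, tb, method=method)


# ---------------------------------------------------------------------------
# pairwise LD via EM haplotype-frequency estimation


def _genotype_pair_counts(dos_i, dos_j) -> tuple[np.ndarray, int]:
    di = np.asarray(dos_i, dtype=float)
    dj = np.asarray(dos_j, dtype=float)
    if di.shape != dj.shape:
        raise ValueError("dosage vectors differ in length")
    ok = np.isfinite(di) & np.isfinite(dj)
    di, dj = di[ok].astype(int), dj[ok].astype(int)
    counts = np.zeros((3, 3))
    np.add.at(counts, (di, dj), 1)
    return counts, int(ok.sum())


def _loglik(counts: np.ndarray, h: tuple[float, float, float, float]) -> float:
    """Log-likelihood of a 3x3 genotype-pair count table given haplotype
    frequencies h = (p_AB, p_Ab, p_aB, p_ab); A/B are the counted alleles."""
    pAB, pAb, paB, pab = h
    # genotype-pair probability from unordered haplotype pairs
    probs = {
        (2, 2): pAB * pAB,
        (2, 1): 2 * pAB * pAb,
        (2, 0): pAb * pAb,
        (1, 2): 2 * pAB * paB,
        (1, 1): 2 * pAB * pab + 2 * pAb * paB,
        (1, 0): 2 * pAb * pab,
        (0, 2): paB * paB,
        (0, 1): 2 * paB * pab,
        (0, 0): pab * pab,
    }
    ll = 0.0
    for (gi, gj), pr in probs.items():
        c = counts[gi, gj]
        if c:
            if pr <= 0:
                return -math.inf
            ll += c * math.log(pr)
    return ll


def em_haplotype_frequencies(
    counts: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
    init: Optional[tuple[float, float, float, float]] = None,
) -> tuple[float, float, float, float]:
    """EM estimate of two-locus haplotype frequencies from genotype pairs.

    Only the double heterozygote is phase-ambiguous; every other genotype
    pair contributes fixed haplotype counts. Initialised at linkage
    equilibrium and iterated until the largest frequency change drops below
    ``tol``.
    """
    n = counts.sum()
    if n == 0:
        raise ValueError("no complete genotype pairs")
    pA = (2 * counts[2, :].sum() + counts[1, :].sum()) / (2 * n)
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    h_le = [pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)]
    if init is None:
        if counts[1, 1] == 0:
            starts = [h_le]
        else:
            # the LE start is a stationary point (saddle) when double
            # heterozygotes dominate; add cis- and trans-leaning restarts
            # and keep the best-likelihood solution
            eps = min(0.5 * min(h_le), 0.02) if min(h_le) > 0 else 0.0
            cis = [h_le[0] + eps, h_le[1] - eps, h_le[2] - eps, h_le[3] + eps]
            trans = [h_le[0] - eps, h_le[1] + eps, h_le[2] + eps, h_le[3] - eps]
            starts = [h_le, cis, trans]
        best, best_ll = None, -math.inf
        for start in starts:
            cand = em_haplotype_frequencies(counts, tol, max_iter, tuple(start))
            ll = _loglik(counts, cand)
            if ll > best_ll:
                best, best_ll = cand, ll
        return best
    h = list(init)

    # fixed haplotype contributions from unambiguous genotype pairs
    c = counts
    base = [
        2 * c[2, 2] + c[2, 1] + c[1, 2],  # AB
        2 * c[2, 0] + c[2, 1] + c[1, 0],  # Ab
        2 * c[0, 2] + c[0, 1] + c[1, 2],  # aB
        2 * c[0, 0] + c[0, 1] + c[1, 0],  # ab
    ]
    n_dh = c[1, 1]  # double heterozygotes: AB/ab or Ab/aB
    denom = 2.0 * n
    for _ in range(max_iter):
        if n_dh:
            cis = h[0] * h[3]
            trans = h[1] * h[2]
            tot = cis + trans
            frac = 0.5 if tot <= 0 else cis / tot
        else:
            frac = 0.0
        # each double heterozygote carries one AB+ab pair (prob frac) or
        # one Ab+aB pair (prob 1-frac)
        new = [
            (base[0] + n_dh * frac) / denom,
            (base[1] + n_dh * (1 - frac)) / denom,
            (base[2] + n_dh * (1 - frac)) / denom,
            (base[3] + n_dh * frac) / denom,
        ]
        delta = max(abs(a - b) for a, b in zip(new, h))
        h = new
        if delta < tol:
            break
    return tuple(h)  # type: ignore[return-value]


def ld_pairwise(dosages_i, dosages_j, rsid_i: str = "i", rsid_j: str = "j") -> LdResult:
    """Pairwise LD statistics between two panel SNPs.

    Haplotype frequencies come from :func:`em_haplotype_frequencies`;
    D = p_AB - p_A p_B, D' normalises D by its frequency-bound maximum, and
    LOD is the log10 likelihood ratio of the EM solution against linkage
    equilibrium. A monomorphic locus yields a flagged degenerate result.
    """
    counts, n = _genotype_pair_counts(dosages_i, dosages_j)
    if n < 2:
        raise ValueError("need at least 2 complete genotype pairs")
    pA = (2 * counts[2, :].sum() + counts[1, :].sum()) / (2 * n)
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        h0 = (pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB))
        return LdResult(rsid_i, rsid_j, h0, 0.0, math.nan, math.nan, 0.0, n, True)
    h = em_haplotype_frequencies(counts)
    D = h[0] - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = 0.0 if dmax == 0 else abs(D) / dmax
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    h_le = (pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB))
    lod = (_loglik(counts, h) - _loglik(counts, h_le)) / math.log(10)
    return LdResult(rsid_i, rsid_j, h, float(D), float(dprime), float(r2),
                    float(lod), n)


def qc_report(cohort_a: Cohort, cohort_b: Cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP and per-pair QC tables for two cohorts.

    Returns (snp_table, ld_table): frequencies and HWE p per cohort with the
    between-cohort comparison; and D'/r2/LOD per SNP pair per cohort.
    """
    panel = cohort_a.panel
    snp_rows = []
    for entry in panel:
        rsid = entry.rsid
        hwe_a = hwe_for_dosages(cohort_a.genotypes.column(rsid), rsid)
        hwe_b = hwe_for_dosages(cohort_b.genotypes.column(rsid), rsid)
        comp = compare_allele_frequencies(cohort_a, cohort_b, rsid)
        snp_rows.append(
            {
                "rsid": rsid,
                "gene": entry.gene,
                "effect_allele": entry.effect_allele,
                f"freq_{cohort_a.label}": comp.freq_a,
                f"freq_{cohort_b.label}": comp.freq_b,
                f"hwe_p_{cohort_a.label}": hwe_a.p,
                f"hwe_p_{cohort_b.label}": hwe_b.p,
                "freq_chi2": comp.chi2,
                "freq_p": comp.p,
            }
        )
    ld_rows = []
    for cohort in (cohort_a, cohort_b):
        for i in range(len(panel)):
            for j in range(i + 1, len(panel)):
                res = ld_pairwise(
                    cohort.genotypes.dosages[:, i],
                    cohort.genotypes.dosages[:, j],
                    panel.rsids[i],
                    panel.rsids[j],
                )
                ld_rows.append(
                    {
                        "cohort": cohort.label,
                        "rsid_i": res.rsid_i,
                        "rsid_j": res.rsid_j,
                        "Dprime": res.Dprime,
                        "r2": res.r2,
                        "lod": res.lod,
                    }
                )
    return pd.DataFrame(snp_rows), pd.DataFrame(ld_rows)
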