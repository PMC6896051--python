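"""Reading, validating and aligning genotype and phenotype inputs.

Genotypes are stored as effect-allele dosages (0/1/2, NaN for missing) in a
samples x panel-SNPs matrix; orientation to the effect allele happens at read
time so every downstream stage sees risk-allele counts only. Phenotypes live
in a typed :class:`pandas.DataFrame`. A :class:`Cohort` pairs the two for one
study population, and :func:`complete_case_filter` applies the study's
complete-case exclusion rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .panel import SnpPanel

logger = logging.getLogger(__name__)

#: phenotype columns every pipeline stage relies on
PHENOTYPE_FIELDS = [
    "sex",
    "age",
    "bmi",
    "hdl",
    "tg",
    "fasting_glucose",
    "on_treatment",
    "population",
]
_POSITIVE_FIELDS = ["age", "bmi", "hdl", "tg", "fasting_glucose"]

# complementary base pairs whose strand cannot be resolved from a VCF record
_AMBIGUOUS_PAIRS = {frozenset("AT"), frozenset("CG")}


class ValidationError(ValueError):
    """Input failed a structural or range check."""


@dataclass
class GenotypeMatrix:
    """Effect-allele dosage matrix aligned to a :class:`SnpPanel`.

    ``dosages`` is a float array with entries in {0, 1, 2} or NaN (missing);
    columns follow panel order.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    panel: SnpPanel

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValidationError("dosage array must be 2-D")
        if self.dosages.shape != (len(self.sample_ids), len(self.panel)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.panel)} SNPs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids are not unique")
        finite = self.dosages[np.isfinite(self.dosages)]
        if not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValidationError("non-missing dosages must be 0, 1 or 2")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, rsid: str) -> np.ndarray:
        return self.dosages[:, self.panel.index_of(rsid)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.panel.rsids,
        )


@dataclass
class Cohort:
    """One study population: aligned genotypes and phenotypes plus a label."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    label: str

    def __post_init__(self) -> None:
        ids = list(self.phenotypes["sample_id"])
        if ids != self.genotypes.sample_ids:
            raise ValidationError(
                "phenotype and genotype sample_ids differ or are re-ordered"
            )

    @property
    def n_samples(self) -> int:
        return self.genotypes.n_samples

    @property
    def panel(self) -> SnpPanel:
        return self.genotypes.panel


def read_genotypes_vcf(path, panel: SnpPanel) -> GenotypeMatrix:
    """Read effect-allele dosages for the panel SNPs from a VCF.

    Sites are matched by ID first, then by chrom:pos where the panel carries
    coordinates. A panel SNP absent from the file yields a fully missing
    column. Strand-ambiguous sites (A/T or C/G) are rejected rather than
    guessed, as are sites where the effect allele matches neither REF nor ALT.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    dosages = np.full((n, len(panel)), np.nan)

    by_rsid = {e.rsid: i for i, e in enumerate(panel)}
    by_pos = {
        (e.chrom, e.pos): i
        for i, e in enumerate(panel)
        if e.chrom is not None and e.pos is not None
    }
    seen = set()
    for rec in vcf:
        idx = by_rsid.get(rec.ID)
        if idx is None:
            idx = by_pos.get((rec.CHROM, rec.POS))
        if idx is None or idx in seen:
            continue
        seen.add(idx)
        entry = panel.entries[idx]
        alleles = [rec.REF] + list(rec.ALT)
        if entry.effect_allele not in alleles:
            raise ValidationError(
                f"{entry.rsid}: effect allele {entry.effect_allele} matches "
                f"neither REF ({rec.REF}) nor ALT ({','.join(rec.ALT) or '-'})"
            )
        if len(alleles) == 2 and frozenset(alleles) in _AMBIGUOUS_PAIRS:
            raise ValidationError(
                f"{entry.rsid}: strand-ambiguous site "
                f"({rec.REF}/{rec.ALT[0]}); refusing to orient effect allele"
            )
        effect_idx = alleles.index(entry.effect_allele)
        gts = rec.genotype.array()  # (n, ploidy + 1); last col is phasing
        calls = gts[:, :-1]
        valid = (calls >= 0).all(axis=1)
        # on a biallelic site every called genotype is interpretable; on a
        # multi-allelic site only REF/effect alleles keep the dosage defined
        allowed = (0, 1) if len(alleles) == 2 else (0, effect_idx)
        valid &= np.isin(calls, allowed).all(axis=1)
        col = np.where(valid, (calls == effect_idx).sum(axis=1), np.nan)
        dosages[:, idx] = col
    return GenotypeMatrix(dosages=dosages, sample_ids=sample_ids, panel=panel)


def read_genotypes_table(path, panel: SnpPanel) -> GenotypeMatrix:
    """Read a dosage table (one row per sample, one column per rsid).

    Cells must be 0/1/2, ``NA`` or empty. Column order is reconciled to
    panel order.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    id_col = df.columns[0]
    missing_cols = [r for r in panel.rsids if r not in df.columns]
    if missing_cols:
        raise ValidationError(f"dosage table missing panel columns: {missing_cols}")
    sample_ids = df[id_col].astype(str).tolist()
    dosages = np.full((len(df), len(panel)), np.nan)
    for j, rsid in enumerate(panel.rsids):
        for i, cell in enumerate(df[rsid]):
            if pd.isna(cell) or str(cell).strip() in ("", "NA"):
                continue
            try:
                value = float(cell)
            except ValueError:
                value = -1.0
            if value not in (0.0, 1.0, 2.0):
                raise ValidationError(
                    f"dosage table row {i + 1} column {rsid!r}: "
                    f"invalid cell {cell!r} (expected 0/1/2/NA)"
                )
            dosages[i, j] = value
    return GenotypeMatrix(dosages=dosages, sample_ids=sample_ids, panel=panel)


def write_genotypes_table(gm: GenotypeMatrix, path) -> None:
    """Write the dosage-table dialect read back by :func:`read_genotypes_table`."""
    df = gm.to_frame()
    out = df.map(lambda v: "NA" if not np.isfinite(v) else str(int(v)))
    out.to_csv(path)


_SEX_CODES = {"male": "male", "m": "male", "female": "female", "f": "female"}
_BOOL_CODES = {
    "0": False, "1": True, "false": False, "true": True,
    "no": False, "yes": True,
}


def read_phenotypes(path) -> pd.DataFrame:
    """Read and type-check a delimited phenotype table.

    Requires a header with ``sample_id`` plus the fields in
    :data:`PHENOTYPE_FIELDS`; extra columns are preserved. Missing numeric
    cells are kept as NaN (the complete-case filter drops them later).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = ["sample_id"] + PHENOTYPE_FIELDS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype table missing columns: {missing}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)

    def parse_sex(v):
        if pd.isna(v):
            return np.nan
        code = _SEX_CODES.get(str(v).strip().lower())
        if code is None:
            raise ValidationError(f"unparseable sex value {v!r}")
        return code

    def parse_bool(v):
        if pd.isna(v):
            return np.nan
        code = _BOOL_CODES.get(str(v).strip().lower())
        if code is None:
            raise ValidationError(f"unparseable boolean value {v!r}")
        return code

    df["sex"] = df["sex"].map(parse_sex)
    df["on_treatment"] = df["on_treatment"].map(parse_bool)
    for col in _POSITIVE_FIELDS:
        df[col] = pd.to_numeric(df[col], errors="raise")
        bad = df[col].dropna() <= 0
        if bad.any():
            raise ValidationError(
                f"non-positive {col} for samples "
                f"{df.loc[bad.index[bad], 'sample_id'].tolist()}"
            )
    df["population"] = df["population"].astype(str)
    return validate_phenotypes(df)


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Range-check an already-typed phenotype frame (idempotent)."""
    missing = [c for c in ["sample_id"] + PHENOTYPE_FIELDS if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype frame missing columns: {missing}")
    for col in _POSITIVE_FIELDS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals.dropna() <= 0).any():
            raise ValidationError(f"non-positive values in {col}")
    return df


def complete_case_filter(cohort: Cohort) -> Cohort:
    """Drop every sample with any missing genotype or phenotype field.

    Mirrors the study's complete-case rule: scores and models are only
    defined for fully observed individuals. Removal counts per reason are
    logged.
    """
    geno_ok = np.isfinite(cohort.genotypes.dosages).all(axis=1)
    pheno = cohort.phenotypes
    pheno_ok = np.ones(len(pheno), dtype=bool)
    for col in PHENOTYPE_FIELDS:
        pheno_ok &= pheno[col].notna().to_numpy()
    keep = geno_ok & pheno_ok
    n_geno = int((~geno_ok).sum())
    n_pheno = int((~pheno_ok).sum())
    n_both = int((~geno_ok & ~pheno_ok).sum())
    logger.info(
        "%s: complete-case filter kept %d of %d samples "
        "(missing genotype: %d, missing phenotype: %d, both: %d)",
        cohort.label, int(keep.sum()), cohort.n_samples, n_geno, n_pheno, n_both,
    )
    if not keep.any():
        raise ValidationError(f"{cohort.label}: no complete cases remain")
    gm = GenotypeMatrix(
        dosages=cohort.genotypes.dosages[keep],
        sample_ids=[s for s, k in zip(cohort.genotypes.sample_ids, keep) if k],
        panel=cohort.panel,
    )
    ph = pheno.loc[keep].reset_index(drop=True)
    return replace(cohort, genotypes=gm, phenotypes=ph)


def assemble_cohort(
    genotypes: GenotypeMatrix, phenotypes: pd.DataFrame, label: str
) -> Cohort:
    """Align phenotype rows to genotype sample order and build a Cohort."""
    ph = phenotypes.set_index("sample_id", drop=False)
    missing = [s for s in genotypes.sample_ids if s not in ph.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} genotyped samples lack phenotypes, e.g. {missing[:3]}"
        )
    ph = ph.loc[genotypes.sample_ids].reset_index(drop=True)
    return Cohort(genotypes=genotypes, phenotypes=ph, label=label)
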