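"""SNP panel definition: the ordered marker set shared by every pipeline stage.

A panel row carries the rsID, gene, effect (risk) allele and the pooled
per-allele odds ratio obtained from published meta-analyses. The panel's
order is fixed and indexes every genotype matrix column downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import pandas as pd

VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class StudyEffect:
    """One published study's effect estimate on the log-odds scale."""

    ln_or: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"standard error must be positive, got {self.se}")


@dataclass(frozen=True)
class PanelEntry:
    rsid: str
    gene: str
    effect_allele: str
    pooled_or: float
    chrom: Optional[str] = None
    pos: Optional[int] = None
    source_studies: tuple[StudyEffect, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(
                f"{self.rsid}: effect allele must be one of A/C/G/T, "
                f"got {self.effect_allele!r}"
            )
        if not self.pooled_or > 0:
            raise ValueError(f"{self.rsid}: pooled OR must be positive")


@dataclass(frozen=True)
class SnpPanel:
    """Ordered, immutable collection of :class:`PanelEntry`."""

    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        rsids = [e.rsid for e in self.entries]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise ValueError(f"duplicate rsids in panel: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def rsids(self) -> list[str]:
        return [e.rsid for e in self.entries]

    @property
    def pooled_ors(self) -> list[float]:
        return [e.pooled_or for e in self.entries]

    def index_of(self, rsid: str) -> int:
        try:
            return self.rsids.index(rsid)
        except ValueError:
            raise KeyError(f"rsid {rsid!r} not in panel") from None

    def __getitem__(self, rsid: str) -> PanelEntry:
        return self.entries[self.index_of(rsid)]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SnpPanel":
        required = {"rsid", "gene", "effect_allele", "pooled_or"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        entries = []
        for row in df.itertuples(index=False):
            entries.append(
                PanelEntry(
                    rsid=str(row.rsid),
                    gene=str(row.gene),
                    effect_allele=str(row.effect_allele).upper(),
                    pooled_or=float(row.pooled_or),
                    chrom=str(row.chrom) if "chrom" in df.columns and pd.notna(row.chrom) else None,
                    pos=int(row.pos) if "pos" in df.columns and pd.notna(row.pos) else None,
                )
            )
        return cls(entries=tuple(entries))

    @classmethod
    def from_csv(cls, path) -> "SnpPanel":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "gene": [e.gene for e in self.entries],
                "effect_allele": [e.effect_allele for e in self.entries],
                "pooled_or": self.pooled_ors,
            }
        )

    @classmethod
    def from_entries(
        cls, rows: Sequence[tuple[str, str, str, float]]
    ) -> "SnpPanel":
        """Build a panel from (rsid, gene, effect_allele, pooled_or) tuples."""
        return cls(
            entries=tuple(
                PanelEntry(rsid=r, gene=g, effect_allele=a, pooled_or=o)
                for r, g, a, o in rows
            )
        )


def load_default_panel() -> SnpPanel:
    """The bundled 16-SNP type 2 diabetes susceptibility panel."""
    with resources.files("grspipe.data").joinpath("panel.csv").open() as fh:
        return SnpPanel.from_frame(pd.read_csv(fh))
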