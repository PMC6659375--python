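"""Core record types shared across the pipeline.

Summary statistics are carried both as lightweight dataclasses (one variant,
one trait) and as :class:`RegionalDataset`, a thin wrapper around a pandas
DataFrame holding all variants of one trait over one genomic window.  All
coordinates are 1-based, inclusive, VCF convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Optional

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order for summary-statistics tables
SUMMARY_COLUMNS = [
    "id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]


@dataclass(frozen=True)
class VariantKey:
    """Identity of a biallelic SNP: id, position and allele pair."""

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for a in (self.effect_allele, self.other_allele):
            if not a or a.upper() != a:
                raise ValueError(f"alleles must be non-empty uppercase, got {a!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G pairs: indistinguishable from their strand complement."""
        return COMPLEMENT.get(self.effect_allele) == self.other_allele

    def complement(self) -> "VariantKey":
        return replace(
            self,
            effect_allele=COMPLEMENT[self.effect_allele],
            other_allele=COMPLEMENT[self.other_allele],
        )

    def swapped(self) -> "VariantKey":
        return replace(
            self, effect_allele=self.other_allele, other_allele=self.effect_allele
        )


@dataclass(frozen=True)
class AssociationRecord:
    """One variant's association with one trait.

    ``beta`` is the per-effect-allele effect in SD units of the trait,
    ``se`` its standard error, ``pvalue`` two-sided, ``eaf`` the effect-allele
    frequency (may be ``None``) and ``n`` the sample size.
    """

    variant: VariantKey
    beta: float
    se: float
    pvalue: float
    eaf: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"pvalue must be in (0,1], got {self.pvalue}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"eaf must be in [0,1], got {self.eaf}")

    @property
    def z(self) -> float:
        return self.beta / self.se

    def flipped(self) -> "AssociationRecord":
        """Same association expressed on the other allele."""
        return replace(
            self,
            variant=self.variant.swapped(),
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


class RegionalDataset:
    """Per-variant association records for one trait over one region.

    Backed by a DataFrame with columns :data:`SUMMARY_COLUMNS`; rows are
    ordered by position and variant ids are unique.
    """

    def __init__(self, trait_id: str, trait_type: str, table: pd.DataFrame):
        if trait_type not in {"methylation", "expression", "complex"}:
            raise ValueError(f"unknown trait_type {trait_type!r}")
        missing = [c for c in SUMMARY_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"summary table missing columns {missing}")
        table = table.loc[:, SUMMARY_COLUMNS].copy()
        if table["chrom"].nunique() > 1:
            raise ValueError("RegionalDataset must lie on a single chromosome")
        if table["id"].duplicated().any():
            raise ValueError("duplicate variant ids in RegionalDataset")
        table = table.sort_values("pos", kind="mergesort").reset_index(drop=True)
        self.trait_id = trait_id
        self.trait_type = trait_type
        self.table = table
        self._index = {vid: i for i, vid in enumerate(table["id"])}

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table["id"])

    def record(self, variant_id: str) -> AssociationRecord:
        row = self.table.iloc[self._index[variant_id]]
        return _row_to_record(row)

    def records(self) -> Iterator[AssociationRecord]:
        for _, row in self.table.iterrows():
            yield _row_to_record(row)

    def subset(self, variant_ids) -> "RegionalDataset":
        keep = [vid for vid in variant_ids if vid in self._index]
        idx = [self._index[v] for v in keep]
        return RegionalDataset(
            self.trait_id, self.trait_type, self.table.iloc[idx]
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<RegionalDataset {self.trait_id!r} ({self.trait_type}), "
            f"{len(self)} variants>"
        )


def _row_to_record(row: pd.Series) -> AssociationRecord:
    eaf = row["eaf"]
    n = row["n"]
    return AssociationRecord(
        variant=VariantKey(
            id=str(row["id"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=str(row["effect_allele"]),
            other_allele=str(row["other_allele"]),
        ),
        beta=float(row["beta"]),
        se=float(row["se"]),
        pvalue=float(row["pvalue"]),
        eaf=None if pd.isna(eaf) else float(eaf),
        n=None if pd.isna(n) else int(n),
    )


@dataclass(frozen=True)
class CpGAnnotation:
    """One CpG site with its upstream-exposure EWAS effect.

    ``ewas_beta``/``ewas_se`` are the exposure -> methylation association from
    an epigenome-wide association study; ``ewas_fdr`` the study's FDR for it.
    """

    cpg_id: str
    chrom: str
    pos: int
    ewas_beta: float
    ewas_se: float
    ewas_fdr: float

    def __post_init__(self) -> None:
        if not self.ewas_se > 0:
            raise ValueError("ewas_se must be > 0")
        if not (0 <= self.ewas_fdr <= 1):
            raise ValueError("ewas_fdr must be in [0,1]")


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    start: int
    end: int

    def distance_to(self, pos: int) -> int:
        """Base pairs from ``pos`` to the nearest edge of the gene interval."""
        if self.start <= pos <= self.end:
            return 0
        return min(abs(pos - self.start), abs(pos - self.end))


@dataclass(frozen=True)
class TraitMeta:
    """Study-level metadata used by the GWAS eligibility filter."""

    trait_id: str
    sample_n: int
    n_variants_reported: int
    population: str
    has_beta_se_ea: bool

    def __post_init__(self) -> None:
        if self.sample_n < 0 or self.n_variants_reported < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class ReferencePanel:
    """Genotype dosages (individuals x variants) for LD and frequency lookup."""

    dosages: np.ndarray
    variants: list[VariantKey]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage matrix does not match variant list")
        self._index = {v.id: i for i, v in enumerate(self.variants)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self._index[variant_id]]

    def eaf(self, variant_id: str) -> float:
        """Effect (ALT) allele frequency from dosage counts."""
        return float(self.column(variant_id).mean() / 2.0)

    def maf(self, variant_id: str) -> float:
        f = self.eaf(variant_id)
        return min(f, 1.0 - f)

    def r(self, id_a: str, id_b: str) -> float:
        """Dosage correlation between two variants (signed)."""
        a, b = self.column(id_a), self.column(id_b)
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    def r2(self, id_a: str, id_b: str) -> float:
        return self.r(id_a, id_b) ** 2

    def ld_matrix(self, variant_ids) -> np.ndarray:
        idx = [self._index[v] for v in variant_ids]
        X = self.dosages[:, idx]
        sd = X.std(axis=0)
        sd[sd == 0] = np.nan
        Xc = (X - X.mean(axis=0)) / sd
        R = (Xc.T @ Xc) / X.shape[0]
        return np.nan_to_num(R, nan=0.0)
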