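"""Reading, validation and writing of summary statistics, panels, annotations.

Summary-statistics tables are tab-delimited with a header; the default header
set is ``SNP CHR BP EA OA EAF BETA SE P N`` and can be remapped with a
``column_map``.  Rows violating the record invariants (se <= 0, p outside
(0,1], malformed alleles ...) never abort a read: they are dropped, counted
and logged, because phenome-scale scans must be fault tolerant.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .records import (
    SUMMARY_COLUMNS,
    VALID_BASES,
    CpGAnnotation,
    GeneAnnotation,
    ReferencePanel,
    RegionalDataset,
    TraitMeta,
    VariantKey,
)

logger = logging.getLogger(__name__)

#: default file header -> canonical field names
DEFAULT_COLUMN_MAP = {
    "SNP": "id", "CHR": "chrom", "BP": "pos", "EA": "effect_allele",
    "OA": "other_allele", "EAF": "eaf", "BETA": "beta", "SE": "se",
    "P": "pvalue", "N": "n",
}

MANDATORY_FIELDS = [
    "id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pvalue",
]


class ColumnMappingError(KeyError):
    """A mandatory summary-statistics column is absent from the file."""


class EmptyInputError(ValueError):
    """No valid rows survived validation."""


def read_summary_table(
    path,
    trait_id: str,
    trait_type: str = "complex",
    column_map: Optional[dict] = None,
) -> RegionalDataset:
    """Read one trait's per-variant summary statistics from a TSV file.

    Invalid rows are rejected (with a logged count); duplicate variant ids
    keep the first occurrence.  Raises :class:`ColumnMappingError` when a
    mandatory column is missing and :class:`EmptyInputError` when no valid
    row remains.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    present = {cmap[c]: c for c in raw.columns if c in cmap}
    missing = [f for f in MANDATORY_FIELDS if f not in present]
    if missing:
        raise ColumnMappingError(
            f"{path}: missing mandatory columns for fields {missing}"
        )
    df = pd.DataFrame(index=raw.index)
    for fld in SUMMARY_COLUMNS:
        if fld in present:
            df[fld] = raw[present[fld]]
        else:
            df[fld] = np.nan

    df["id"] = df["id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for a in ("effect_allele", "other_allele"):
        df[a] = df[a].astype(str).str.upper().str.strip()
    for num in ("pos", "eaf", "beta", "se", "pvalue", "n"):
        df[num] = pd.to_numeric(df[num], errors="coerce")

    ok = (
        df["pos"].notna() & (df["pos"] >= 1)
        & df["beta"].notna() & df["se"].notna() & (df["se"] > 0)
        & df["pvalue"].notna() & (df["pvalue"] > 0) & (df["pvalue"] <= 1)
        & df["effect_allele"].map(_valid_allele)
        & df["other_allele"].map(_valid_allele)
        & (df["effect_allele"] != df["other_allele"])
        & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)))
    )
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning(
            "%s: rejected %d of %d rows failing record invariants",
            path, n_rejected, len(df),
        )
    df = df[ok]
    dup = df["id"].duplicated()
    if dup.any():
        logger.warning("%s: dropped %d duplicate variant ids", path, int(dup.sum()))
        df = df[~dup]
    if df.empty:
        raise EmptyInputError(f"{path}: no valid summary rows")
    df["pos"] = df["pos"].astype(int)
    return RegionalDataset(trait_id, trait_type, df.reset_index(drop=True))


def _valid_allele(a: str) -> bool:
    return len(a) > 0 and set(a) <= VALID_BASES


def write_summary_table(dataset: RegionalDataset, path) -> None:
    """Write a dataset back to the default tab-delimited layout.

    Uses ``repr``-faithful float formatting so that a read/write round trip
    reproduces every numeric field.
    """
    inv = {v: k for k, v in DEFAULT_COLUMN_MAP.items()}
    out = dataset.table.rename(columns=inv)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_reference_panel(path, region: Optional[tuple] = None) -> ReferencePanel:
    """Load biallelic SNP dosages from a VCF file.

    ``region`` is an optional ``(chrom, start, end)`` triple (1-based,
    inclusive).  Multiallelic and non-SNP records are skipped.  The returned
    dosages count copies of the ALT allele, which is taken as the effect
    allele of each :class:`VariantKey`.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 raises OSError subclasses
        raise OSError(f"cannot read VCF {path}: {exc}") from exc
    keys: list[VariantKey] = []
    columns: list[np.ndarray] = []
    for v in vcf:
        if region is not None:
            chrom, start, end = region
            if str(v.CHROM) != str(chrom) or not (start <= v.POS <= end):
                continue
        if len(v.ALT) != 1 or not v.is_snp:
            continue
        ref, alt = v.REF.upper(), v.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1:
            continue
        gts = np.asarray(v.genotypes)[:, :2]
        dose = gts.sum(axis=1).astype(float)
        dose[(gts < 0).any(axis=1)] = np.nan
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        keys.append(
            VariantKey(
                id=str(vid), chrom=str(v.CHROM), pos=int(v.POS),
                effect_allele=alt, other_allele=ref,
            )
        )
        columns.append(dose)
    vcf.close()
    if not keys:
        raise EmptyInputError(f"{path}: no biallelic SNPs in requested region")
    return ReferencePanel(np.column_stack(columns), keys)


def filter_trait_eligibility(meta: TraitMeta) -> tuple[bool, str]:
    """GWAS inclusion rule: a pure conjunction of four criteria.

    Samples strictly larger than 1000, strictly more than 100 000 reported
    variants, European or mixed population, and beta/SE/effect-allele columns
    present.  Returns ``(eligible, reason)`` where reason names the first
    failing criterion, or ``"eligible"``.
    """
    if not meta.sample_n > 1000:
        return False, "sample size"
    if not meta.n_variants_reported > 100000:
        return False, "variant count"
    if meta.population not in {"European", "mixed"}:
        return False, "population"
    if not meta.has_beta_se_ea:
        return False, "missing beta/se/effect allele"
    return True, "eligible"


def read_cpg_annotation(path) -> list[CpGAnnotation]:
    """CpG annotation TSV: cpg_id, chrom, pos, ewas_beta, ewas_se, ewas_fdr."""
    df = pd.read_csv(path, sep="\t")
    return [
        CpGAnnotation(
            cpg_id=str(r.cpg_id), chrom=str(r.chrom), pos=int(r.pos),
            ewas_beta=float(r.ewas_beta), ewas_se=float(r.ewas_se),
            ewas_fdr=float(r.ewas_fdr),
        )
        for r in df.itertuples()
    ]


def write_cpg_annotation(cpgs, path) -> None:
    pd.DataFrame(
        [
            {
                "cpg_id": c.cpg_id, "chrom": c.chrom, "pos": c.pos,
                "ewas_beta": c.ewas_beta, "ewas_se": c.ewas_se,
                "ewas_fdr": c.ewas_fdr,
            }
            for c in cpgs
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gene_annotation(path) -> list[GeneAnnotation]:
    """Gene annotation TSV: gene_id, chrom, start, end."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneAnnotation(
            gene_id=str(r.gene_id), chrom=str(r.chrom),
            start=int(r.start), end=int(r.end),
        )
        for r in df.itertuples()
    ]


def write_gene_annotation(genes, path) -> None:
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end}
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def load_config(path) -> dict:
    """Load a YAML pipeline configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_vcf(panel: ReferencePanel, path, sample_prefix: str = "S") -> None:
    """Write a reference panel as a plain-text VCF 4.2 file with GT fields.

    Dosages must be integral 0/1/2; heterozygotes are written unphased (0/1).
    """
    n = panel.dosages.shape[0]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in dict.fromkeys(v.chrom for v in panel.variants):
        lines.append(f"##contig=<ID={chrom}>")
    samples = "\t".join(f"{sample_prefix}{i}" for i in range(n))
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + samples
    )
    order = np.argsort([v.pos for v in panel.variants], kind="stable")
    for j in order:
        v = panel.variants[j]
        gts = "\t".join(gt_map[int(d)] for d in panel.dosages[:, j])
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.id}\t{v.other_allele}\t{v.effect_allele}"
            f"\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
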