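"""Top-level pipeline: eligibility -> instruments -> MR scan -> colocalization
-> top-trait selection -> orientation -> (optional) replication comparison.

The stage order and gating mirror the analysis flow of a two-step epigenetic
MR study: only CpG-trait pairs whose MR p-value survives the Bonferroni
threshold reach colocalization, and only pairs with PPA_abc at or above the
configured threshold reach orientation.  Per-CpG/trait failures are isolated
and recorded; the pipeline always completes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import instruments as ins_mod
from .mr import MRResult, bonferroni_threshold, run_phenome_scan
from .orientation import (
    compare_estimates,
    orient_chain,
    reverse_mr,
    steiger_direction,
)
from .records import ReferencePanel
from .summary_io import (
    filter_trait_eligibility,
    read_cpg_annotation,
    read_gene_annotation,
    read_reference_panel,
    read_summary_table,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineParams:
    """All thresholds of the pipeline, in one place."""

    alpha: float = 0.05
    mqtl_p_threshold: float = ins_mod.MQTL_P_THRESHOLD
    cis_window: int = ins_mod.CIS_WINDOW
    collinearity_r2: float = ins_mod.COLLINEARITY_R2
    ppa_threshold: float = coloc_mod.PPA_THRESHOLD
    coloc_window: int = coloc_mod.GENE_WINDOW
    coloc_min_variants: int = coloc_mod.MIN_VARIANTS
    coloc_min_maf: float = coloc_mod.MIN_MAF
    coloc_priors: tuple = coloc_mod.DEFAULT_PRIORS
    coloc_prior_w: float = coloc_mod.DEFAULT_PRIOR_W
    reverse_p_threshold: float = 5e-8
    steiger_level: float = 0.05


@dataclass
class StudyData:
    """In-memory study: annotations, summary datasets, metadata, panel."""

    cpgs: list
    genes: list
    mqtl: dict
    eqtl: dict
    gwas: dict
    trait_meta: dict
    panel: ReferencePanel


def load_study(directory) -> StudyData:
    """Load a study from the on-disk layout ``write_study`` emits."""
    d = Path(directory)
    cpgs = read_cpg_annotation(d / "cpgs.tsv")
    genes = read_gene_annotation(d / "genes.tsv")
    mqtl = {
        c.cpg_id: read_summary_table(
            d / f"mqtl_{c.cpg_id}.tsv", c.cpg_id, "methylation"
        )
        for c in cpgs
    }
    eqtl = {
        g.gene_id: read_summary_table(
            d / f"eqtl_{g.gene_id}.tsv", g.gene_id, "expression"
        )
        for g in genes
    }
    gwas = {}
    for p in sorted(d.glob("gwas_*.tsv")):
        trait_id = p.stem[len("gwas_"):]
        gwas[trait_id] = read_summary_table(p, trait_id, "complex")
    panel = read_reference_panel(d / "panel.vcf")
    from .records import TraitMeta

    trait_meta = {
        t: TraitMeta(
            trait_id=t,
            sample_n=int(ds.table["n"].max()),
            n_variants_reported=1_000_000,
            population="European",
            has_beta_se_ea=True,
        )
        for t, ds in gwas.items()
    }
    return StudyData(
        cpgs=cpgs, genes=genes, mqtl=mqtl, eqtl=eqtl, gwas=gwas,
        trait_meta=trait_meta, panel=panel,
    )


@dataclass
class PipelineReport:
    eligibility: pd.DataFrame
    instruments: pd.DataFrame
    scan: pd.DataFrame
    coloc: pd.DataFrame
    top_traits: pd.DataFrame
    orientation: pd.DataFrame
    comparisons: pd.DataFrame
    final: pd.DataFrame
    manifest: dict


def run_pipeline(
    study,
    params: Optional[PipelineParams] = None,
    outdir=None,
    replication: Optional[dict] = None,
) -> PipelineReport:
    """Execute all stages on a study and (optionally) write every table.

    ``study`` needs attributes cpgs, genes, mqtl, eqtl, gwas, trait_meta and
    panel (e.g. a :class:`StudyData` or a simulated study).  ``replication``
    optionally maps trait_id -> RegionalDataset of an independent outcome
    sample for the comparison stage.
    """
    p = params or PipelineParams()
    panel = study.panel

    # --- stage 1: trait eligibility ------------------------------------
    elig_rows = []
    eligible_traits = {}
    for trait_id, ds in study.gwas.items():
        meta = study.trait_meta[trait_id]
        ok, reason = filter_trait_eligibility(meta)
        elig_rows.append(
            {"trait_id": trait_id, "eligible": ok, "reason": reason}
        )
        if ok:
            eligible_traits[trait_id] = ds
    eligibility = pd.DataFrame(elig_rows)

    # --- stage 2: instrument selection ---------------------------------
    ins_rows = []
    instrument_sets = {}
    for cpg in study.cpgs:
        try:
            iset = ins_mod.cojo_slct(
                study.mqtl[cpg.cpg_id], panel, cpg,
                p_threshold=p.mqtl_p_threshold, cis_window=p.cis_window,
                collinearity_r2=p.collinearity_r2,
            )
        except ins_mod.UninstrumentableCpGError:
            instrument_sets[cpg.cpg_id] = None
            ins_rows.append(
                {
                    "cpg_id": cpg.cpg_id, "variant_id": "", "pos": -1,
                    "effect_allele": "", "other_allele": "",
                    "beta": np.nan, "se": np.nan, "pvalue": np.nan,
                    "joint_beta": np.nan, "joint_se": np.nan,
                    "joint_pvalue": np.nan, "status": "uninstrumentable",
                }
            )
            continue
        instrument_sets[cpg.cpg_id] = iset
        for rec, jb, jse, jp in iset.instruments:
            ins_rows.append(
                {
                    "cpg_id": cpg.cpg_id, "variant_id": rec.variant.id,
                    "pos": rec.variant.pos,
                    "effect_allele": rec.variant.effect_allele,
                    "other_allele": rec.variant.other_allele,
                    "beta": rec.beta, "se": rec.se, "pvalue": rec.pvalue,
                    "joint_beta": jb, "joint_se": jse, "joint_pvalue": jp,
                    "status": "selected",
                }
            )
    instruments = pd.DataFrame(ins_rows)

    # --- stage 3/4: phenome scan + multiple-testing threshold ----------
    scan = run_phenome_scan(
        instrument_sets, eligible_traits, panel, alpha=p.alpha
    )
    threshold = scan.attrs.get("bonferroni_threshold", np.nan)
    significant = scan[scan["significant"]]

    # --- stage 5: colocalization on significant hits --------------------
    cpg_by_id = {c.cpg_id: c for c in study.cpgs}
    coloc_rows = []
    for _, hit in significant.iterrows():
        cpg = cpg_by_id[hit["cpg_id"]]
        res = coloc_mod.gene_window_scan(
            cpg, study.mqtl[cpg.cpg_id], eligible_traits[hit["trait_id"]],
            study.eqtl, study.genes, panel,
            window=p.coloc_window, min_variants=p.coloc_min_variants,
            min_maf=p.coloc_min_maf, prior_w=p.coloc_prior_w,
            priors=p.coloc_priors,
        )
        res["mr_pvalue"] = hit["pvalue"]
        res["mr_beta"] = hit["beta"]
        res["mr_se"] = hit["se"]
        res["mr_method"] = hit["method"]
        res["mr_n_instruments"] = hit["n_instruments"]
        coloc_rows.append(res)
    coloc_results = (
        pd.concat(coloc_rows, ignore_index=True)
        if coloc_rows
        else pd.DataFrame(
            columns=[
                "cpg_id", "gene_id", "trait_id", "n_variants", "ppa_abc",
                "best_shared_variant", "skip_reason", "posterior",
                "mr_pvalue", "mr_beta", "mr_se", "mr_method",
                "mr_n_instruments",
            ]
        )
    )

    # --- stage 6: top trait per CpG among colocalizing hits --------------
    passing = coloc_results[
        coloc_results["ppa_abc"].notna()
        & (coloc_results["ppa_abc"] >= p.ppa_threshold)
    ]
    top = coloc_mod.select_top_trait(passing) if len(passing) else passing

    # --- stage 7: orientation -------------------------------------------
    orient_rows = []
    for _, row in top.iterrows():
        cpg = cpg_by_id[row["cpg_id"]]
        mr_res = MRResult(
            cpg_id=row["cpg_id"], trait_id=row["trait_id"],
            beta=float(row["mr_beta"]), se=float(row["mr_se"]),
            pvalue=float(row["mr_pvalue"]), method=str(row["mr_method"]),
            n_instruments=int(row["mr_n_instruments"])
            if str(row["mr_method"]) == "ivw" else 1,
        )
        chain = orient_chain(cpg, mr_res)
        rev = reverse_mr(
            eligible_traits[row["trait_id"]], study.mqtl[cpg.cpg_id], panel,
            p_threshold=p.reverse_p_threshold,
        )
        steiger = _steiger_chain(
            instrument_sets[row["cpg_id"]], study.mqtl[cpg.cpg_id],
            study.eqtl.get(row["gene_id"]), eligible_traits[row["trait_id"]],
            level=p.steiger_level,
        )
        orient_rows.append(
            {
                "cpg_id": row["cpg_id"], "trait_id": row["trait_id"],
                "gene_id": row["gene_id"],
                "mr_beta": mr_res.beta, "mr_se": mr_res.se,
                "mr_pvalue": mr_res.pvalue,
                "ppa_abc": row["ppa_abc"],
                "ewas_beta": cpg.ewas_beta,
                "implied_exposure_effect": chain.implied_exposure_effect,
                "reverse_mr_pvalue": np.nan if rev is None else rev.pvalue,
                "reverse_mr_beta": np.nan if rev is None else rev.beta,
                "steiger_meth_expr": steiger.get("meth_expr", ""),
                "steiger_expr_trait": steiger.get("expr_trait", ""),
                "steiger_meth_trait": steiger.get("meth_trait", ""),
            }
        )
    orientation = pd.DataFrame(
        orient_rows,
        columns=[
            "cpg_id", "trait_id", "gene_id", "mr_beta", "mr_se", "mr_pvalue",
            "ppa_abc", "ewas_beta", "implied_exposure_effect",
            "reverse_mr_pvalue", "reverse_mr_beta", "steiger_meth_expr",
            "steiger_expr_trait", "steiger_meth_trait",
        ],
    )

    # --- stage 8: optional replication comparison ------------------------
    comp_rows = []
    if replication:
        for _, row in orientation.iterrows():
            trait_id = row["trait_id"]
            if trait_id not in replication:
                continue
            iset = instrument_sets[row["cpg_id"]]
            from .mr import MRModel

            model = MRModel.from_datasets(iset, replication[trait_id], panel)
            if not model.exposures:
                continue
            rep_res = model.fit()
            base = MRResult(
                cpg_id=row["cpg_id"], trait_id=trait_id,
                beta=float(row["mr_beta"]), se=float(row["mr_se"]),
                pvalue=float(row["mr_pvalue"]),
                method="wald" if rep_res.method == "wald" else "ivw",
                n_instruments=rep_res.n_instruments
                if rep_res.method == "ivw" else 1,
            )
            rep_res.cpg_id = row["cpg_id"]
            comp = compare_estimates(base, rep_res)
            comp_rows.append(
                {
                    "cpg_id": comp.cpg_id, "trait_id": comp.trait_id,
                    "beta_discovery": comp.beta_a, "se_discovery": comp.se_a,
                    "beta_replication": comp.beta_b,
                    "se_replication": comp.se_b,
                    "sign_concordant": comp.sign_concordant,
                    "heterogeneity_z": comp.heterogeneity_z,
                    "heterogeneity_p": comp.heterogeneity_p,
                }
            )
    comparisons = pd.DataFrame(
        comp_rows,
        columns=[
            "cpg_id", "trait_id", "beta_discovery", "se_discovery",
            "beta_replication", "se_replication", "sign_concordant",
            "heterogeneity_z", "heterogeneity_p",
        ],
    )

    final = orientation.copy()
    manifest = {
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(p).items()
        },
        "bonferroni_threshold": float(threshold),
        "n_cpgs": int(scan.attrs.get("n_cpgs", 0)),
        "n_traits": int(scan.attrs.get("n_traits", 0)),
        "n_significant_pairs": int(len(significant)),
        "n_colocalizing_pairs": int(len(passing)),
        "seed": getattr(getattr(study, "config", None), "seed", None),
    }
    report = PipelineReport(
        eligibility=eligibility, instruments=instruments, scan=scan,
        coloc=coloc_results, top_traits=top, orientation=orientation,
        comparisons=comparisons, final=final, manifest=manifest,
    )
    if outdir is not None:
        _write_report(report, outdir)
    return report


def _steiger_chain(iset, mqtl, eqtl, gwas, level=0.05) -> dict:
    """Pairwise Steiger directions over (methylation, expression, trait)."""
    out = {}
    if iset is None or len(iset) == 0 or eqtl is None:
        return out
    recs = sorted(iset.records, key=lambda r: r.pvalue)
    vid = next((r.variant.id for r in recs if r.variant.id in eqtl
                and r.variant.id in gwas), None)
    if vid is None:
        return out
    m_rec = next(r for r in recs if r.variant.id == vid)
    e_rec = eqtl.record(vid)
    t_rec = gwas.record(vid)
    for key, x, y in (
        ("meth_expr", m_rec, e_rec),
        ("expr_trait", e_rec, t_rec),
        ("meth_trait", m_rec, t_rec),
    ):
        out[key] = steiger_direction([x], [y], level=level).direction
    return out


def _write_report(report: PipelineReport, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "eligibility": report.eligibility,
        "instruments": report.instruments,
        "scan": report.scan,
        "coloc": report.coloc.drop(columns=["posterior"], errors="ignore"),
        "top_traits": report.top_traits.drop(
            columns=["posterior"], errors="ignore"
        ),
        "orientation": report.orientation,
        "comparisons": report.comparisons,
        "final_report": report.final,
    }
    for name, df in tables.items():
        df.to_csv(
            out / f"{name}.tsv", sep="\t", index=False,
            float_format=FLOAT_FORMAT, na_rep="NA",
        )
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(report.manifest, fh, sort_keys=True)
    lines = [
        "Epigenetic MR pipeline summary",
        "==============================",
        f"traits analysed: {report.manifest['n_traits']}",
        f"CpGs analysed: {report.manifest['n_cpgs']}",
        f"Bonferroni threshold: {report.manifest['bonferroni_threshold']:.6g}",
        f"significant MR pairs: {report.manifest['n_significant_pairs']}",
        f"colocalizing pairs (PPA >= threshold): "
        f"{report.manifest['n_colocalizing_pairs']}",
        "",
    ]
    for _, row in report.final.iterrows():
        lines.append(
            f"{row['cpg_id']} -> {row['trait_id']} (gene {row['gene_id']}): "
            f"MR beta {row['mr_beta']:.4g} (SE {row['mr_se']:.3g}), "
            f"p {row['mr_pvalue']:.3g}, PPA_abc {row['ppa_abc']:.3f}; "
            f"exposure {row['implied_exposure_effect']} the trait"
        )
    if not len(report.final):
        lines.append("no CpG-trait association survived all gates")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
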