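"""Multi-CpG, multi-trait synthetic study for end-to-end pipeline runs.

Lays out one AR(1)-LD cis region per CpG (regions 10 Mb apart on one
chromosome, so cis windows never overlap), one gene and one expression
phenotype per region, and a distant block of independent background loci
providing each complex trait with its own polygenic instruments.  Causal
methylation -> trait links exist only for the *planted* (CpG, trait) pairs;
every other pair is null.  Methylation -> expression links exist in every
region (a shared local architecture), so colocalization is informative
exactly where a trait link is planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .records import GeneAnnotation, ReferencePanel, TraitMeta
from .simulate import (
    SimulationConfig,
    _mix,
    _std,
    compute_summary_stats,
    genotypes_given_mafs,
    make_variant_keys,
    simulate_ewas_table,
)
from .summary_io import (
    write_cpg_annotation,
    write_gene_annotation,
    write_summary_table,
    write_vcf,
)


@dataclass
class StudyConfig:
    """Layout of a planted-truth phenome scan."""

    n_cpgs: int = 10
    n_traits: int = 6
    planted: tuple = ((0, 0),)   # (cpg index, trait index) causal pairs
    bg_per_trait: int = 5
    bg_r2: float = 0.008
    region: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0


@dataclass
class SimulatedStudy:
    config: StudyConfig
    cpgs: list
    genes: list
    mqtl: dict       # cpg_id -> RegionalDataset over the full variant grid
    eqtl: dict       # gene_id -> RegionalDataset over its cis region
    gwas: dict       # trait_id -> RegionalDataset over the full variant grid
    trait_meta: dict
    panel: ReferencePanel
    truth: dict

    def trait_ids(self):
        return list(self.gwas)


def simulate_study(config: StudyConfig) -> SimulatedStudy:
    """Simulate all cohorts and emit summary statistics for the whole study."""
    sc = config
    rc = sc.region
    ss = np.random.SeedSequence(sc.seed)
    rng_maf, rng_panel, rng_m, rng_e, rng_g, rng_ph = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    m = rc.n_variants
    n_bg = sc.n_traits * sc.bg_per_trait

    blocks = []   # (keys, mafs, rho) per region block
    for r in range(sc.n_cpgs):
        mafs = rng_maf.uniform(rc.maf_range[0], rc.maf_range[1], size=m)
        keys = make_variant_keys(
            m, chrom=rc.chrom, start=1_000_000 + r * 10_000_000,
            spacing=rc.spacing, prefix=f"r{r:02d}v",
        )
        blocks.append((keys, mafs, rc.ld_rho))
    mafs_bg = rng_maf.uniform(rc.maf_range[0], rc.maf_range[1], size=n_bg)
    keys_bg = make_variant_keys(
        n_bg, chrom=rc.chrom, start=500_000_000, spacing=2_000_000, prefix="bg"
    )
    blocks.append((keys_bg, mafs_bg, 0.0))
    all_keys = [k for keys, _, _ in blocks for k in keys]

    def draw(n, rng):
        return np.hstack(
            [genotypes_given_mafs(n, mafs, rho, rng) for _, mafs, rho in blocks]
        )

    G = {
        "mqtl": draw(rc.n_mqtl, rng_m),
        "eqtl": draw(rc.n_eqtl, rng_e),
        "gwas": draw(rc.n_gwas, rng_g),
        "panel": draw(rc.n_panel, rng_panel),
    }
    k_causal = m // 2
    col = lambda cohort, r: G[cohort][:, r * m + k_causal]

    meth_obs, meth_latent_gwas, expr = {}, {}, {}
    for r in range(sc.n_cpgs):
        meth_obs[r] = _mix(_std(col("mqtl", r)), rc.causal_r2, rng_ph)
        m_e = _mix(_std(col("eqtl", r)), rc.causal_r2, rng_ph)
        expr[r] = _mix(m_e, rc.beta_me**2, rng_ph) * np.sign(rc.beta_me)
        meth_latent_gwas[r] = _mix(_std(col("gwas", r)), rc.causal_r2, rng_ph)

    planted = {(int(r), int(t)) for r, t in sc.planted}
    traits = {}
    bg_offset = sc.n_cpgs * m
    for t in range(sc.n_traits):
        y = np.zeros(rc.n_gwas)
        var = 0.0
        for (r, tt) in planted:
            if tt == t:
                y += rc.beta_mt * meth_latent_gwas[r]
                var += rc.beta_mt**2
        for j in range(sc.bg_per_trait):
            idx = bg_offset + t * sc.bg_per_trait + j
            y += np.sqrt(sc.bg_r2) * _std(G["gwas"][:, idx])
            var += sc.bg_r2
        y += np.sqrt(1.0 - var) * rng_ph.standard_normal(rc.n_gwas)
        traits[t] = _std(y)

    cpg_sites = []
    genes = []
    for r in range(sc.n_cpgs):
        keys_r = blocks[r][0]
        center = keys_r[k_causal].pos + 137
        cpg_sites.append((f"cg{r:08d}", rc.chrom, center))
        genes.append(
            GeneAnnotation(
                gene_id=f"GENE{r:02d}", chrom=rc.chrom,
                start=center - 15_000, end=center - 5_000,
            )
        )
    cpgs = simulate_ewas_table(cpg_sites, rc, seed=sc.seed)

    mqtl_ds = {
        cpgs[r].cpg_id: compute_summary_stats(
            G["mqtl"], meth_obs[r], all_keys, cpgs[r].cpg_id, "methylation"
        )
        for r in range(sc.n_cpgs)
    }
    eqtl_ds = {
        genes[r].gene_id: compute_summary_stats(
            G["eqtl"][:, r * m:(r + 1) * m], expr[r], blocks[r][0],
            genes[r].gene_id, "expression",
        )
        for r in range(sc.n_cpgs)
    }
    gwas_ds = {
        f"trait{t}": compute_summary_stats(
            G["gwas"], traits[t], all_keys, f"trait{t}", "complex"
        )
        for t in range(sc.n_traits)
    }
    trait_meta = {
        f"trait{t}": TraitMeta(
            trait_id=f"trait{t}", sample_n=rc.n_gwas,
            n_variants_reported=1_000_000, population="European",
            has_beta_se_ea=True,
        )
        for t in range(sc.n_traits)
    }
    panel = ReferencePanel(G["panel"], all_keys)
    truth = {
        "planted": sorted(
            (cpgs[r].cpg_id, f"trait{t}") for r, t in planted
        ),
        "true_mr_effect": rc.beta_mt,
        "causal_offset": k_causal,
    }
    return SimulatedStudy(
        config=sc, cpgs=cpgs, genes=genes, mqtl=mqtl_ds, eqtl=eqtl_ds,
        gwas=gwas_ds, trait_meta=trait_meta, panel=panel, truth=truth,
    )


def write_study(study: SimulatedStudy, outdir) -> dict:
    """Emit the study as the on-disk formats the readers consume.

    Writes per-CpG mQTL tables, per-gene eQTL tables, per-trait GWAS tables,
    the panel VCF, CpG/gene annotations and a truth/scenario YAML.  Returns
    the path manifest.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"mqtl": {}, "eqtl": {}, "gwas": {}}
    for cpg_id, ds in study.mqtl.items():
        p = out / f"mqtl_{cpg_id}.tsv"
        write_summary_table(ds, p)
        manifest["mqtl"][cpg_id] = str(p)
    for gene_id, ds in study.eqtl.items():
        p = out / f"eqtl_{gene_id}.tsv"
        write_summary_table(ds, p)
        manifest["eqtl"][gene_id] = str(p)
    for trait_id, ds in study.gwas.items():
        p = out / f"gwas_{trait_id}.tsv"
        write_summary_table(ds, p)
        manifest["gwas"][trait_id] = str(p)
    write_vcf(study.panel, out / "panel.vcf")
    manifest["panel"] = str(out / "panel.vcf")
    write_cpg_annotation(study.cpgs, out / "cpgs.tsv")
    manifest["cpgs"] = str(out / "cpgs.tsv")
    write_gene_annotation(study.genes, out / "genes.tsv")
    manifest["genes"] = str(out / "genes.tsv")
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "planted": [list(p) for p in study.truth["planted"]],
                "true_mr_effect": float(study.truth["true_mr_effect"]),
                "seed": int(study.config.seed),
            },
            fh, sort_keys=True,
        )
    manifest["truth"] = str(out / "truth.yaml")
    return manifest
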