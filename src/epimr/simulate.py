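"""Coupled genotype/phenotype simulator emitting regression summary statistics.

The generator stands in for the real data sources of a two-sample epigenetic
MR study: an mQTL cohort (methylation + genotypes), an eQTL cohort
(expression + genotypes), a GWAS cohort (complex trait + genotypes) and an
external LD reference panel.  The four cohorts draw *independent* genotypes
from one population model — the two-sample assumption — and every phenotype
is standardized so all effects are in SD/SD units.

LD model: first-order autoregressive latent Gaussian per haplotype,
thresholded at the MAF quantile (a Gaussian copula); two independent
haplotypes per person give dosages in {0,1,2} whose adjacent-variant
correlation decays approximately as ``ld_rho**distance``.

Causal scenarios
----------------
shared
    one variant drives methylation; expression and trait are downstream of
    methylation (effects ``beta_me`` and ``beta_mt``), so all three traits
    share the causal variant — the colocalizing regime.
distinct
    methylation is driven by one variant, expression and the trait by a
    second variant in (weak) LD with the first — association through LD
    between two separate causal variants, the non-colocalizing regime.
null
    no genetic effect on any phenotype.
methylation_only
    an mQTL exists but has no downstream effect (true MR effect 0).
trait_causal
    the trait is genetically driven and methylation is (optionally)
    downstream of the trait via ``beta_tm`` — the reverse-causation regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .records import (
    CpGAnnotation,
    GeneAnnotation,
    ReferencePanel,
    RegionalDataset,
    VariantKey,
)

SCENARIOS = {"shared", "distinct", "null", "methylation_only", "trait_causal"}

_ALLELE_CYCLE = [("G", "A"), ("T", "C"), ("A", "G"), ("C", "T")]

_MIN_P = 5e-324  # smallest subnormal double; keeps p in (0, 1]


@dataclass
class SimulationConfig:
    """Parameters of one simulated cis region.

    Defaults mirror the data regime the pipeline targets: an ARIES-sized
    mQTL cohort (n≈1000), GTEx v7 whole blood (n=369), a 1000-Genomes-EUR
    sized panel (n=503) and a desk-scale GWAS (n=10 000).  Effects are
    SD/SD: ``causal_r2`` is the methylation variance explained by its mQTL,
    ``beta_me``/``beta_mt`` the downstream effects of methylation on
    expression and trait, ``beta_tm`` the reverse trait-on-methylation
    effect used only by scenario ``trait_causal``.
    """

    n_panel: int = 503
    n_mqtl: int = 1000
    n_eqtl: int = 369
    n_gwas: int = 10000
    n_variants: int = 60
    ld_rho: float = 0.9
    maf_range: tuple = (0.1, 0.5)
    scenario: str = "shared"
    causal_r2: float = 0.2
    beta_me: float = 0.6
    beta_mt: float = 0.15
    beta_tm: float = 0.0
    ewas_beta: float = -0.008
    ewas_se: float = 0.002
    seed: int = 0
    chrom: str = "1"
    region_start: int = 1_000_000
    spacing: int = 2_000
    cpg_id: str = "cg00000001"
    gene_id: str = "GENE1"
    trait_id: str = "trait"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (0 < self.causal_r2 < 1):
            raise ValueError("causal_r2 must be in (0,1)")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0,1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for nm in ("n_panel", "n_mqtl", "n_eqtl", "n_gwas"):
            if getattr(self, nm) < 10:
                raise ValueError(f"{nm} must be >= 10")


@dataclass
class Truth:
    """Ground truth of a simulated region, for oracle-based tests."""

    scenario: str
    causal_index_meth: Optional[int]
    causal_index_downstream: Optional[int]
    true_mr_effect: float
    true_reverse_effect: float = 0.0
    panel_r2_between_causals: Optional[float] = None
    background_indices: list = field(default_factory=list)


@dataclass
class SimulatedRegion:
    config: SimulationConfig
    variants: list
    mafs: np.ndarray
    genotypes: dict
    phenotypes: dict
    truth: Truth
    datasets: dict
    panel: ReferencePanel
    cpg: CpGAnnotation
    gene: GeneAnnotation


def make_variant_keys(m, chrom="1", start=1_000_000, spacing=2_000, prefix="rs"):
    """Deterministic variant grid: evenly spaced, non-palindromic allele pairs."""
    keys = []
    for j in range(m):
        ea, oa = _ALLELE_CYCLE[j % len(_ALLELE_CYCLE)]
        keys.append(
            VariantKey(
                id=f"{prefix}{j:05d}", chrom=str(chrom), pos=start + j * spacing,
                effect_allele=ea, other_allele=oa,
            )
        )
    return keys


def _haplotypes(n_hap: int, mafs: np.ndarray, rho: float, rng) -> np.ndarray:
    # Thresholding a latent Gaussian attenuates the correlation of the
    # resulting alleles (phi ~ (2/pi) arcsin(rho_latent) at MAF 0.5), so the
    # latent AR parameter is pre-compensated with the inverse arcsine map to
    # make the *genotype* correlation track ld_rho.
    rho_latent = np.sin(np.pi * rho / 2.0)
    m = len(mafs)
    eps = rng.standard_normal((n_hap, m))
    x = np.empty_like(eps)
    x[:, 0] = eps[:, 0]
    c = np.sqrt(1.0 - rho_latent * rho_latent)
    for j in range(1, m):
        x[:, j] = rho_latent * x[:, j - 1] + c * eps[:, j]
    return (x < stats.norm.ppf(mafs)[None, :]).astype(float)


def genotypes_given_mafs(n: int, mafs: np.ndarray, rho: float, rng) -> np.ndarray:
    """Dosage matrix (n x m) from two independent AR(1)-copula haplotypes."""
    return _haplotypes(n, mafs, rho, rng) + _haplotypes(n, mafs, rho, rng)


def simulate_genotypes(n, m, ld_rho, maf_range, seed):
    """Public one-shot genotype draw: returns (dosages, VariantKey list, mafs)."""
    ss = np.random.SeedSequence(seed)
    rng_maf, rng_geno = (np.random.default_rng(s) for s in ss.spawn(2))
    mafs = rng_maf.uniform(maf_range[0], maf_range[1], size=m)
    G = genotypes_given_mafs(n, mafs, ld_rho, rng_geno)
    return G, make_variant_keys(m), mafs


def _std(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def _mix(signal: np.ndarray, r2: float, rng) -> np.ndarray:
    """signal (unit variance) + noise so the signal explains ``r2``; re-standardized."""
    n = len(signal)
    y = np.sqrt(r2) * signal + np.sqrt(1.0 - r2) * rng.standard_normal(n)
    return _std(y)


def simulate_traits(genotypes: dict, config: SimulationConfig, rng) -> tuple[dict, Truth]:
    """Phenotypes per cohort under the configured causal scenario.

    ``genotypes`` maps cohort name (mqtl/eqtl/gwas) to a dosage matrix on the
    shared variant grid.  Methylation is realized independently in every
    cohort from that cohort's own genotypes (it is a latent mediator in the
    eQTL and GWAS cohorts).
    """
    m = genotypes["mqtl"].shape[1]
    # distinct scenario separates the two causal variants widely enough that
    # their panel r^2 stays low despite the slow arcsine-corrected LD decay
    k1 = m // 6 if config.scenario == "distinct" else m // 2
    k2 = (5 * m) // 6
    c = config

    def meth(G):
        return _mix(_std(G[:, k1]), c.causal_r2, rng)

    pheno: dict = {"mqtl": {}, "eqtl": {}, "gwas": {}}
    if c.scenario == "shared":
        pheno["mqtl"]["methylation"] = meth(genotypes["mqtl"])
        pheno["eqtl"]["expression"] = _mix(
            meth(genotypes["eqtl"]), c.beta_me**2, rng
        ) * np.sign(c.beta_me)
        m_gwas = meth(genotypes["gwas"])
        if c.beta_mt == 0:
            pheno["gwas"]["trait"] = _std(rng.standard_normal(len(m_gwas)))
        else:
            pheno["gwas"]["trait"] = _mix(m_gwas, c.beta_mt**2, rng) * np.sign(c.beta_mt)
        truth = Truth(
            c.scenario, k1, k1 if c.beta_mt != 0 else None, c.beta_mt
        )
    elif c.scenario == "distinct":
        pheno["mqtl"]["methylation"] = meth(genotypes["mqtl"])
        g2e = _std(genotypes["eqtl"][:, k2])
        g2t = _std(genotypes["gwas"][:, k2])
        pheno["eqtl"]["expression"] = _mix(g2e, c.beta_me**2 * c.causal_r2, rng)
        pheno["gwas"]["trait"] = _mix(g2t, c.beta_mt**2 * c.causal_r2, rng)
        truth = Truth(c.scenario, k1, k2, 0.0)
    elif c.scenario == "null":
        for cohort, name in (
            ("mqtl", "methylation"), ("eqtl", "expression"), ("gwas", "trait")
        ):
            pheno[cohort][name] = _std(
                rng.standard_normal(genotypes[cohort].shape[0])
            )
        truth = Truth(c.scenario, None, None, 0.0)
    elif c.scenario == "methylation_only":
        pheno["mqtl"]["methylation"] = meth(genotypes["mqtl"])
        pheno["eqtl"]["expression"] = _std(
            rng.standard_normal(genotypes["eqtl"].shape[0])
        )
        pheno["gwas"]["trait"] = _std(rng.standard_normal(genotypes["gwas"].shape[0]))
        truth = Truth(c.scenario, k1, None, 0.0)
    else:  # trait_causal: reverse causation
        def trait(G):
            return _mix(_std(G[:, k1]), c.causal_r2, rng)

        pheno["gwas"]["trait"] = trait(genotypes["gwas"])
        t_mqtl = trait(genotypes["mqtl"])
        if c.beta_tm == 0:
            pheno["mqtl"]["methylation"] = _std(
                rng.standard_normal(genotypes["mqtl"].shape[0])
            )
        else:
            pheno["mqtl"]["methylation"] = _mix(
                t_mqtl, c.beta_tm**2, rng
            ) * np.sign(c.beta_tm)
        pheno["eqtl"]["expression"] = _std(
            rng.standard_normal(genotypes["eqtl"].shape[0])
        )
        truth = Truth(
            c.scenario, None, k1, 0.0, true_reverse_effect=c.beta_tm
        )
    return pheno, truth


def compute_summary_stats(
    G: np.ndarray, y: np.ndarray, variants, trait_id: str, trait_type: str
) -> RegionalDataset:
    """Per-variant simple linear regression of phenotype on dosage.

    Emits beta, SE, two-sided t-test p, dosage-derived EAF and n for every
    variant.  Monomorphic variants are emitted with missing beta/se (NaN)
    so downstream selection can exclude them.
    """
    import pandas as pd

    n, m = G.shape
    if len(y) != n:
        raise ValueError("phenotype length does not match genotype rows")
    xm = G.mean(axis=0)
    Gc = G - xm
    yc = y - y.mean()
    sxx = (Gc**2).sum(axis=0)
    sxy = Gc.T @ yc
    syy = float((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        sse = syy - beta * sxy
        sigma2 = np.maximum(sse, 0.0) / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    pval = np.clip(pval, _MIN_P, 1.0)
    mono = sxx == 0
    beta[mono] = np.nan
    se[mono] = np.nan
    pval[mono] = np.nan
    table = pd.DataFrame(
        {
            "id": [v.id for v in variants],
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "effect_allele": [v.effect_allele for v in variants],
            "other_allele": [v.other_allele for v in variants],
            "eaf": xm / 2.0,
            "beta": beta,
            "se": se,
            "pvalue": pval,
            "n": n,
        }
    )
    return RegionalDataset(trait_id, trait_type, table)


def simulate_ewas_table(cpg_sites, config: Optional[SimulationConfig] = None,
                        seed: int = 0) -> list[CpGAnnotation]:
    """EWAS annotation rows for a list of ``(cpg_id, chrom, pos)`` triples.

    Effect signs alternate starting negative (both signs are represented for
    two or more CpGs), magnitudes are the configured exposure effect, and
    every row carries FDR < 0.01, emulating the shape of an
    exposure-associated CpG list from a large EWAS.
    """
    c = config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = []
    mag = abs(c.ewas_beta)
    for i, (cpg_id, chrom, pos) in enumerate(cpg_sites):
        sign = -1.0 if i % 2 == 0 else 1.0
        out.append(
            CpGAnnotation(
                cpg_id=str(cpg_id), chrom=str(chrom), pos=int(pos),
                ewas_beta=sign * mag, ewas_se=c.ewas_se,
                ewas_fdr=float(rng.uniform(1e-6, 0.009)),
            )
        )
    return out


def simulate_region(config: SimulationConfig) -> SimulatedRegion:
    """One fully simulated cis region: cohorts, panel, summary statistics.

    All randomness derives from ``config.seed`` through deterministic
    substreams, so a fixed seed gives bit-identical output.
    """
    c = config
    ss = np.random.SeedSequence(c.seed)
    rng_maf, rng_panel, rng_m, rng_e, rng_g, rng_ph = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    mafs = rng_maf.uniform(c.maf_range[0], c.maf_range[1], size=c.n_variants)
    keys = make_variant_keys(
        c.n_variants, chrom=c.chrom, start=c.region_start, spacing=c.spacing
    )
    genotypes = {
        "mqtl": genotypes_given_mafs(c.n_mqtl, mafs, c.ld_rho, rng_m),
        "eqtl": genotypes_given_mafs(c.n_eqtl, mafs, c.ld_rho, rng_e),
        "gwas": genotypes_given_mafs(c.n_gwas, mafs, c.ld_rho, rng_g),
        "panel": genotypes_given_mafs(c.n_panel, mafs, c.ld_rho, rng_panel),
    }
    pheno, truth = simulate_traits(genotypes, c, rng_ph)
    panel = ReferencePanel(genotypes["panel"], keys)
    if c.scenario == "distinct":
        truth.panel_r2_between_causals = panel.r2(
            keys[truth.causal_index_meth].id, keys[truth.causal_index_downstream].id
        )
    datasets = {
        "mqtl": compute_summary_stats(
            genotypes["mqtl"], pheno["mqtl"]["methylation"], keys,
            c.cpg_id, "methylation",
        ),
        "eqtl": compute_summary_stats(
            genotypes["eqtl"], pheno["eqtl"]["expression"], keys,
            c.gene_id, "expression",
        ),
        "gwas": compute_summary_stats(
            genotypes["gwas"], pheno["gwas"]["trait"], keys,
            c.trait_id, "complex",
        ),
    }
    center = keys[c.n_variants // 2].pos + 137
    cpg = CpGAnnotation(
        cpg_id=c.cpg_id, chrom=c.chrom, pos=center,
        ewas_beta=c.ewas_beta, ewas_se=c.ewas_se, ewas_fdr=0.001,
    )
    gene = GeneAnnotation(
        gene_id=c.gene_id, chrom=c.chrom, start=center - 15_000, end=center - 5_000
    )
    return SimulatedRegion(
        config=c, variants=keys, mafs=mafs, genotypes=genotypes,
        phenotypes=pheno, truth=truth, datasets=datasets, panel=panel,
        cpg=cpg, gene=gene,
    )


# ---------------------------------------------------------------------------
# Chain study: one shared cis region plus a polygenic trait background, for
# direction-of-effect (Steiger / reverse MR) testing.
# ---------------------------------------------------------------------------

@dataclass
class ChainStudy:
    config: SimulationConfig
    variants: list
    truth: Truth
    datasets: dict        # mqtl/eqtl/gwas RegionalDatasets (eqtl cis-only)
    panel: ReferencePanel
    cpg: CpGAnnotation
    gene: GeneAnnotation
    cis_ids: list
    background_ids: list


def simulate_chain_study(
    config: SimulationConfig, n_background: int = 30, bg_r2: float = 0.008
) -> ChainStudy:
    """Shared-scenario cis region plus ``n_background`` independent trait loci.

    The background block emulates the rest of the trait's polygenic
    architecture: each background variant directly explains ``bg_r2`` of
    trait variance, lies megabases from the CpG, and has no effect on
    methylation or expression.  These are the loci a reverse-MR analysis
    would draw its trait instruments from.
    """
    c = config
    if c.scenario != "shared":
        raise ValueError("chain studies are defined for scenario='shared'")
    total_bg = n_background * bg_r2
    if c.beta_mt**2 + total_bg >= 1:
        raise ValueError("trait variance components exceed 1")
    ss = np.random.SeedSequence(c.seed)
    rng_maf, rng_panel, rng_m, rng_e, rng_g, rng_ph = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    m = c.n_variants
    mafs_cis = rng_maf.uniform(c.maf_range[0], c.maf_range[1], size=m)
    mafs_bg = rng_maf.uniform(c.maf_range[0], c.maf_range[1], size=n_background)
    keys_cis = make_variant_keys(
        m, chrom=c.chrom, start=c.region_start, spacing=c.spacing, prefix="rs"
    )
    keys_bg = make_variant_keys(
        n_background, chrom=c.chrom, start=200_000_000, spacing=2_000_000,
        prefix="bg",
    )
    keys = keys_cis + keys_bg

    def draw(n, rng):
        cis = genotypes_given_mafs(n, mafs_cis, c.ld_rho, rng)
        bg = genotypes_given_mafs(n, mafs_bg, 0.0, rng)
        return np.hstack([cis, bg])

    G = {
        "mqtl": draw(c.n_mqtl, rng_m),
        "eqtl": draw(c.n_eqtl, rng_e),
        "gwas": draw(c.n_gwas, rng_g),
        "panel": draw(c.n_panel, rng_panel),
    }
    k1 = m // 2

    def meth(Gc):
        return _mix(_std(Gc[:, k1]), c.causal_r2, rng_ph)

    m_mqtl = meth(G["mqtl"])
    expr = _mix(meth(G["eqtl"]), c.beta_me**2, rng_ph) * np.sign(c.beta_me)
    m_gwas = meth(G["gwas"])
    bg_part = np.zeros(c.n_gwas)
    for j in range(n_background):
        bg_part += np.sqrt(bg_r2) * _std(G["gwas"][:, m + j])
    resid = 1.0 - c.beta_mt**2 - total_bg
    trait = _std(
        c.beta_mt * m_gwas + bg_part
        + np.sqrt(resid) * rng_ph.standard_normal(c.n_gwas)
    )
    datasets = {
        "mqtl": compute_summary_stats(G["mqtl"], m_mqtl, keys, c.cpg_id, "methylation"),
        "eqtl": compute_summary_stats(
            G["eqtl"][:, :m], expr, keys_cis, c.gene_id, "expression"
        ),
        "gwas": compute_summary_stats(G["gwas"], trait, keys, c.trait_id, "complex"),
    }
    panel = ReferencePanel(G["panel"], keys)
    truth = Truth(
        "shared", k1, k1 if c.beta_mt != 0 else None, c.beta_mt,
        background_indices=list(range(m, m + n_background)),
    )
    center = keys_cis[k1].pos + 137
    cpg = CpGAnnotation(
        cpg_id=c.cpg_id, chrom=c.chrom, pos=center,
        ewas_beta=c.ewas_beta, ewas_se=c.ewas_se, ewas_fdr=0.001,
    )
    gene = GeneAnnotation(
        gene_id=c.gene_id, chrom=c.chrom, start=center - 15_000, end=center - 5_000
    )
    return ChainStudy(
        config=c, variants=keys, truth=truth, datasets=datasets, panel=panel,
        cpg=cpg, gene=gene,
        cis_ids=[k.id for k in keys_cis],
        background_ids=[k.id for k in keys_bg],
    )
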