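"""Instrument selection (cis filter + conditional stepwise), proxies,
allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epimr.instruments import (
    UninstrumentableCpGError,
    cojo_slct,
    find_proxy,
    harmonize,
    harmonize_pairs,
    select_cis_mqtl,
)
from epimr.mr import wald_ratio
from epimr.records import CpGAnnotation, ReferencePanel, RegionalDataset
from epimr.simulate import (
    SimulationConfig,
    compute_summary_stats,
    genotypes_given_mafs,
    make_variant_keys,
    simulate_region,
)

from conftest import make_record


def dataset_from_rows(rows, trait_id="cpg", trait_type="methylation"):
    return RegionalDataset(trait_id, trait_type, pd.DataFrame(rows))


def row(vid, pos, p, beta=0.5, se=0.05, ea="A", oa="G", eaf=0.3, n=1000):
    return {
        "id": vid, "chrom": "1", "pos": pos, "effect_allele": ea,
        "other_allele": oa, "eaf": eaf, "beta": beta, "se": se,
        "pvalue": p, "n": n,
    }


CPG = CpGAnnotation("cg1", "1", 5_000_000, -0.008, 0.002, 0.001)


class TestSelectCisMqtl:
    def test_cis_and_p_boundaries_are_strict(self):
        ds = dataset_from_rows([
            row("in_window", CPG.pos - 999_999, 5e-8),
            row("out_window", CPG.pos + 1_000_001, 1e-30),
            row("at_threshold", CPG.pos + 10, 1.0e-7),
            row("weak", CPG.pos + 20, 1e-3),
        ])
        got = select_cis_mqtl(ds, CPG)
        assert got.variant_ids == ["in_window"]

    def test_no_candidate_raises(self):
        ds = dataset_from_rows([row("weak", CPG.pos, 1e-3)])
        with pytest.raises(UninstrumentableCpGError):
            select_cis_mqtl(ds, CPG)


def simulate_two_causal(seed, r2_each=0.12, n=4000, m=12, rho=0.0):
    """Methylation with two independent causal variants; returns the pieces
    needed for conditional-selection tests plus an individual-level oracle."""
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(0.2, 0.5, size=m)
    G = genotypes_given_mafs(n, mafs, rho, rng)
    Gp = genotypes_given_mafs(800, mafs, rho, rng)
    keys = make_variant_keys(m, start=4_900_000)
    k1, k2 = 3, 8
    g1 = (G[:, k1] - G[:, k1].mean()) / G[:, k1].std()
    g2 = (G[:, k2] - G[:, k2].mean()) / G[:, k2].std()
    y = np.sqrt(r2_each) * (g1 + g2) + np.sqrt(1 - 2 * r2_each) * \
        rng.standard_normal(n)
    y = (y - y.mean()) / y.std()
    ds = compute_summary_stats(G, y, keys, "cg1", "methylation")
    return ds, ReferencePanel(Gp, keys), keys, (k1, k2), (G, y)


class TestCojoSlct:
    def test_single_causal_no_ld_selects_exactly_that_variant(self):
        reg = simulate_region(SimulationConfig(
            seed=5, ld_rho=0.0, n_variants=10, causal_r2=0.15,
            n_eqtl=10, n_panel=800,
        ))
        cpg = CpGAnnotation("cg1", "1", reg.cpg.pos, -0.008, 0.002, 0.001)
        iset = cojo_slct(reg.datasets["mqtl"], reg.panel, cpg)
        assert len(iset) == 1
        assert iset.records[0].variant.id == \
            reg.variants[reg.truth.causal_index_meth].id

    def test_two_unlinked_causals_both_selected_with_joint_betas(self):
        """Joint effects within 2 SE of the two-variant OLS oracle."""
        import statsmodels.api as sm

        ds, panel, keys, (k1, k2), (G, y) = simulate_two_causal(31)
        cpg = CpGAnnotation("cg1", "1", keys[5].pos, -0.008, 0.002, 0.001)
        iset = cojo_slct(ds, panel, cpg)
        got = {ins[0].variant.id: ins for ins in iset.instruments}
        assert set(got) == {keys[k1].id, keys[k2].id}
        X = sm.add_constant(np.column_stack([G[:, k1], G[:, k2]]))
        fit = sm.OLS(y, X).fit()
        for j, kk in enumerate((k1, k2)):
            _, jb, jse, jp = got[keys[kk].id]
            assert abs(jb - fit.params[j + 1]) < 2 * fit.bse[j + 1]
            assert jp < 1e-7

    def test_shadow_variant_in_high_ld_yields_single_instrument(self):
        """A causal variant plus a shadow at r^2 ~ 0.95 gives one pick."""
        rng = np.random.default_rng(77)
        n, m = 4000, 6
        mafs = np.full(m, 0.3)
        G = genotypes_given_mafs(n, mafs, 0.0, rng)
        # make column 3 a noisy copy of column 2 (high LD shadow)
        flip = rng.random(n) < 0.02
        G[:, 3] = np.where(flip, 2 - G[:, 2], G[:, 2])
        Gp = G[rng.choice(n, 700, replace=False)]
        keys = make_variant_keys(m, start=4_950_000)
        g = (G[:, 2] - G[:, 2].mean()) / G[:, 2].std()
        y = 0.4 * g + np.sqrt(1 - 0.16) * rng.standard_normal(n)
        ds = compute_summary_stats(G, y, keys, "cg1", "methylation")
        panel = ReferencePanel(Gp, keys)
        assert panel.r2(keys[2].id, keys[3].id) > 0.9
        cpg = CpGAnnotation("cg1", "1", keys[2].pos, -0.008, 0.002, 0.001)
        iset = cojo_slct(ds, panel, cpg)
        assert len(iset) == 1
        assert iset.records[0].variant.id in {keys[2].id, keys[3].id}

    def test_invariant_to_input_row_order(self):
        ds, panel, keys, _, _ = simulate_two_causal(55)
        cpg = CpGAnnotation("cg1", "1", keys[5].pos, -0.008, 0.002, 0.001)
        a = cojo_slct(ds, panel, cpg)
        shuffled = RegionalDataset(
            ds.trait_id, ds.trait_type,
            ds.table.sample(frac=1, random_state=1),
        )
        b = cojo_slct(shuffled, panel, cpg)
        assert [r.variant.id for r in a.records] == \
            [r.variant.id for r in b.records]
        assert [i[1:] for i in a.instruments] == [i[1:] for i in b.instruments]

    def test_selected_instrument_tags_the_causal_variant(self):
        """Across seeds the pick is in high LD with the true causal variant."""
        hits = 0
        n_seeds = 15
        for seed in range(n_seeds):
            reg = simulate_region(SimulationConfig(
                seed=seed, n_variants=30, n_mqtl=800, causal_r2=0.15,
                n_eqtl=10, n_gwas=10, n_panel=500,
            ))
            iset = cojo_slct(reg.datasets["mqtl"], reg.panel, reg.cpg)
            causal = reg.variants[reg.truth.causal_index_meth].id
            if any(reg.panel.r2(r.variant.id, causal) >= 0.8
                   for r in iset.records):
                hits += 1
        assert hits >= 0.9 * n_seeds


class TestFindProxy:
    def test_identity_proxy_when_query_present(self, shared_region):
        ds = shared_region.datasets["gwas"]
        q = shared_region.variants[5]
        pr = find_proxy(q, ds, shared_region.panel)
        assert pr.r2 == 1.0 and pr.proxy.id == q.id

    def test_low_ld_returns_none(self, shared_region):
        reg = shared_region
        q = reg.variants[0]
        far_ids = [v.id for v in reg.variants[40:]]
        outcome = reg.datasets["gwas"].subset(far_ids)
        assert find_proxy(q, outcome, reg.panel, r2_threshold=0.8) is None

    def test_mr_estimate_sign_invariant_under_proxy_substitution(self):
        """Running MR through a proxy preserves the causal-effect sign."""
        reg = simulate_region(
            SimulationConfig(seed=19, n_eqtl=10, ld_rho=0.95,
                             maf_range=(0.3, 0.5))
        )
        k = reg.truth.causal_index_meth
        exp = reg.datasets["mqtl"].record(reg.variants[k].id)
        direct = wald_ratio(exp, reg.datasets["gwas"].record(exp.variant.id))
        # hide the instrument from the outcome dataset
        rest = [v.id for v in reg.variants if v.id != exp.variant.id]
        outcome = reg.datasets["gwas"].subset(rest)
        pairs, skipped = harmonize_pairs([exp], outcome, reg.panel)
        assert pairs, f"proxy lookup failed: {skipped}"
        via_proxy = wald_ratio(*pairs[0])
        assert np.sign(via_proxy.beta) == np.sign(direct.beta)
        assert via_proxy.instruments_used[0] != exp.variant.id


class TestHarmonize:
    def test_swapped_alleles_negate_outcome_beta(self):
        exp = make_record(beta=0.5, ea="A", oa="G")
        out = make_record(beta=0.2, ea="G", oa="A", eaf=0.7)
        _, aligned, reason = harmonize(exp, out)
        assert aligned.beta == -0.2
        assert aligned.eaf == pytest.approx(0.3)
        assert aligned.variant.effect_allele == "A"

    def test_ambiguous_palindrome_is_dropped(self):
        exp = make_record(ea="A", oa="T", eaf=0.50)
        out = make_record(ea="A", oa="T", eaf=0.50)
        e, o, reason = harmonize(exp, out)
        assert e is None and reason == "palindromic_ambiguous_eaf"

    def test_palindrome_missing_eaf_is_dropped(self):
        exp = make_record(ea="C", oa="G", eaf=None)
        out = make_record(ea="C", oa="G", eaf=0.2)
        assert harmonize(exp, out)[2] == "palindromic_missing_eaf"

    def test_informative_palindrome_oriented_by_frequency(self):
        exp = make_record(beta=0.5, ea="A", oa="T", eaf=0.2)
        disc = make_record(beta=0.2, ea="A", oa="T", eaf=0.8)
        _, aligned, _ = harmonize(exp, disc)
        assert aligned.beta == -0.2  # discordant frequency implies a flip

    def test_strand_flip_resolved_by_complementing(self):
        exp = make_record(beta=0.5, ea="A", oa="G")
        out = make_record(beta=0.2, ea="T", oa="C", eaf=0.3)
        _, aligned, _ = harmonize(exp, out)
        assert aligned.beta == 0.2
        assert aligned.variant.effect_allele == "A"

    def test_irreconcilable_alleles_dropped_with_reason(self):
        exp = make_record(ea="A", oa="G")
        out = make_record(ea="A", oa="C")
        assert harmonize(exp, out)[2] == "incompatible_alleles"

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        beta=st.floats(-1, 1, allow_nan=False),
        eaf=st.floats(0.05, 0.95),
        orient=st.sampled_from(["same", "swap", "flip", "flipswap"]),
    )
    def test_harmonize_is_idempotent(self, beta, eaf, orient):
        exp = make_record(beta=0.4, ea="A", oa="G", eaf=0.3)
        ea, oa, b, f = {
            "same": ("A", "G", beta, eaf),
            "swap": ("G", "A", beta, eaf),
            "flip": ("T", "C", beta, eaf),
            "flipswap": ("C", "T", beta, eaf),
        }[orient]
        out = make_record(beta=b, ea=ea, oa=oa, eaf=f)
        _, once, _ = harmonize(exp, out)
        _, twice, _ = harmonize(exp, once)
        assert twice == once

    def test_mr_invariant_under_global_allele_label_swap(self, shared_region):
        """Swapping every allele label (and negating betas) in the outcome
        file leaves the MR estimate unchanged."""
        reg = shared_region
        k = reg.truth.causal_index_meth
        exp = reg.datasets["mqtl"].record(reg.variants[k].id)
        out = reg.datasets["gwas"].record(exp.variant.id)
        swapped = out.flipped()
        r1 = wald_ratio(*harmonize(exp, out)[:2])
        r2 = wald_ratio(*harmonize(exp, swapped)[:2])
        assert r1.beta == pytest.approx(r2.beta, abs=1e-12)
        assert r1.se == pytest.approx(r2.se, abs=1e-12)
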