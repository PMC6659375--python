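"""Colocalization: Wakefield ABFs, configuration enumeration, evidence
against a brute-force oracle, posteriors, window scan, trait selection."""

import math

import numpy as np
import pandas as pd
import pytest

from epimr.coloc import (
    ABFSet,
    MolocModel,
    config_evidence,
    enumerate_configurations,
    gene_window_scan,
    moloc_posteriors,
    select_top_trait,
    wakefield_abf,
)
from epimr.records import GeneAnnotation
from epimr.simulate import SimulationConfig, simulate_region


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def brute_force_classes(n):
    """Independent enumeration: all maps trait -> {none} U group labels,
    canonicalized as a set of frozensets."""
    from itertools import product

    seen = set()
    for labels in product(range(-1, n), repeat=n):
        groups = {}
        for trait, lab in enumerate(labels):
            if lab >= 0:
                groups.setdefault(lab, set()).add(trait)
        seen.add(frozenset(frozenset(g) for g in groups.values()))
    return seen


def naive_log_evidence(labfs, groups):
    """Exhaustive loops over distinct-variant assignments (log of sum)."""
    m = len(labfs[0])
    t = [sum(labfs[i] for i in g) for g in groups]
    total = 0.0
    if len(groups) == 0:
        return 0.0
    if len(groups) == 1:
        total = sum(math.exp(t[0][v]) for v in range(m))
    elif len(groups) == 2:
        for v in range(m):
            for w in range(m):
                if v != w:
                    total += math.exp(t[0][v] + t[1][w])
    else:
        for v in range(m):
            for w in range(m):
                for u in range(m):
                    if len({v, w, u}) == 3:
                        total += math.exp(t[0][v] + t[1][w] + t[2][u])
    return math.log(total) if total > 0 else -math.inf


def random_abfsets(m, seed, scale=2.0):
    rng = np.random.default_rng(seed)
    ids = [f"v{j}" for j in range(m)]
    return [
        ABFSet(t, ids, rng.normal(0.0, scale, size=m))
        for t in ("meth", "expr", "trait")
    ]


class TestWakefield:
    def test_balanced_null_value(self):
        """z=0 with V = prior_w gives 0.5*log(0.5)."""
        assert wakefield_abf(0.0, 0.2, prior_w=0.04) == \
            pytest.approx(0.5 * np.log(0.5))

    def test_monotone_in_abs_z(self):
        se = 0.05
        zs = np.array([0.0, 0.5, 1.0, 2.0, 5.0, 10.0])
        vals = wakefield_abf(zs * se, np.full_like(zs, se))
        assert np.all(np.diff(vals) > 0)
        assert wakefield_abf(-0.5, 0.05) == wakefield_abf(0.5, 0.05)

    def test_vanishing_prior_limit(self):
        for z in (0.0, 3.0, 30.0):
            assert abs(wakefield_abf(z * 0.05, 0.05, prior_w=1e-12)) < 1e-6


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(1, 2), (2, 5), (3, 15)])
    def test_class_counts_match_brute_force(self, n, count):
        got = enumerate_configurations(n)
        assert len(got) == count
        oracle = brute_force_classes(n)
        assert len(oracle) == count
        assert {frozenset(c.groups) for c in got} == oracle

    def test_three_trait_labels(self):
        labels = {c.label for c in enumerate_configurations(3)}
        assert {"null", "a", "b", "c", "ab", "ac", "bc", "abc",
                "a.b", "a.c", "b.c", "ab.c", "ac.b", "a.bc", "a.b.c"} == labels

    def test_more_than_three_traits_unsupported(self):
        with pytest.raises(ValueError):
            enumerate_configurations(4)


class TestEvidence:
    @pytest.mark.parametrize("m", [2, 3, 4, 5, 6])
    def test_matches_naive_loops_for_small_regions(self, m):
        """All 15 class log-evidences agree with exhaustive loops to 1e-9."""
        sets = random_abfsets(m, seed=m)
        labfs = [s.labf for s in sets]
        for cfg in enumerate_configurations(3):
            got = config_evidence(sets, cfg)
            want = naive_log_evidence(labfs, cfg.groups)
            if math.isinf(want):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(want, abs=1e-9)

    def test_single_variant_region_multigroup_impossible(self):
        sets = random_abfsets(1, seed=3)
        for cfg in enumerate_configurations(3):
            ev = config_evidence(sets, cfg)
            if cfg.n_groups >= 2:
                assert ev == -np.inf
            elif cfg.n_groups == 0:
                assert ev == 0.0  # null class evidence is exactly 1
            else:
                assert np.isfinite(ev)

    def test_permutation_invariance_in_variant_order(self):
        sets = random_abfsets(6, seed=9)
        perm = np.random.default_rng(0).permutation(6)
        permuted = [
            ABFSet(s.trait_id, [s.variant_ids[j] for j in perm], s.labf[perm])
            for s in sets
        ]
        for cfg in enumerate_configurations(3):
            assert config_evidence(sets, cfg) == \
                pytest.approx(config_evidence(permuted, cfg), abs=1e-10)


class TestPosteriors:
    def test_flat_data_favors_null(self):
        ids = [f"v{j}" for j in range(200)]
        sets = [
            ABFSet(t, ids, np.full(200, wakefield_abf(0.0, 0.01)))
            for t in ("a", "b", "c")
        ]
        post = moloc_posteriors(sets)
        assert post.class_posteriors["null"] > 0.99

    def test_posteriors_sum_to_one(self):
        for seed in range(5):
            post = moloc_posteriors(random_abfsets(8, seed))
            assert sum(post.class_posteriors.values()) == \
                pytest.approx(1.0, abs=1e-10)
            assert len(post.class_posteriors) == 15

    def test_trait_label_equivariance(self):
        """Relabelling a<->b swaps the corresponding class posteriors."""
        a, b, c = random_abfsets(7, seed=4)
        p1 = moloc_posteriors([a, b, c]).class_posteriors
        p2 = moloc_posteriors([b, a, c]).class_posteriors
        swap = {"a": "b", "b": "a", "ac": "bc", "bc": "ac",
                "a.c": "b.c", "b.c": "a.c", "a.b": "a.b", "ab": "ab",
                "ab.c": "ab.c", "ac.b": "a.bc", "a.bc": "ac.b",
                "a.b.c": "a.b.c", "abc": "abc", "c": "c", "null": "null"}
        for lab, val in p1.items():
            assert val == pytest.approx(p2[swap[lab]], abs=1e-12)

    def test_shared_region_colocalizes(self, shared_region):
        reg = shared_region
        post = MolocModel.from_datasets(
            [reg.datasets["mqtl"], reg.datasets["eqtl"], reg.datasets["gwas"]]
        ).fit()
        assert post.ppa_abc >= 0.8
        assert post.best_shared_variant == \
            reg.variants[reg.truth.causal_index_meth].id
        assert "abc" in post.summary()


class TestGeneWindowScan:
    @pytest.fixture(scope="class")
    def region(self):
        return simulate_region(SimulationConfig(seed=17))

    def run_scan(self, reg, genes, **kw):
        return gene_window_scan(
            reg.cpg, reg.datasets["mqtl"], reg.datasets["gwas"],
            {g.gene_id: reg.datasets["eqtl"] for g in genes}, genes,
            reg.panel, **kw,
        )

    def test_window_rule_99kb_in_101kb_out(self, region):
        near = GeneAnnotation("near", "1", region.cpg.pos + 99_000,
                              region.cpg.pos + 99_500)
        far = GeneAnnotation("far", "1", region.cpg.pos + 101_000,
                             region.cpg.pos + 102_000)
        res = self.run_scan(region, [near, far]).set_index("gene_id")
        assert res.loc["near", "skip_reason"] == ""
        assert res.loc["near", "ppa_abc"] >= 0.8
        assert res.loc["far", "skip_reason"] == "outside_window"

    def test_min_variant_rule_49_is_too_few(self, region):
        gene = GeneAnnotation("g", "1", region.cpg.pos - 10_000,
                              region.cpg.pos - 5_000)
        keep = [v.id for v in region.variants[:49]]
        sub = {
            "g": region.datasets["eqtl"].subset(keep)
        }
        res = gene_window_scan(
            region.cpg, region.datasets["mqtl"], region.datasets["gwas"],
            sub, [gene], region.panel,
        )
        assert res.loc[0, "skip_reason"] == "min_variants"
        assert res.loc[0, "n_variants"] == 49

    def test_low_maf_variants_are_excluded(self, region):
        """A variant at panel MAF 4.9% drops out of the intersection."""
        gene = GeneAnnotation("g", "1", region.cpg.pos - 10_000,
                              region.cpg.pos - 5_000)
        panel = region.panel
        j = 0
        n = panel.dosages.shape[0]
        k = max(1, int(round(0.049 * 2 * n)))
        panel.dosages[:, j] = 0.0
        panel.dosages[:k // 2 + k % 2, j] = 1.0
        if k >= 2:
            panel.dosages[0, j] = 2.0 if k % 2 == 0 else panel.dosages[0, j]
        dropped_id = panel.variants[j].id
        assert panel.maf(dropped_id) < 0.05
        res = self.run_scan(region, [gene])
        assert res.loc[0, "n_variants"] == len(region.variants) - 1
        assert res.loc[0, "skip_reason"] == ""


class TestSelectTopTrait:
    def make(self, rows):
        return pd.DataFrame(
            rows, columns=["cpg_id", "trait_id", "gene_id", "ppa_abc",
                           "mr_pvalue"],
        )

    def test_argmax_ppa(self):
        df = self.make([
            ("cg1", "fev1", "g", 0.95, 1e-10),
            ("cg1", "height", "g", 0.22, 1e-20),
        ])
        top = select_top_trait(df)
        assert list(top["trait_id"]) == ["fev1"]

    def test_tie_breaks_on_smaller_mr_p_then_trait_id(self):
        df = self.make([
            ("cg1", "b_trait", "g", 0.9, 1e-8),
            ("cg1", "a_trait", "g", 0.9, 1e-12),
        ])
        assert list(select_top_trait(df)["trait_id"]) == ["a_trait"]
        df2 = self.make([
            ("cg1", "b_trait", "g", 0.9, 1e-8),
            ("cg1", "a_trait", "g", 0.9, 1e-8),
        ])
        assert list(select_top_trait(df2)["trait_id"]) == ["a_trait"]

    def test_single_trait_is_itself(self):
        df = self.make([("cg1", "only", "g", 0.5, 1e-9)])
        assert list(select_top_trait(df)["trait_id"]) == ["only"]
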