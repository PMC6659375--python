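"""Multiple-trait (three-way) Bayesian colocalization over a cis region.

Per-variant evidence uses Wakefield's asymptotic Bayes factor: with
z = beta/se, V = se^2 and prior effect-size variance W,

    lABF = 0.5 * [ log(1 - r) + z^2 * r ],   r = W / (V + W).

For traits a (methylation), b (expression) and c (complex trait) every
*configuration class* assigns each trait to "unassociated" or to a causal-
variant group, where a group of associated traits shares one causal variant
and distinct groups have distinct variants; three traits yield exactly 15
classes (null, a, b, c, ab, ac, bc, a.b, a.c, b.c, abc, ab.c, ac.b, bc.a,
a.b.c).  Class evidence sums, over all admissible assignments of distinct
variants to groups, the product of group-summed ABFs; all accumulation is
in log space with signed log-sum-exp (the inclusion-exclusion terms for
multi-group classes subtract same-variant collisions).

Posteriors weight each class by per-variant priors p1 (one trait), p2 (two
traits sharing) and p3 (all three sharing); PPA_abc is the posterior of the
single class in which one variant is causal for all three traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .records import ReferencePanel, RegionalDataset

TRAIT_LETTERS = "abc"

DEFAULT_PRIORS = (1e-4, 1e-6, 1e-7)   # p1, p2, p3 per variant
DEFAULT_PRIOR_W = 0.04                # SD 0.2 prior on standardized effects

GENE_WINDOW = 100_000
MIN_VARIANTS = 50
MIN_MAF = 0.05
PPA_THRESHOLD = 0.8


def wakefield_abf(beta, se, prior_w: float = DEFAULT_PRIOR_W):
    """Log approximate Bayes factor (alternative vs null) for beta/se pairs.

    Vectorized over array inputs.  ``prior_w`` is the prior variance of the
    true effect; as it vanishes the lABF tends to 0 for any z.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if prior_w < 0:
        raise ValueError("prior_w must be >= 0")
    z2 = (beta / se) ** 2
    V = se**2
    r = prior_w / (V + prior_w)
    out = 0.5 * (np.log1p(-r) + z2 * r)
    return out if out.ndim else float(out)


@dataclass
class ABFSet:
    """Per-variant log ABFs for one trait on a shared variant grid."""

    trait_id: str
    variant_ids: list
    labf: np.ndarray

    def __post_init__(self) -> None:
        self.labf = np.asarray(self.labf, dtype=float)
        if len(self.labf) != len(self.variant_ids):
            raise ValueError("lABF length does not match variant grid")
        if not np.all(np.isfinite(self.labf)):
            raise ValueError("lABFs must be finite")

    @classmethod
    def from_dataset(
        cls, dataset: RegionalDataset, prior_w: float = DEFAULT_PRIOR_W
    ) -> "ABFSet":
        t = dataset.table
        ok = t["beta"].notna() & t["se"].notna()
        t = t[ok]
        return cls(
            trait_id=dataset.trait_id,
            variant_ids=list(t["id"]),
            labf=wakefield_abf(t["beta"].to_numpy(), t["se"].to_numpy(), prior_w),
        )

    def subset(self, variant_ids) -> "ABFSet":
        index = {v: i for i, v in enumerate(self.variant_ids)}
        idx = [index[v] for v in variant_ids]
        return ABFSet(self.trait_id, list(variant_ids), self.labf[idx])


@dataclass(frozen=True)
class ConfigurationClass:
    """One sharing pattern: which traits are associated, grouped by variant."""

    label: str
    groups: tuple            # tuple of frozensets of trait indices

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def _partitions(items: tuple):
    """All set partitions of ``items`` (brute force; n <= 3 in practice)."""
    if not items:
        yield ()
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        # first in its own block
        yield (frozenset({first}),) + part
        # first joined to each existing block
        for i, block in enumerate(part):
            yield part[:i] + (block | {first},) + part[i + 1:]


def _label(groups) -> str:
    if not groups:
        return "null"
    parts = sorted("".join(sorted(TRAIT_LETTERS[i] for i in g)) for g in groups)
    return ".".join(parts)


def enumerate_configurations(n_traits: int) -> list[ConfigurationClass]:
    """All configuration classes for 1-3 traits (2, 5 and 15 classes)."""
    if n_traits not in (1, 2, 3):
        raise ValueError("only 1-3 traits supported")
    traits = tuple(range(n_traits))
    seen = {}
    for k in range(n_traits + 1):
        for assoc in combinations(traits, k):
            for part in _partitions(assoc):
                groups = tuple(sorted(part, key=lambda g: min(g)))
                lab = _label(groups)
                if lab not in seen:
                    seen[lab] = ConfigurationClass(label=lab, groups=groups)
    return sorted(seen.values(), key=lambda c: (c.n_groups, c.label))


def _signed_lse(terms) -> float:
    """log of a signed sum given (log magnitude, sign) terms; -inf if <= 0."""
    vals = np.array([t[0] for t in terms])
    signs = np.array([t[1] for t in terms], dtype=float)
    finite = np.isfinite(vals)
    if not finite.any():
        return -np.inf
    total, sign = logsumexp(vals[finite], b=signs[finite], return_sign=True)
    if sign <= 0:
        return -np.inf
    # combinatorially-impossible classes cancel exactly in real arithmetic;
    # treat a residual below ~1e-12 of the leading term as zero
    if total - float(np.max(vals[finite])) < np.log(1e-12):
        return -np.inf
    return float(total)


def config_evidence(abfsets: list, config: ConfigurationClass) -> float:
    """Log marginal evidence of one configuration class.

    ``abfsets`` must share one variant grid.  The null class has evidence 1
    (log 0); classes requiring more distinct variants than the region holds
    get -inf.
    """
    grids = {tuple(s.variant_ids) for s in abfsets}
    if len(grids) != 1:
        raise ValueError("ABF sets must be aligned to one variant grid")
    if config.n_groups == 0:
        return 0.0
    t = [
        np.sum([abfsets[i].labf for i in g], axis=0) for g in config.groups
    ]
    S = [logsumexp(x) for x in t]
    if config.n_groups == 1:
        return float(S[0])
    if config.n_groups == 2:
        c12 = logsumexp(t[0] + t[1])
        return _signed_lse([(S[0] + S[1], +1.0), (c12, -1.0)])
    # three singleton groups
    c01 = logsumexp(t[0] + t[1])
    c02 = logsumexp(t[0] + t[2])
    c12 = logsumexp(t[1] + t[2])
    c012 = logsumexp(t[0] + t[1] + t[2])
    return _signed_lse(
        [
            (S[0] + S[1] + S[2], +1.0),
            (S[0] + c12, -1.0),
            (S[1] + c02, -1.0),
            (S[2] + c01, -1.0),
            (np.log(2.0) + c012, +1.0),
        ]
    )


@dataclass
class ColocPosterior:
    """Posterior over all configuration classes for one region."""

    class_posteriors: dict           # label -> posterior probability
    ppa_abc: float
    best_shared_variant: Optional[str]
    n_variants: int
    trait_ids: tuple = ()

    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        rows = [
            [lab, f"{p:.4f}"]
            for lab, p in sorted(
                self.class_posteriors.items(), key=lambda kv: -kv[1]
            )
        ]
        rows.append(["PPA_abc", f"{self.ppa_abc:.4f}"])
        rows.append(["best shared variant", str(self.best_shared_variant)])
        rows.append(["n variants", str(self.n_variants)])
        return str(
            SimpleTable(rows, title="Multiple-trait colocalization posterior")
        )


def moloc_posteriors(
    abfsets: list,
    priors: tuple = DEFAULT_PRIORS,
    configurations: Optional[list] = None,
) -> ColocPosterior:
    """Posterior probabilities over all configuration classes.

    Each class is weighted by the product, over its groups, of the
    per-variant prior for the group size (p1 singleton, p2 pair, p3
    triple); the evidence sums already run over variant assignments.  If
    every non-null evidence is -inf the posterior mass falls on the null
    class.
    """
    n_traits = len(abfsets)
    configs = configurations or enumerate_configurations(n_traits)
    logp = np.log(np.asarray(priors[:n_traits], dtype=float))
    log_unnorm = {}
    for cfg in configs:
        prior_term = sum(logp[len(g) - 1] for g in cfg.groups)
        log_unnorm[cfg.label] = prior_term + config_evidence(abfsets, cfg)
    labels = list(log_unnorm)
    vals = np.array([log_unnorm[lab] for lab in labels])
    denom = logsumexp(vals[np.isfinite(vals)])
    post = {
        lab: (float(np.exp(v - denom)) if np.isfinite(v) else 0.0)
        for lab, v in zip(labels, vals)
    }
    full_label = _label((frozenset(range(n_traits)),))
    ppa = post.get(full_label, 0.0)
    total = np.sum([s.labf for s in abfsets], axis=0)
    best = abfsets[0].variant_ids[int(np.argmax(total))] if len(total) else None
    return ColocPosterior(
        class_posteriors=post, ppa_abc=ppa, best_shared_variant=best,
        n_variants=len(abfsets[0].variant_ids),
        trait_ids=tuple(s.trait_id for s in abfsets),
    )


class MolocModel:
    """Model object for three-trait colocalization on aligned summary data.

    Built from the three regional datasets (methylation, expression,
    complex trait); ``fit()`` intersects the grids and returns a
    :class:`ColocPosterior`.
    """

    def __init__(self, abfsets, priors=DEFAULT_PRIORS):
        self.abfsets = list(abfsets)
        self.priors = priors

    @classmethod
    def from_datasets(
        cls,
        datasets: list,
        prior_w: float = DEFAULT_PRIOR_W,
        priors: tuple = DEFAULT_PRIORS,
        variant_ids: Optional[list] = None,
    ) -> "MolocModel":
        sets = [ABFSet.from_dataset(d, prior_w) for d in datasets]
        if variant_ids is None:
            common = set(sets[0].variant_ids)
            for s in sets[1:]:
                common &= set(s.variant_ids)
            variant_ids = [v for v in sets[0].variant_ids if v in common]
        return cls([s.subset(variant_ids) for s in sets], priors)

    def fit(self) -> ColocPosterior:
        return moloc_posteriors(self.abfsets, self.priors)


def gene_window_scan(
    cpg,
    mqtl: RegionalDataset,
    gwas: RegionalDataset,
    eqtl_catalog: dict,
    genes: list,
    panel: ReferencePanel,
    window: int = GENE_WINDOW,
    min_variants: int = MIN_VARIANTS,
    min_maf: float = MIN_MAF,
    prior_w: float = DEFAULT_PRIOR_W,
    priors: tuple = DEFAULT_PRIORS,
) -> pd.DataFrame:
    """Colocalization for every gene within ``window`` bp of the CpG.

    Distance is measured from the CpG position to the nearest edge of the
    annotated gene interval.  For each gene the three variant grids are
    intersected with the panel, variants with panel MAF below ``min_maf``
    are dropped, and moloc runs only if at least ``min_variants`` remain;
    skipped genes carry a reason.  Because lABFs depend on z^2 only, no
    allele harmonization is required here.
    """
    rows = []
    panel_ids = {v.id for v in panel.variants}
    for gene in genes:
        row = {
            "cpg_id": cpg.cpg_id, "gene_id": gene.gene_id,
            "trait_id": gwas.trait_id, "n_variants": 0,
            "ppa_abc": np.nan, "best_shared_variant": None,
            "skip_reason": "", "posterior": None,
        }
        if gene.chrom != cpg.chrom or gene.distance_to(cpg.pos) > window:
            row["skip_reason"] = "outside_window"
            rows.append(row)
            continue
        eqtl = eqtl_catalog.get(gene.gene_id)
        if eqtl is None:
            row["skip_reason"] = "no_eqtl_data"
            rows.append(row)
            continue
        sets = [
            ABFSet.from_dataset(d, prior_w) for d in (mqtl, eqtl, gwas)
        ]
        common = set(sets[0].variant_ids) & set(sets[1].variant_ids) \
            & set(sets[2].variant_ids) & panel_ids
        ids = [
            v for v in sets[0].variant_ids
            if v in common and panel.maf(v) >= min_maf
        ]
        if len(ids) < min_variants:
            row["skip_reason"] = "min_variants"
            row["n_variants"] = len(ids)
            rows.append(row)
            continue
        post = moloc_posteriors([s.subset(ids) for s in sets], priors)
        row.update(
            n_variants=len(ids), ppa_abc=post.ppa_abc,
            best_shared_variant=post.best_shared_variant, posterior=post,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def select_top_trait(results: pd.DataFrame) -> pd.DataFrame:
    """Keep, per CpG, the trait (and gene) with the highest PPA_abc.

    Ties break on the smaller MR p-value (``mr_pvalue`` column, if present)
    and then lexicographic trait id.
    """
    df = results.copy()
    if "mr_pvalue" not in df.columns:
        df["mr_pvalue"] = np.nan
    df = df[df["ppa_abc"].notna()]
    if df.empty:
        return df
    df = df.sort_values(
        ["cpg_id", "ppa_abc", "mr_pvalue", "trait_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
        na_position="last",
    )
    return df.groupby("cpg_id", as_index=False).head(1).reset_index(drop=True)
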