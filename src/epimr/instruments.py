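"""cis-mQTL instrument selection, LD proxies and allele harmonization.

Instruments are conditionally independent cis-mQTLs: variants within 1 Mb of
the CpG with marginal P strictly below 1e-7, thinned to a conditionally
independent set by a stepwise conditional-and-joint (COJO-style) selection
reimplemented from summary statistics plus a reference-panel LD matrix.
Only cis instruments are ever returned — trans-mQTLs are excluded outright
as they are more prone to horizontal pleiotropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .records import (
    AssociationRecord,
    ReferencePanel,
    RegionalDataset,
    CpGAnnotation,
    VariantKey,
    COMPLEMENT,
)

logger = logging.getLogger(__name__)

CIS_WINDOW = 1_000_000          # bp, "cis" means closer than this to the CpG
MQTL_P_THRESHOLD = 1e-7         # strict inequality
COLLINEARITY_R2 = 0.9           # between selected instruments
PROXY_R2_THRESHOLD = 0.8        # strict inequality
PROXY_SEARCH_WINDOW = 500_000   # bp either side of the query
PALINDROME_EAF_WINDOW = (0.42, 0.58)


class UninstrumentableCpGError(ValueError):
    """No cis-mQTL passes the selection threshold for this CpG."""


@dataclass
class InstrumentSet:
    """Conditionally independent cis-mQTLs instrumenting one CpG."""

    cpg_id: str
    instruments: list          # of (AssociationRecord, joint_beta, joint_se, joint_p)
    window: tuple              # (chrom, start, end) cis interval used

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def records(self) -> list:
        return [ins[0] for ins in self.instruments]


@dataclass(frozen=True)
class ProxyResult:
    query: VariantKey
    proxy: VariantKey
    r2: float
    allele_map: dict           # query allele -> proxy allele


def select_cis_mqtl(
    mqtl: RegionalDataset,
    cpg: CpGAnnotation,
    p_threshold: float = MQTL_P_THRESHOLD,
    cis_window: int = CIS_WINDOW,
) -> RegionalDataset:
    """Candidate instruments: cis (|pos - cpg| < window) and P < threshold.

    Both inequalities are strict.  Raises
    :class:`UninstrumentableCpGError` when nothing qualifies.
    """
    t = mqtl.table
    if not (t["chrom"] == cpg.chrom).all():
        raise ValueError("mQTL dataset and CpG are on different chromosomes")
    keep = (
        t["beta"].notna()
        & (t["pvalue"] < p_threshold)
        & ((t["pos"] - cpg.pos).abs() < cis_window)
    )
    if not keep.any():
        raise UninstrumentableCpGError(
            f"{cpg.cpg_id}: no cis-mQTL with P < {p_threshold:g}"
        )
    return RegionalDataset(mqtl.trait_id, mqtl.trait_type, t[keep])


def _joint_fit(
    betas: np.ndarray, freqs: np.ndarray, ns: np.ndarray, R: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Multivariate least-squares approximation from marginal summary stats.

    Genotype variances are 2f(1-f) (Hardy-Weinberg), phenotypic variance is
    1 (standardized traits), so with D = diag(2f(1-f)) and panel LD R the
    joint coefficients solve  (D^0.5 R D^0.5) b = D beta_marginal, with
    covariance sigma^2 (D^0.5 R D^0.5)^-1 / n and sigma^2 = 1.
    """
    d = 2.0 * freqs * (1.0 - freqs)
    sd = np.sqrt(d)
    B = sd[:, None] * R * sd[None, :]
    rhs = d * betas
    b = np.linalg.solve(B, rhs)
    n_eff = float(np.median(ns))
    cov = np.linalg.inv(B) / n_eff
    se = np.sqrt(np.diag(cov))
    return b, se


def cojo_slct(
    mqtl: RegionalDataset,
    panel: ReferencePanel,
    cpg: CpGAnnotation,
    p_threshold: float = MQTL_P_THRESHOLD,
    cis_window: int = CIS_WINDOW,
    collinearity_r2: float = COLLINEARITY_R2,
) -> InstrumentSet:
    """Forward stepwise conditional selection of independent cis-mQTLs.

    Seeds with the smallest marginal p; at each step refits the joint model
    of current picks plus each remaining candidate via the summary-statistic
    approximation, and adds the candidate with the smallest joint p provided
    that p is below ``p_threshold`` and its panel r^2 with every selected
    variant is below ``collinearity_r2``.  Stops when no candidate
    qualifies.  Output is invariant to input row order (deterministic
    tie-breaks on p, position, id).
    """
    cand = select_cis_mqtl(mqtl, cpg, p_threshold, cis_window)
    rows = cand.table[cand.table["id"].isin(
        [v.id for v in panel.variants]
    )].copy()
    if rows.empty:
        raise UninstrumentableCpGError(
            f"{cpg.cpg_id}: no candidate present in the reference panel"
        )
    rows = rows.sort_values(
        ["pvalue", "pos", "id"], kind="mergesort"
    ).reset_index(drop=True)
    ids = list(rows["id"])
    betas = rows["beta"].to_numpy()
    freqs = rows["eaf"].to_numpy()
    if np.isnan(freqs).any():
        # fall back to panel frequencies when the table omits EAF
        freqs = np.array([panel.eaf(v) for v in ids])
    ns = rows["n"].to_numpy(dtype=float)
    R = panel.ld_matrix(ids)

    selected = [0]
    dropped: set[int] = set()
    while True:
        best: Optional[tuple] = None
        for j in range(len(ids)):
            if j in selected or j in dropped:
                continue
            if max(R[j, s] ** 2 for s in selected) >= collinearity_r2:
                continue
            trial = selected + [j]
            sub = np.ix_(trial, trial)
            try:
                b, se = _joint_fit(betas[trial], freqs[trial], ns[trial], R[sub])
            except np.linalg.LinAlgError:
                logger.warning(
                    "cojo_slct: singular LD submatrix, dropping %s", ids[j]
                )
                dropped.add(j)
                continue
            if not np.all(np.isfinite(se)) or np.any(se <= 0):
                dropped.add(j)
                continue
            p_new = _norm_p(b[-1] / se[-1])
            if best is None or p_new < best[0]:
                best = (p_new, j)
        if best is None or best[0] >= p_threshold:
            break
        selected.append(best[1])

    sub = np.ix_(selected, selected)
    b, se = _joint_fit(betas[selected], freqs[selected], ns[selected], R[sub])
    joint_p = _norm_p(b / se)
    order = np.argsort([rows.loc[i, "pos"] for i in selected], kind="stable")
    instruments = []
    for o in order:
        i = selected[o]
        rec = _row_record(rows.loc[i])
        instruments.append((rec, float(b[o]), float(se[o]), float(joint_p[o])))
    return InstrumentSet(
        cpg_id=cpg.cpg_id,
        instruments=instruments,
        window=(cpg.chrom, cpg.pos - cis_window, cpg.pos + cis_window),
    )


def _norm_p(z):
    return np.clip(2.0 * stats.norm.sf(np.abs(z)), 5e-324, 1.0)


def _row_record(row) -> AssociationRecord:
    return AssociationRecord(
        variant=VariantKey(
            id=str(row["id"]), chrom=str(row["chrom"]), pos=int(row["pos"]),
            effect_allele=str(row["effect_allele"]),
            other_allele=str(row["other_allele"]),
        ),
        beta=float(row["beta"]), se=float(row["se"]),
        pvalue=float(row["pvalue"]),
        eaf=None if np.isnan(row["eaf"]) else float(row["eaf"]),
        n=None if np.isnan(row["n"]) else int(row["n"]),
    )


def find_proxy(
    query: VariantKey,
    outcome: RegionalDataset,
    panel: ReferencePanel,
    r2_threshold: float = PROXY_R2_THRESHOLD,
    search_window: int = PROXY_SEARCH_WINDOW,
) -> Optional[ProxyResult]:
    """Best LD proxy for an instrument absent from the outcome dataset.

    If the query itself is present, returns the identity proxy (r2 = 1).
    Otherwise scans outcome variants within ``search_window`` bp that are
    also in the panel and returns the one with the highest panel r^2 to the
    query, provided r^2 strictly exceeds the threshold.  The allele map
    follows the sign of the dosage correlation: a negative correlation pairs
    the query's effect allele with the proxy's *other* allele, so the
    harmonized effect direction is invariant to which variant is used.
    """
    if query.id in outcome:
        return ProxyResult(
            query=query, proxy=outcome.record(query.id).variant, r2=1.0,
            allele_map={
                query.effect_allele: query.effect_allele,
                query.other_allele: query.other_allele,
            },
        )
    if query.id not in panel:
        logger.info("find_proxy: query %s absent from panel", query.id)
        return None
    t = outcome.table
    near = t[(t["pos"] - query.pos).abs() <= search_window]
    best = None
    for _, row in near.iterrows():
        vid = str(row["id"])
        if vid not in panel:
            continue
        r = panel.r(query.id, vid)
        r2 = r * r
        key = (r2, -int(row["pos"]), vid)
        if best is None or key > best[0]:
            best = (key, row, r)
    if best is None or best[0][0] <= r2_threshold:
        logger.info("find_proxy: no proxy above r2 > %g for %s",
                    r2_threshold, query.id)
        return None
    _, row, r = best
    proxy_key = _row_record(row).variant
    if r >= 0:
        amap = {
            query.effect_allele: proxy_key.effect_allele,
            query.other_allele: proxy_key.other_allele,
        }
    else:
        amap = {
            query.effect_allele: proxy_key.other_allele,
            query.other_allele: proxy_key.effect_allele,
        }
    return ProxyResult(query=query, proxy=proxy_key, r2=float(r * r),
                       allele_map=amap)


def harmonize(
    exposure: AssociationRecord, outcome: AssociationRecord
) -> tuple[Optional[AssociationRecord], Optional[AssociationRecord], str]:
    """Align an outcome record to the exposure's effect allele.

    Returns ``(exposure, aligned_outcome, reason)``; on a drop the records
    are ``None`` and the reason names the rule.  Resolution order: direct
    match, allele swap (beta negated, EAF reflected), strand complement
    (then match/swap).  Palindromic (A/T, C/G) pairs are dropped when either
    EAF is missing or near 0.5, otherwise oriented by frequency concordance.
    """
    if exposure.variant.id != outcome.variant.id:
        return None, None, "different_variants"
    exp_v, out_v = exposure.variant, outcome.variant

    if exp_v.is_palindromic:
        if {out_v.effect_allele, out_v.other_allele} != {
            exp_v.effect_allele, exp_v.other_allele
        }:
            return None, None, "incompatible_alleles"
        if exposure.eaf is None or outcome.eaf is None:
            return None, None, "palindromic_missing_eaf"
        lo, hi = PALINDROME_EAF_WINDOW
        if lo <= exposure.eaf <= hi or lo <= outcome.eaf <= hi:
            return None, None, "palindromic_ambiguous_eaf"
        concordant = (exposure.eaf - 0.5) * (outcome.eaf - 0.5) > 0
        same_label = out_v.effect_allele == exp_v.effect_allele
        if concordant == same_label:
            aligned = outcome if same_label else outcome.flipped()
        else:
            aligned = outcome.flipped() if same_label else outcome
        # force the allele labels onto the exposure orientation
        aligned = AssociationRecord(
            variant=exp_v, beta=aligned.beta, se=aligned.se,
            pvalue=aligned.pvalue, eaf=aligned.eaf, n=aligned.n,
        )
        return exposure, aligned, "palindromic_freq_oriented"

    pairs = {
        (exp_v.effect_allele, exp_v.other_allele): "same",
        (exp_v.other_allele, exp_v.effect_allele): "swap",
        (COMPLEMENT[exp_v.effect_allele], COMPLEMENT[exp_v.other_allele]): "same",
        (COMPLEMENT[exp_v.other_allele], COMPLEMENT[exp_v.effect_allele]): "swap",
    }
    action = pairs.get((out_v.effect_allele, out_v.other_allele))
    if action is None:
        return None, None, "incompatible_alleles"
    aligned = outcome if action == "same" else outcome.flipped()
    aligned = AssociationRecord(
        variant=exp_v, beta=aligned.beta, se=aligned.se,
        pvalue=aligned.pvalue, eaf=aligned.eaf, n=aligned.n,
    )
    return exposure, aligned, action


def harmonize_pairs(
    instruments: list,
    outcome: RegionalDataset,
    panel: Optional[ReferencePanel] = None,
) -> tuple[list, list]:
    """Harmonize each instrument to the outcome dataset, via proxy if needed.

    Returns (pairs, skipped): pairs of (exposure, aligned outcome) records
    and a list of (variant id, reason) for drops.
    """
    pairs, skipped = [], []
    for rec in instruments:
        out_rec = None
        if rec.variant.id in outcome:
            out_rec = outcome.record(rec.variant.id)
            exp_rec = rec
        elif panel is not None:
            proxy = find_proxy(rec.variant, outcome, panel)
            if proxy is None:
                skipped.append((rec.variant.id, "no_proxy"))
                continue
            out_raw = outcome.record(proxy.proxy.id)
            # express the exposure effect on the proxy's allele grid
            mapped_ea = proxy.allele_map[rec.variant.effect_allele]
            exp_rec = AssociationRecord(
                variant=VariantKey(
                    id=proxy.proxy.id, chrom=proxy.proxy.chrom,
                    pos=proxy.proxy.pos, effect_allele=mapped_ea,
                    other_allele=(
                        proxy.proxy.other_allele
                        if mapped_ea == proxy.proxy.effect_allele
                        else proxy.proxy.effect_allele
                    ),
                ),
                beta=rec.beta, se=rec.se, pvalue=rec.pvalue,
                eaf=rec.eaf, n=rec.n,
            )
            out_rec = out_raw
        else:
            skipped.append((rec.variant.id, "no_instrument"))
            continue
        if np.isnan(out_rec.beta) if out_rec.beta is not None else True:
            skipped.append((rec.variant.id, "missing_outcome_beta"))
            continue
        exp_a, out_a, reason = harmonize(exp_rec, out_rec)
        if exp_a is None:
            skipped.append((rec.variant.id, reason))
            continue
        pairs.append((exp_a, out_a))
    return pairs, skipped
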