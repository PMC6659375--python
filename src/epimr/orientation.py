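"""Direction-of-effect analyses: Steiger tests, reverse MR, sign chaining.

The Steiger directionality test compares the variance an instrument explains
in two traits.  From summary statistics, the instrument-explained variance is

    r^2 = z^2 / (z^2 + n - 2),    z = beta / se,

which is exactly the squared genotype-phenotype correlation implied by the
regression t-statistic.  Because the two traits come from non-overlapping
samples in the two-sample design, the |r| values are compared with a
two-sample Fisher-z test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .instruments import harmonize_pairs
from .mr import MRResult, ivw, wald_ratio
from .records import AssociationRecord, CpGAnnotation, ReferencePanel, RegionalDataset

logger = logging.getLogger(__name__)

GWAS_P_THRESHOLD = 5e-8       # genome-wide threshold for reverse-MR instruments
PRUNE_R2 = 0.1                # LD pruning among reverse-MR instruments
PRUNE_WINDOW = 500_000        # bp horizon for LD pruning
STEIGER_LEVEL = 0.05


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction: str            # exposure_to_outcome / outcome_to_exposure / indeterminate
    z_statistic: float
    pvalue: float


@dataclass
class ChainReport:
    """Oriented exposure -> CpG -> trait chain for one association."""

    cpg_id: str
    trait_id: str
    ewas_sign: int
    mr_sign: int
    implied_exposure_effect: str      # raises / lowers / none
    steiger_chain: Optional[dict] = None
    reverse_mr_pvalue: Optional[float] = None


def steiger_r2(record: AssociationRecord) -> float:
    """Variance in the trait explained by the instrument, from beta/se/n."""
    if record.n is None or record.n < 3:
        raise ValueError("steiger_r2 requires n >= 3")
    z2 = (record.beta / record.se) ** 2
    return float(z2 / (z2 + record.n - 2))


def _sum_r2(records) -> float:
    return float(sum(steiger_r2(r) for r in records))


def steiger_direction(
    exposure_records,
    outcome_records,
    n_exposure: Optional[int] = None,
    n_outcome: Optional[int] = None,
    level: float = STEIGER_LEVEL,
) -> SteigerResult:
    """Directionality test between two traits sharing instrument(s).

    Instrument-explained r^2 is summed over (conditionally independent)
    instruments per trait; |r| values are compared on the Fisher-z scale
    with variance 1/(nX-3) + 1/(nY-3).  The direction goes to the trait
    with the larger r^2 when p < ``level``, otherwise indeterminate.
    """
    if isinstance(exposure_records, AssociationRecord):
        exposure_records = [exposure_records]
    if isinstance(outcome_records, AssociationRecord):
        outcome_records = [outcome_records]
    nx = n_exposure or exposure_records[0].n
    ny = n_outcome or outcome_records[0].n
    if nx is None or ny is None or nx < 4 or ny < 4:
        raise ValueError("sample sizes >= 4 required")
    r2x = min(_sum_r2(exposure_records), 1.0 - 1e-12)
    r2y = min(_sum_r2(outcome_records), 1.0 - 1e-12)
    zx, zy = np.arctanh(np.sqrt(r2x)), np.arctanh(np.sqrt(r2y))
    denom = np.sqrt(1.0 / (nx - 3) + 1.0 / (ny - 3))
    z = float((zx - zy) / denom)
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), 5e-324, 1.0))
    if p < level and r2x > r2y:
        direction = "exposure_to_outcome"
    elif p < level and r2y > r2x:
        direction = "outcome_to_exposure"
    else:
        direction = "indeterminate"
    return SteigerResult(
        r2_exposure=r2x, r2_outcome=r2y, direction=direction,
        z_statistic=z, pvalue=p,
    )


def select_gwas_instruments(
    trait: RegionalDataset,
    panel: Optional[ReferencePanel] = None,
    p_threshold: float = GWAS_P_THRESHOLD,
    prune_r2: float = PRUNE_R2,
    prune_window: int = PRUNE_WINDOW,
) -> list:
    """Genome-wide-significant, LD-pruned instruments for a complex trait.

    Greedy pruning by ascending p: a variant is kept when its panel r^2
    with every already-kept variant within ``prune_window`` bp is below
    ``prune_r2`` (variants farther apart are assumed independent).
    """
    t = trait.table
    hits = t[t["beta"].notna() & (t["pvalue"] < p_threshold)]
    hits = hits.sort_values(["pvalue", "pos", "id"], kind="mergesort")
    kept = []
    for _, row in hits.iterrows():
        ok = True
        for k in kept:
            if abs(int(row["pos"]) - k.variant.pos) > prune_window:
                continue
            if panel is not None and row["id"] in panel and k.variant.id in panel:
                if panel.r2(str(row["id"]), k.variant.id) >= prune_r2:
                    ok = False
                    break
            else:
                ok = False   # cannot certify independence without the panel
                break
        if ok:
            from .instruments import _row_record

            kept.append(_row_record(row))
    return kept


def reverse_mr(
    trait: RegionalDataset,
    methylation: RegionalDataset,
    panel: Optional[ReferencePanel] = None,
    p_threshold: float = GWAS_P_THRESHOLD,
    steiger_filter: bool = True,
) -> Optional[MRResult]:
    """MR with the complex trait as exposure and methylation as outcome.

    Instruments are the trait's genome-wide-significant, LD-pruned variants;
    estimates reuse the forward Wald/IVW machinery with the roles swapped.
    With ``steiger_filter`` (default), instruments that explain more
    variance in the outcome (methylation) than in the exposure (trait) are
    excluded — such variants are primarily mQTLs and would contaminate the
    reverse estimate through the forward path.  Returns ``None`` (logged)
    when no instrument can be harmonized.
    """
    instruments = select_gwas_instruments(trait, panel, p_threshold)
    if steiger_filter:
        kept = []
        for rec in instruments:
            if rec.variant.id not in methylation:
                kept.append(rec)
                continue
            m_rec = methylation.record(rec.variant.id)
            try:
                if steiger_r2(rec) > steiger_r2(m_rec):
                    kept.append(rec)
            except ValueError:
                kept.append(rec)
        instruments = kept
    if not instruments:
        logger.info("reverse_mr: no genome-wide-significant trait instrument")
        return None
    pairs, skipped = harmonize_pairs(instruments, methylation, panel)
    if not pairs:
        logger.info("reverse_mr: no harmonizable instrument (%s)", skipped)
        return None
    exposures = [p[0] for p in pairs]
    outcomes = [p[1] for p in pairs]
    if len(pairs) == 1:
        return wald_ratio(
            exposures[0], outcomes[0],
            cpg_id=trait.trait_id, trait_id=methylation.trait_id,
        )
    return ivw(
        exposures, outcomes,
        cpg_id=trait.trait_id, trait_id=methylation.trait_id,
    )


def orient_chain(cpg: CpGAnnotation, mr: MRResult) -> ChainReport:
    """Sign-chain the exposure -> methylation -> trait path.

    The implied effect of the upstream exposure on the trait is the sign of
    ewas_beta * mr_beta: negative products mean the exposure lowers the
    trait, positive products raise it; a zero on either side yields "none".
    """
    prod = cpg.ewas_beta * mr.beta
    if prod == 0:
        implied = "none"
    elif prod < 0:
        implied = "lowers"
    else:
        implied = "raises"
    return ChainReport(
        cpg_id=cpg.cpg_id, trait_id=mr.trait_id,
        ewas_sign=int(np.sign(cpg.ewas_beta)), mr_sign=int(np.sign(mr.beta)),
        implied_exposure_effect=implied,
    )


@dataclass
class ComparisonReport:
    """Two MR estimates of the same CpG-trait pair from independent samples."""

    cpg_id: str
    trait_id: str
    beta_a: float
    se_a: float
    beta_b: float
    se_b: float
    sign_concordant: bool
    heterogeneity_z: float
    heterogeneity_p: float


def compare_estimates(result_a: MRResult, result_b: MRResult) -> ComparisonReport:
    """Sign concordance and a two-sample heterogeneity z-test.

    z = (b1 - b2) / sqrt(se1^2 + se2^2), two-sided normal p.  Supports
    timepoint, population and stratified split-sample comparisons.
    """
    if (result_a.cpg_id, result_a.trait_id) != (result_b.cpg_id, result_b.trait_id):
        raise ValueError("comparison requires the same CpG-trait pair")
    z = (result_a.beta - result_b.beta) / np.hypot(result_a.se, result_b.se)
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), 5e-324, 1.0))
    return ComparisonReport(
        cpg_id=result_a.cpg_id, trait_id=result_a.trait_id,
        beta_a=result_a.beta, se_a=result_a.se,
        beta_b=result_b.beta, se_b=result_b.se,
        sign_concordant=bool(np.sign(result_a.beta) == np.sign(result_b.beta)),
        heterogeneity_z=float(z), heterogeneity_p=p,
    )
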