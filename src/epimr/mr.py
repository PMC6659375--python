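"""Two-sample Mendelian randomization estimators and the phenome-scan driver.

With gene-exposure association gamma_j and gene-outcome association Gamma_j
(SE sigma_Yj), the single-instrument causal estimate is the Wald ratio

    beta_j = Gamma_j / gamma_j,     se = sigma_Yj / |gamma_j|

(first-order delta method, exposure-side uncertainty ignored — documented as
anti-conservative for weak instruments).  With k >= 2 instruments the
fixed-effect inverse-variance-weighted (IVW) combination is

    beta_IVW = sum_j w_j beta_j / sum_j w_j,   w_j = gamma_j^2 / sigma_Yj^2,

with se = (sum_j w_j)^(-1/2); for a single instrument IVW reduces exactly to
the Wald ratio.  Two-sided p-values use the standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import InstrumentSet, harmonize_pairs
from .records import AssociationRecord, ReferencePanel, RegionalDataset

_MIN_P = 5e-324


@dataclass
class MRResult:
    """A fitted MR estimate for one CpG-trait pair.

    Carries the causal estimate (SD outcome per SD exposure), its standard
    error, two-sided normal p-value, the method used and the instruments
    that entered the fit.
    """

    cpg_id: str
    trait_id: str
    beta: float
    se: float
    pvalue: float
    method: str                       # "wald" or "ivw"
    n_instruments: int
    instruments_used: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in {"wald", "ivw"}:
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "wald" and self.n_instruments != 1:
            raise ValueError("Wald ratio is a single-instrument method")
        if not self.se > 0:
            raise ValueError("se must be > 0")
        if not (0 < self.pvalue <= 1):
            raise ValueError("pvalue must be in (0,1]")

    @property
    def z(self) -> float:
        return self.beta / self.se

    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        rows = [
            ["exposure (CpG)", self.cpg_id],
            ["outcome", self.trait_id],
            ["method", self.method],
            ["n instruments", str(self.n_instruments)],
            ["beta (SD/SD)", f"{self.beta:.6g}"],
            ["se", f"{self.se:.6g}"],
            ["p-value", f"{self.pvalue:.3e}"],
            ["95% CI", f"[{self.beta - 1.959964 * self.se:.6g}, "
                       f"{self.beta + 1.959964 * self.se:.6g}]"],
        ]
        return str(
            SimpleTable(rows, title="Two-sample MR result")
        )


def _norm_p(z: float) -> float:
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), _MIN_P, 1.0))


def wald_ratio(
    exposure: AssociationRecord, outcome: AssociationRecord,
    cpg_id: str = "", trait_id: str = "",
) -> MRResult:
    """Single-instrument Wald ratio on a harmonized exposure/outcome pair."""
    if exposure.beta == 0:
        raise ZeroDivisionError("Wald ratio undefined for gamma = 0")
    beta = outcome.beta / exposure.beta
    se = outcome.se / abs(exposure.beta)
    return MRResult(
        cpg_id=cpg_id or exposure.variant.id, trait_id=trait_id or "outcome",
        beta=beta, se=se, pvalue=_norm_p(beta / se),
        method="wald", n_instruments=1,
        instruments_used=[exposure.variant.id],
    )


def ivw(
    exposures: list, outcomes: list, cpg_id: str = "", trait_id: str = "",
) -> MRResult:
    """Fixed-effect IVW over harmonized (exposure, outcome) record lists."""
    if len(exposures) == 0 or len(exposures) != len(outcomes):
        raise ValueError("need >= 1 harmonized exposure/outcome pair")
    if len(exposures) == 1:
        # single instrument: reduces exactly to the Wald ratio
        return wald_ratio(exposures[0], outcomes[0], cpg_id, trait_id)
    g = np.array([e.beta for e in exposures])
    G = np.array([o.beta for o in outcomes])
    s = np.array([o.se for o in outcomes])
    if np.any(g == 0):
        raise ZeroDivisionError("IVW requires all gamma_j != 0")
    w = g**2 / s**2
    beta = float(np.sum(w * (G / g)) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    return MRResult(
        cpg_id=cpg_id, trait_id=trait_id, beta=beta, se=se,
        pvalue=_norm_p(beta / se), method="ivw", n_instruments=len(g),
        instruments_used=[e.variant.id for e in exposures],
    )


class MRModel:
    """Model object over harmonized instrument pairs for one CpG-trait pair.

    ``fit()`` dispatches to the Wald ratio (one instrument) or fixed-effect
    IVW (two or more) and returns an :class:`MRResult`.
    """

    def __init__(self, exposures, outcomes, cpg_id="", trait_id=""):
        self.exposures = list(exposures)
        self.outcomes = list(outcomes)
        self.cpg_id = cpg_id
        self.trait_id = trait_id

    @classmethod
    def from_datasets(
        cls,
        instruments: InstrumentSet,
        outcome: RegionalDataset,
        panel: Optional[ReferencePanel] = None,
    ) -> "MRModel":
        pairs, skipped = harmonize_pairs(instruments.records, outcome, panel)
        model = cls(
            [p[0] for p in pairs], [p[1] for p in pairs],
            cpg_id=instruments.cpg_id, trait_id=outcome.trait_id,
        )
        model.skipped = skipped
        return model

    def fit(self) -> MRResult:
        if not self.exposures:
            raise ValueError("no harmonized instruments to fit")
        if len(self.exposures) == 1:
            return wald_ratio(
                self.exposures[0], self.outcomes[0], self.cpg_id, self.trait_id
            )
        return ivw(self.exposures, self.outcomes, self.cpg_id, self.trait_id)


def bonferroni_threshold(n_cpgs: int, n_traits: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / (number of CpG-trait combinations)."""
    if n_cpgs < 1 or n_traits < 1:
        raise ValueError("counts must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0,1)")
    return alpha / (n_cpgs * n_traits)


def mr_power(n_outcome: int, r2_gx: float, beta_xy: float,
             alpha: float = 0.05) -> float:
    """Asymptotic two-sided power of the MR test for standardized traits.

    The non-centrality of the MR z-statistic is |beta_xy| * sqrt(n * r2_gx)
    where r2_gx is the variance in the exposure explained by the instrument
    and n the outcome sample size.
    """
    if not (0 < r2_gx < 1):
        raise ValueError("r2_gx must be in (0,1)")
    if n_outcome < 10:
        raise ValueError("n_outcome must be >= 10")
    zc = stats.norm.isf(alpha / 2.0)
    ncp = abs(beta_xy) * np.sqrt(n_outcome * r2_gx)
    return float(stats.norm.cdf(-zc + ncp) + stats.norm.cdf(-zc - ncp))


def run_phenome_scan(
    instrument_sets: dict,
    outcome_datasets: dict,
    panel: Optional[ReferencePanel] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """MR over every CpG x trait combination, with Bonferroni flags.

    ``instrument_sets`` maps cpg_id -> InstrumentSet (or None for
    uninstrumentable CpGs), ``outcome_datasets`` maps trait_id ->
    RegionalDataset.  Per-pair failures never abort the scan: skipped pairs
    are emitted with machine-readable reasons.  The significance flag uses
    strict ``p < alpha / (n_cpgs * n_traits)``.
    """
    n_cpgs = sum(
        1 for s in instrument_sets.values() if s is not None and len(s) > 0
    )
    n_traits = len(outcome_datasets)
    threshold = (
        bonferroni_threshold(n_cpgs, n_traits, alpha)
        if n_cpgs and n_traits else alpha
    )
    rows = []
    for cpg_id, iset in instrument_sets.items():
        for trait_id, outcome in outcome_datasets.items():
            row = {
                "cpg_id": cpg_id, "trait_id": trait_id, "method": "",
                "n_instruments": 0, "beta": np.nan, "se": np.nan,
                "pvalue": np.nan, "significant": False, "skip_reason": "",
            }
            if iset is None or len(iset) == 0:
                row["skip_reason"] = "no_instrument"
                rows.append(row)
                continue
            model = MRModel.from_datasets(iset, outcome, panel)
            if not model.exposures:
                row["skip_reason"] = "no_instrument"
                rows.append(row)
                continue
            try:
                res = model.fit()
            except ZeroDivisionError:
                row["skip_reason"] = "zero_exposure_beta"
                rows.append(row)
                continue
            row.update(
                method=res.method, n_instruments=res.n_instruments,
                beta=res.beta, se=res.se, pvalue=res.pvalue,
                significant=bool(res.pvalue < threshold),
            )
            rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["alpha"] = alpha
    out.attrs["n_cpgs"] = n_cpgs
    out.attrs["n_traits"] = n_traits
    return out
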