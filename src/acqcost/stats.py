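"""Acquisition-cost statistics and lag/growth tradeoff summaries.

The acquisition cost of a plasmid is the mean time-to-threshold (TTT) of
freshly-made (de novo) transconjugant colonies divided by the mean TTT of
fully adapted transconjugants: a cost of 1.5 means new acquisitions need
50% longer to reach the reference density.  Costs are compared with
two-sided t-tests (Bonferroni-corrected across plasmids where relevant),
and the within-population lag/growth tradeoff is summarized by an OLS
regression of growth rate on lag time.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AcquisitionCostResult",
    "TradeoffFit",
    "acquisition_cost",
    "compare_populations",
    "regress",
    "cost_tradeoff_summary",
]


@dataclass
class AcquisitionCostResult:
    plasmid_id: str
    cost: float
    p_value: float
    n_de_novo: int
    n_adapted: int
    mean_ttt_adapted: float
    per_colony_normalized_ttt: np.ndarray = field(repr=False, default=None)


@dataclass
class TradeoffFit:
    """OLS summary of growth rate (per hour) against lag time (hours)."""

    plasmid_id: str
    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    pearson_rho: float
    n: int


def compare_populations(sample_a, sample_b, n_comparisons: int = 1,
                        equal_var: bool = True) -> float:
    """Two-sided two-sample t-test p-value, Bonferroni-multiplied and capped.

    Pooled (equal-variance) by default, matching the original analysis
    convention; set ``equal_var=False`` for Welch.  Two zero-variance
    samples with equal means give p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    if a.std() == 0 and b.std() == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(sps.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return min(p * n_comparisons, 1.0)


def acquisition_cost(de_novo_ttt, adapted_ttt, plasmid_id: str = "",
                     n_comparisons: int = 1) -> AcquisitionCostResult:
    """Acquisition cost: mean de novo TTT over mean adapted TTT.

    Equivalently the mean of per-colony de novo TTTs each normalized by the
    single adapted mean (identical by construction; both views retained).
    The p-value is a two-sided t-test on the raw TTT samples.
    """
    dn = np.asarray(de_novo_ttt, dtype=float)
    ad = np.asarray(adapted_ttt, dtype=float)
    if len(dn) == 0 or len(ad) == 0:
        raise ValueError("both TTT samples must be non-empty")
    mean_ad = float(ad.mean())
    if mean_ad <= 0:
        raise ValueError("mean adapted TTT must be positive")
    normalized = dn / mean_ad
    p = compare_populations(dn, ad, n_comparisons=n_comparisons) \
        if len(dn) >= 2 and len(ad) >= 2 else float("nan")
    return AcquisitionCostResult(
        plasmid_id=plasmid_id,
        cost=float(normalized.mean()),
        p_value=p,
        n_de_novo=len(dn),
        n_adapted=len(ad),
        mean_ttt_adapted=mean_ad,
        per_colony_normalized_ttt=normalized,
    )


def regress(x, y, plasmid_id: str = "") -> TradeoffFit:
    """Ordinary least squares of y on x with a t-based 95% CI on the slope.

    Constant x raises (slope undefined); constant y returns slope 0 with
    Pearson rho reported as NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points to regress")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    if np.ptp(y) == 0:
        return TradeoffFit(plasmid_id, 0.0, float(y[0]), (0.0, 0.0), float("nan"), n)
    res = sps.linregress(x, y)
    tcrit = sps.t.ppf(0.975, n - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return TradeoffFit(
        plasmid_id=plasmid_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci95=(float(ci[0]), float(ci[1])),
        pearson_rho=float(res.rvalue),
        n=n,
    )


def cost_tradeoff_summary(per_plasmid: list[tuple[AcquisitionCostResult, TradeoffFit]]):
    """Panel-level association between acquisition cost and tradeoff slope.

    Returns (table, rho): a tidy DataFrame of per-plasmid cost and tradeoff
    slope with CIs, plus the Pearson correlation between cost and slope
    across the panel (the cross-plasmid tradeoff-strength relationship).
    """
    if len(per_plasmid) < 3:
        raise ValueError("need at least 3 plasmids to summarize the panel")
    rows = []
    for cost_res, fit in per_plasmid:
        rows.append({
            "plasmid_id": cost_res.plasmid_id or fit.plasmid_id,
            "cost": cost_res.cost,
            "p_value": cost_res.p_value,
            "n_de_novo": cost_res.n_de_novo,
            "n_adapted": cost_res.n_adapted,
            "tradeoff_slope": fit.slope,
            "slope_lo95": fit.slope_ci95[0],
            "slope_hi95": fit.slope_ci95[1],
            "tradeoff_rho": fit.pearson_rho,
        })
    table = pd.DataFrame(rows)
    rho = float(sps.pearsonr(table["cost"], table["tradeoff_slope"]).statistic)
    return table, rho
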