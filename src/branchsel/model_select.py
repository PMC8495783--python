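"""Likelihood-ratio testing and FDR correction across the gene batch.

Terminology note (deliberate, and the opposite of common statistical
usage): the *general* model is the parameter-rich one and the
*alternative* model is the restricted one nested within it.  The LRT
statistic is 2(lnL_general − lnL_alternative), compared to a chi-square
with df equal to the difference in free-parameter counts; per-gene p
values are Benjamini–Hochberg adjusted across the batch, and the general
model is selected for a gene only when its adjusted p value falls below
alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .codeml_io import ModelFit

DEFAULT_ALPHA = 0.05


class ModelSelectError(ValueError):
    pass


@dataclass
class LRTResult:
    gene_id: str
    lnl_general: float
    lnl_alternative: float
    stat: float  # 2*delta-lnL, clamped at 0
    df: int
    pvalue: float
    qvalue: float | None = None  # filled by FDR adjustment across genes
    best_model: str | None = None
    negative_stat_flag: bool = False


def lrt(general: ModelFit, alternative: ModelFit) -> LRTResult:
    """Chi-square LRT of the restricted (alternative) model against the
    general one.  A negative raw statistic — possible when an optimizer
    stalls in a local optimum despite replicate starts — is clamped to 0
    and flagged, never silently rerun."""
    if alternative.np >= general.np:
        raise ModelSelectError(
            f"{general.gene_id}: alternative model (np={alternative.np}) must be nested in "
            f"the general one (np={general.np}); check the two control templates"
        )
    raw = 2.0 * (general.lnl - alternative.lnl)
    stat = max(0.0, raw)
    df = general.np - alternative.np
    return LRTResult(
        gene_id=general.gene_id,
        lnl_general=general.lnl,
        lnl_alternative=alternative.lnl,
        stat=stat,
        df=df,
        pvalue=float(chi2.sf(stat, df)),
        negative_stat_flag=raw < 0,
    )


def fdr_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p values, order-aligned with
    the input."""
    if len(pvalues) == 0:
        return []
    if any(p < 0 or p > 1 for p in pvalues):
        raise ModelSelectError("p values must lie in [0, 1]")
    _, qvals, _, _ = multipletests(list(pvalues), method="fdr_bh")
    return [float(q) for q in qvals]


def select_best(result: LRTResult, alpha: float = DEFAULT_ALPHA) -> str:
    """The restricted model is preferred unless rejected: general iff
    qvalue < alpha (strict)."""
    if result.qvalue is None:
        raise ModelSelectError(f"{result.gene_id}: qvalue missing (run fdr_adjust first)")
    return "general" if result.qvalue < alpha else "alternative"


def apply_fdr_and_select(
    results: Iterable[LRTResult], alpha: float = DEFAULT_ALPHA
) -> list[LRTResult]:
    results = list(results)
    qvals = fdr_adjust([r.pvalue for r in results])
    for r, q in zip(results, qvals):
        r.qvalue = q
        r.best_model = select_best(r, alpha)
    return results


_COLUMNS = [
    "gene_id",
    "lnl_general",
    "lnl_alternative",
    "stat",
    "df",
    "pvalue",
    "qvalue",
    "best_model",
    "negative_stat_flag",
]


def summary_table(results: Iterable[LRTResult]) -> pd.DataFrame:
    """One row per tested gene (failed genes live in the exclusion log,
    not here); sorted by gene_id for scheduling-independent output."""
    rows = [
        {
            "gene_id": r.gene_id,
            "lnl_general": r.lnl_general,
            "lnl_alternative": r.lnl_alternative,
            "stat": r.stat,
            "df": r.df,
            "pvalue": r.pvalue,
            "qvalue": r.qvalue,
            "best_model": r.best_model,
            "negative_stat_flag": r.negative_stat_flag,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=_COLUMNS).sort_values("gene_id").reset_index(drop=True)
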