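"""RT-qPCR validation: delta-delta-Ct relative quantification, Pearson
correlation against array log2 fold changes, and the replicate-level
one-way ANOVA F-test used for micronutrient comparisons.

The delta-delta-Ct method assumes an amplification efficiency of 2 per
cycle.  Target Ct values are normalized against a reference (housekeeping)
gene within each condition: dCt = mean(Ct_target - Ct_reference); the
between-condition difference ddCt = dCt_treated - dCt_control gives the
relative quantity RQ = 2^(-ddCt), i.e. log2 RQ = -ddCt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ferrex.stats import one_way_anova

log = logging.getLogger(__name__)

anova_f = one_way_anova  # shared definition with the array DE test


@dataclass
class RelativeQuantification:
    gene: str
    dct_control: float
    dct_treated: float
    ddct: float
    rq: float

    @property
    def log2_rq(self) -> float:
        return -self.ddct


def delta_delta_ct(
    records: pd.DataFrame,
    gene: str | None = None,
    control: str = "control",
    treated: str = "iron",
) -> RelativeQuantification:
    """Delta-delta-Ct for one gene from a Ct table.

    ``records`` needs columns ``condition``, ``ct_target``, ``ct_reference``
    (and ``gene`` when more than one gene is present).  Replicate Ct
    differences are averaged within condition before the between-condition
    difference is taken.
    """
    if gene is not None:
        records = records.loc[records["gene"] == gene]
    elif "gene" in records.columns:
        unique = records["gene"].unique()
        if len(unique) != 1:
            raise ValueError("records contain several genes; pass gene=")
        gene = str(unique[0])
    dct = {}
    for condition in (control, treated):
        sub = records.loc[records["condition"] == condition]
        if sub.empty:
            raise ValueError(f"no records for condition {condition!r}")
        dct[condition] = float((sub["ct_target"] - sub["ct_reference"]).mean())
    ddct = dct[treated] - dct[control]
    return RelativeQuantification(
        gene=gene or "", dct_control=dct[control], dct_treated=dct[treated],
        ddct=ddct, rq=float(2.0 ** (-ddct)),
    )


def quantify_all(records: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Delta-delta-Ct for every gene in a Ct table.

    Returns columns gene, ddct, rq, log2_rq.
    """
    rows = []
    for gene in records["gene"].unique():
        rq = delta_delta_ct(records, gene=gene, **kwargs)
        rows.append({"gene": gene, "ddct": rq.ddct, "rq": rq.rq, "log2_rq": rq.log2_rq})
    return pd.DataFrame(rows)


def validate_correlation(
    array_log2fc, qpcr_log2rq
) -> tuple[float, float, int]:
    """Pearson correlation between array log2FC and qPCR log2 RQ.

    Pairs with missing values are dropped (logged).  Returns ``(r, p, n)``
    with the two-sided t-based p-value.  Zero variance in either vector is
    an error (r undefined).
    """
    x = np.asarray(array_log2fc, dtype=float)
    y = np.asarray(qpcr_log2rq, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < len(x):
        log.warning("dropping %d pair(s) with missing values", int(len(x) - keep.sum()))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least three complete pairs")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), int(len(x))


def validation_table(
    expression: pd.DataFrame, quantified: pd.DataFrame
) -> pd.DataFrame:
    """Join array DE records with qPCR quantification on the gene id."""
    expr = expression.rename(columns={"feature": "gene"})[["gene", "log2FC"]]
    return quantified.merge(expr, on="gene", how="inner")
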