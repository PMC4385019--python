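"""Shared statistical primitives: one-way ANOVA and Benjamini-Hochberg FDR.

Two-group one-way ANOVA (the F-test used both for differential expression
and for micronutrient comparisons) is equivalent to the two-sided
equal-variance t-test; the F statistic and p-value are computed in closed
form so degenerate inputs (zero within-group variance) can be handled
explicitly and the whole feature matrix can be tested in one vectorized
call.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def one_way_anova(*groups: Sequence[float]) -> tuple[float, float]:
    """One-way ANOVA F-test across ``groups`` of replicate measurements.

    Returns ``(F, p)``.  If every group has zero within-group variance and
    all group means are equal, there is no evidence of any effect and the
    test is reported as ``(0.0, 1.0)`` by convention; zero within-group
    variance with unequal means gives ``(inf, 0.0)``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two replicates")
    n = sum(a.size for a in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    dfb, dfw = k - 1, n - k
    if ssw == 0.0:
        if ssb == 0.0:
            log.debug("degenerate ANOVA input: zero variance everywhere; p=1")
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(f, dfb, dfw))
    return float(f), p


def two_group_f_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-group one-way ANOVA over the rows of ``a`` and ``b``.

    ``a`` and ``b`` are (n_features, n_replicates) arrays for the two
    conditions.  Returns ``(F, p)`` arrays; degenerate rows follow the same
    convention as :func:`one_way_anova`.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each condition needs at least two replicates")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    grand = (a.sum(axis=1) + b.sum(axis=1)) / (na + nb)
    ssb = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ssw = ((a - ma[:, None]) ** 2).sum(axis=1) + ((b - mb[:, None]) ** 2).sum(axis=1)
    dfb, dfw = 1, na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = np.where(np.isfinite(f), sps.f.sf(np.where(np.isfinite(f), f, 0.0), dfb, dfw), 0.0)
    both_zero = (ssw == 0.0) & (ssb == 0.0)
    f = np.where(both_zero, 0.0, f)
    p = np.where(both_zero, 1.0, p)
    only_within_zero = (ssw == 0.0) & (ssb > 0.0)
    f = np.where(only_within_zero, np.inf, f)
    p = np.where(only_within_zero, 0.0, p)
    return f, p


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved.

    adj_(i) = min_{j >= i}( p_(j) * m / j ), clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
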