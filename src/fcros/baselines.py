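"""Formula-level comparator statistics: FC ranking, pooled t-test, WAD.

These are the simple per-gene statistics FCROS is routinely benchmarked
against.  Heavier competitors (SAM, moderated-t/TREAT, rank product) are
deliberately out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import fold_changes
from .matrix import ExpressionMatrix

__all__ = ["TTestResult", "pooled_t_test", "pooled_t_table",
           "wad_statistic", "fc_ranking", "two_sided_fc_score",
           "ttest_selection_error"]


@dataclass
class TTestResult:
    """Equal-variance two-sample t-test for one gene."""

    t_statistic: float
    pooled_variance: float
    p_value: float
    df: int


def pooled_t_test(control_values: np.ndarray, test_values: np.ndarray) -> TTestResult:
    """Pooled (equal-variance) two-sample Student t-test.

    ``t = (mean_t - mean_c) / (sp * sqrt(1/m1 + 1/m2))`` with the pooled
    variance ``sp^2 = ((m1-1)s1^2 + (m2-1)s2^2)/(m1+m2-2)``; the p-value is
    the two-sided tail under Student t with ``m1 + m2 - 2`` df.
    """
    c = np.asarray(control_values, dtype=float)
    t = np.asarray(test_values, dtype=float)
    m1, m2 = c.size, t.size
    if m1 < 2 or m2 < 2:
        raise ValueError("need at least 2 samples per group")
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite sample value")
    df = m1 + m2 - 2
    sp2 = ((m1 - 1) * c.var(ddof=1) + (m2 - 1) * t.var(ddof=1)) / df
    if sp2 == 0.0:
        raise ValueError("zero pooled variance: t statistic undefined")
    tstat = (t.mean() - c.mean()) / np.sqrt(sp2 * (1.0 / m1 + 1.0 / m2))
    p = 2.0 * stats.t.sf(abs(tstat), df)
    # identical groups give t = 0 exactly; sf(0) = 0.5 so p = 1
    return TTestResult(float(tstat), float(sp2), float(p), df)


def pooled_t_table(data: ExpressionMatrix) -> np.ndarray:
    """Vectorized pooled t-test over all genes.

    Returns a structured-free ``(n, 3)`` array of columns
    (t_statistic, pooled_variance, p_value).  Genes with zero pooled
    variance get ``t = 0, p = 1`` rather than an error, so a genome-wide
    scan never aborts on a flat probe.
    """
    c, t = data.control_values, data.test_values
    m1, m2 = c.shape[1], t.shape[1]
    df = m1 + m2 - 2
    sp2 = ((m1 - 1) * c.var(axis=1, ddof=1) + (m2 - 1) * t.var(axis=1, ddof=1)) / df
    denom = np.sqrt(sp2 * (1.0 / m1 + 1.0 / m2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(denom > 0, (t.mean(axis=1) - c.mean(axis=1)) / denom, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    return np.column_stack([tstat, sp2, p])


def wad_statistic(data: ExpressionMatrix) -> np.ndarray:
    """Weighted average difference (WAD) score per gene.

    The average difference ``AD_i = mean_t(x_i) - mean_c(x_i)`` on the log2
    scale is weighted by the gene's relative overall expression
    ``w_i = (xbar_i - min_j xbar_j) / (max_j xbar_j - min_j xbar_j)``,
    where ``xbar_i`` is the mean over all samples, so highly expressed
    genes are promoted.  Weights lie in [0, 1].
    """
    ad = data.test_values.mean(axis=1) - data.control_values.mean(axis=1)
    xbar = data.values.mean(axis=1)
    lo, hi = xbar.min(), xbar.max()
    if hi == lo:
        raise ValueError("all genes share the same overall mean: WAD weights degenerate")
    w = (xbar - lo) / (hi - lo)
    return ad * w


def two_sided_fc_score(fc: np.ndarray) -> np.ndarray:
    """Two-sided magnitude of a fold change: ``max(FC, 1/FC)``.

    Symmetric under ``FC -> 1/FC`` so down-regulation (FC = 0.2, score 5)
    can outrank up-regulation (FC = 4, score 4) in a single top-N list.
    """
    fc = np.asarray(fc, dtype=float)
    return np.maximum(fc, 1.0 / fc)


def fc_ranking(data: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Fold changes plus their two-sided rank order (most changed first).

    Returns ``(fc, order)`` where ``order`` sorts genes by decreasing
    ``max(FC, 1/FC)`` with ties broken by gene index for determinism.
    """
    fc = fold_changes(data)
    score = two_sided_fc_score(fc)
    order = np.lexsort((np.arange(score.size), -score))
    return fc, order


def ttest_selection_error(alpha: float, n_genes: int, n_selected: int) -> float:
    """Expected false-selection percentage of a t-type threshold rule.

    With ``n`` genes tested at per-gene level ``alpha`` and ``n2`` genes
    selected, the expected proportion of false positives in the list is
    ``alpha * n / n2``; returned as a percentage, ``100 * alpha * n / n2``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_selected < 1 or n_genes < 1:
        raise ValueError("gene counts must be positive")
    return 100.0 * alpha * n_genes / n_selected
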