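"""Method-comparison machinery: confusion counts, AUC, subsampling scores.

Implements the standard evaluation protocols for two-condition DE
detectors: 2x2 confusion counts against a planted truth, rank-based
(Mann-Whitney) AUC, the subsampling score protocol (repeatedly rerun a
method on random sample subsets, count how often each gene enters the
top-N list) with its randomized-groups null variant, and reproducibility
counting of perfect/good scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .baselines import pooled_t_table, two_sided_fc_score, wad_statistic
from .core import fcros, fold_changes
from .matrix import ExpressionMatrix

__all__ = ["ScoreTable", "confusion_counts", "rank_auc", "de_score",
           "top_n_selection", "subsample_score", "reproducibility_counts",
           "METHODS"]


@dataclass
class ScoreTable:
    """Per-gene occurrence counts over resampling runs.

    ``score[i]`` counts the runs (out of ``runs``) in which gene ``i`` was
    in the top-N selection; total score mass is ``runs * top_n``.
    """

    gene_ids: list[str]
    score: np.ndarray  # int, in [0, runs]
    runs: int
    protocol_tag: str  # "true-groups" | "randomized-groups"


def confusion_counts(
    selected: Iterable[int], truth: Iterable[int], n: int
) -> tuple[int, int, int, int]:
    """Standard 2x2 counts (TP, FP, FN, TN) over a universe of n genes."""
    sel, tru = set(selected), set(truth)
    if sel and (min(sel) < 0 or max(sel) >= n):
        raise ValueError("selected index outside the gene universe")
    if tru and (min(tru) < 0 or max(tru) >= n):
        raise ValueError("truth index outside the gene universe")
    tp = len(sel & tru)
    fp = len(sel - tru)
    fn = len(tru - sel)
    tn = n - tp - fp - fn
    return tp, fp, fn, tn


def rank_auc(statistic: np.ndarray, truth: Iterable[int]) -> float:
    """Area under the ROC curve via the Mann-Whitney identity.

    ``statistic`` must already be oriented so that larger means "more DE"
    (use :func:`de_score` to fold f-values two-sidedly).  Returns the
    probability that a uniformly chosen true-DE gene outranks a uniformly
    chosen non-DE gene, counting ties as 1/2 — identical to trapezoidal
    integration of the ROC curve.
    """
    s = np.asarray(statistic, dtype=float)
    n = s.size
    pos = np.zeros(n, dtype=bool)
    pos[list(truth)] = True
    n_pos = int(pos.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one DE and one non-DE gene for AUC")
    r = stats.rankdata(s)  # midranks
    u = r[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def de_score(f_values: np.ndarray) -> np.ndarray:
    """Two-sided DE ordering for f-values: distance from 0.5.

    f-values code direction (0 = down, 1 = up); for a single joint top-N
    list both tails count equally, so genes are ordered by ``|f - 0.5|``.
    """
    return np.abs(np.asarray(f_values, dtype=float) - 0.5)


def top_n_selection(score: np.ndarray, top_n: int) -> np.ndarray:
    """Indices of the top-N genes by decreasing score, stable on ties.

    Ties are broken by gene index so repeated runs on identical data give
    identical lists.
    """
    score = np.asarray(score, dtype=float)
    if not 1 <= top_n <= score.size:
        raise ValueError(f"top_n must be in [1, {score.size}]")
    order = np.lexsort((np.arange(score.size), -score))
    return np.sort(order[:top_n])


# named statistics usable in the resampling protocols; each maps an
# ExpressionMatrix to a per-gene "more DE = larger" score
METHODS: dict[str, Callable[[ExpressionMatrix], np.ndarray]] = {
    "fcros": lambda d: de_score(fcros(d).f_value),
    "fc": lambda d: two_sided_fc_score(fold_changes(d)),
    "ttest": lambda d: -np.log10(np.maximum(pooled_t_table(d)[:, 2], 1e-300)),
    "wad": lambda d: np.abs(wad_statistic(d)),
}


def subsample_score(
    data: ExpressionMatrix,
    method: str | Callable[[ExpressionMatrix], np.ndarray],
    m1_sub: int,
    m2_sub: int,
    runs: int,
    top_n: int,
    seed: int,
    randomize_groups: bool = False,
) -> ScoreTable:
    """Occurrence score of each gene over repeated subsampled analyses.

    Each run draws ``m1_sub`` control and ``m2_sub`` test samples at
    random (without replacement) from their true groups, reruns ``method``
    on the subset, selects the ``top_n`` most-DE genes and adds 1 to their
    scores.  With ``randomize_groups=True`` the ``m1_sub + m2_sub``
    samples are drawn from the pooled columns irrespective of their true
    group — the null protocol whose maximal score calibrates a threshold
    separating reproducibly detected genes from chance.
    """
    fn = METHODS[method] if isinstance(method, str) else method
    if runs < 1:
        raise ValueError("runs must be >= 1")
    m1, m2 = data.m1, data.m2
    if randomize_groups:
        if m1_sub + m2_sub > m1 + m2:
            raise ValueError("subsample larger than the pooled sample set")
    elif m1_sub > m1 or m2_sub > m2:
        raise ValueError("subsample larger than a sample group")
    if m1_sub < 1 or m2_sub < 1:
        raise ValueError("subsample sizes must be >= 1")

    rng = np.random.default_rng(seed)
    score = np.zeros(data.n_genes, dtype=int)
    all_cols = np.asarray(data.control_indices + data.test_indices)
    for _ in range(runs):
        if randomize_groups:
            cols = rng.choice(all_cols, size=m1_sub + m2_sub, replace=False)
            ctl, tst = cols[:m1_sub], cols[m1_sub:]
        else:
            ctl = rng.choice(data.control_indices, size=m1_sub, replace=False)
            tst = rng.choice(data.test_indices, size=m2_sub, replace=False)
        sub = ExpressionMatrix(
            gene_ids=data.gene_ids,
            values=data.values[:, np.concatenate([ctl, tst])],
            control_indices=list(range(m1_sub)),
            test_indices=list(range(m1_sub, m1_sub + m2_sub)),
            scale_tag=data.scale_tag,
        )
        score[top_n_selection(fn(sub), top_n)] += 1
    tag = "randomized-groups" if randomize_groups else "true-groups"
    return ScoreTable(gene_ids=list(data.gene_ids), score=score,
                      runs=runs, protocol_tag=tag)


def reproducibility_counts(
    scores: ScoreTable, thresholds: Sequence[int]
) -> dict[int, int]:
    """Number of genes with score >= threshold, per threshold.

    E.g. ``thresholds=(runs, int(0.9 * runs))`` counts genes detected in
    every run ("perfect") and in at least 90% of runs ("good").
    """
    out: dict[int, int] = {}
    for thr in thresholds:
        out[int(thr)] = int(np.count_nonzero(scores.score >= thr))
    return out
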