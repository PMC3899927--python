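"""Fold change rank ordering statistics (FCROS).

Differential expression between two conditions is scored from the *ranks*
of per-gene fold changes across many pairwise control/test sample
comparisons, rather than from the fold changes themselves.  For each of the
``k <= m1*m2`` comparisons, all ``n`` genes' log2 fold changes are sorted
in increasing order and replaced by their ranks (midranks on ties).  The
per-gene trimmed mean of its ``k`` ranks, standardized by ``n``, is
approximately normal when ``k`` grows (central limit theorem on the rank
samples); its ordered values form an approximately equally spaced grid
between a minimum ``a`` and maximum ``b`` with mean gap
``delta = (b - a)/(n - 1)``.  Fitting a normal distribution with the sample
mean ``R_bar`` and variance ``sigma2`` of the standardized rank means and
evaluating its CDF at each gene yields the *f-value*: a probability near 0
for down-regulated genes, near 0.5 for equally expressed genes, and near 1
for up-regulated genes.  A single global fit produces all gene calls, so no
per-gene multiple-testing correction is involved.

The ideal noise-free geometry is ``a = 1, b = n, delta = 1`` (each gene
keeps one rank in every comparison); the normal model then has mean
``(a + b)/2`` and variance ``(n^2 - 1)/12 * delta^2``
(:func:`theoretical_moments`).  Observed ``delta`` below 1 measures rank
instability across comparisons.

The two-batch variant (:func:`fcros2`) exploits that ranks are computed
within single comparisons: pairwise comparisons from two experimental
batches can be pooled (``k = k1 + k2``) without any inter-batch
normalization, because a per-batch monotone distortion leaves within-batch
fold-change ranks unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix

__all__ = [
    "PairwiseRanks",
    "RankSummary",
    "FcrosResult",
    "build_pairing",
    "compute_pairwise_fc",
    "rank_columns",
    "trimmed_rank_means",
    "fit_rank_model",
    "compute_f_values",
    "classify_genes",
    "selection_error_percent",
    "gene_fold_change",
    "fold_changes",
    "theoretical_moments",
    "fcros",
    "fcros2",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class PairwiseRanks:
    """Tie-adjusted fold-change ranks, one column per pairwise comparison.

    ``ranks[i, j]`` is the (mid)rank of gene ``i``'s fold change in
    comparison ``j``; every column sums to ``n(n+1)/2``.
    """

    ranks: np.ndarray  # (n, k), values in [1, n]
    pairing: list[tuple[int, int]]  # (control_column, test_column) per comparison

    @property
    def n_genes(self) -> int:
        return self.ranks.shape[0]

    @property
    def k(self) -> int:
        return self.ranks.shape[1]


@dataclass
class RankSummary:
    """Fitted parameters of the rank-mean model (standardized scale).

    All quantities live on the ranks-divided-by-``n`` scale, so ``rbar`` is
    in ``(0, 1]`` and the ideal ``delta`` (each gene holding a stable rank)
    equals ``1/n * n = 1`` after rescaling by ``n``.  ``delta_hat`` is the
    mean gap between consecutive sorted rank means, which telescopes to
    ``(b - a)/(n - 1)`` exactly.
    """

    rbar: np.ndarray
    a: float
    b: float
    delta_hat: float
    R_bar: float
    sigma2_hat: float
    trim: float

    @property
    def delta(self) -> float:
        """``delta_hat`` rescaled to the integer-rank scale (interval [0, 1]
        of the dataset size range, as commonly monitored)."""
        n = self.rbar.size
        return self.delta_hat * n

    def theoretical(self) -> tuple[float, float]:
        """Normal-model moments implied by (a, b, n, delta) alone."""
        return theoretical_moments(self.a, self.b, self.rbar.size, self.delta_hat)


@dataclass
class FcrosResult:
    """Per-gene FCROS output plus the fitted rank model."""

    gene_ids: list[str]
    rbar: np.ndarray
    f_value: np.ndarray
    fold_change: np.ndarray
    call: np.ndarray  # strings: "down" | "EE" | "up"
    alpha1: float
    alpha2: float
    error_percent: float
    summary: RankSummary

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def de_indices(self) -> np.ndarray:
        return np.flatnonzero(self.call != "EE")


# ---------------------------------------------------------------------------
# step 1: pairing, fold changes, ranks


def build_pairing(m1: int, m2: int, k: int | str = "all") -> list[tuple[int, int]]:
    """Enumerate the (control, test) column pairs for the k comparisons.

    The full grid is walked in control-major order
    ``(c0,t0), (c0,t1), ..., (c1,t0), ...``; when ``k`` is below the
    maximum ``m1*m2`` the first ``k`` pairs of that canonical order are
    used, which keeps runs reproducible.
    """
    if m1 < 1 or m2 < 1:
        raise ValueError("need at least one sample per group")
    kmax = m1 * m2
    if k == "all":
        k = kmax
    k = int(k)
    if not 1 <= k <= kmax:
        raise ValueError(f"k must be in [1, {kmax}], got {k}")
    grid = [(c, t) for c in range(m1) for t in range(m2)]
    return grid[:k]


def compute_pairwise_fc(
    data: ExpressionMatrix, pairing: list[tuple[int, int]]
) -> np.ndarray:
    """Per-gene log2 fold change (test minus control) for each pair.

    Group-local pair indices refer to positions within the control / test
    groups.  Since inputs are log2 values the difference equals the log2 of
    the test/control ratio; ranking downstream is invariant under the
    monotone ``2**x`` map, so the log scale is used throughout.
    """
    ctl = data.control_values
    tst = data.test_values
    for c, t in pairing:
        if not (0 <= c < ctl.shape[1]) or not (0 <= t < tst.shape[1]):
            raise ValueError(f"pair ({c}, {t}) out of range for groups "
                             f"({ctl.shape[1]}, {tst.shape[1]})")
    cs = [c for c, _ in pairing]
    ts = [t for _, t in pairing]
    return tst[:, ts] - ctl[:, cs]


def rank_columns(fc: np.ndarray) -> np.ndarray:
    """Ascending ranks per column with midranks on ties.

    Each comparison's n fold changes are sorted in increasing order and
    genes receive the corresponding ranks ``1..n``; tied values get the
    average of the integer ranks they span, so every column sums to
    ``n(n+1)/2`` exactly.
    """
    fc = np.asarray(fc, dtype=float)
    if fc.ndim == 1:
        fc = fc[:, None]
    if fc.shape[0] < 2:
        raise ValueError("need at least 2 genes to rank")
    if not np.all(np.isfinite(fc)):
        raise ValueError("non-finite fold change encountered")
    return stats.rankdata(fc, method="average", axis=0)


# ---------------------------------------------------------------------------
# steps 2-3: trimmed rank means, model fit


def trimmed_rank_means(ranks: np.ndarray | PairwiseRanks, trim: float = 0.3) -> np.ndarray:
    """Standardized trimmed mean of each gene's ranks.

    For each gene the k ranks are sorted, ``g = floor(k*trim)`` values are
    dropped from each end (so ``trim = 0.1`` keeps 80% of the ranks when k
    is a multiple of 10), the remainder is averaged and divided by n.  The
    result lies in ``(0, 1]``.
    """
    if isinstance(ranks, PairwiseRanks):
        ranks = ranks.ranks
    ranks = np.asarray(ranks, dtype=float)
    n, k = ranks.shape
    if not 0 <= trim < 0.5:
        raise ValueError(f"trim must be in [0, 0.5), got {trim}")
    g = int(np.floor(k * trim))
    if k - 2 * g < 1:
        raise ValueError(f"trim={trim} leaves no ranks out of k={k}")
    srt = np.sort(ranks, axis=1)
    kept = srt[:, g : k - g] if g else srt
    return kept.mean(axis=1) / n


def fit_rank_model(rbar: np.ndarray, trim: float = 0.3) -> RankSummary:
    """Fit the equally-spaced-grid rank model to standardized rank means.

    Returns the extremes ``a``/``b``, the mean consecutive gap
    ``delta_hat`` (exactly ``(b - a)/(n - 1)`` by telescoping), the sample
    mean ``R_bar`` and the unbiased sample variance ``sigma2_hat``, all on
    the standardized scale.
    """
    rbar = np.asarray(rbar, dtype=float)
    n = rbar.size
    if n < 2:
        raise ValueError("need at least 2 genes")
    if np.any(rbar <= 0) or np.any(rbar > 1):
        raise ValueError("standardized rank means must lie in (0, 1]")
    a = float(rbar.min())
    b = float(rbar.max())
    srt = np.sort(rbar)
    # mean of consecutive sorted differences; telescopes to (b - a)/(n - 1)
    delta_hat = float(np.diff(srt).mean())
    R_bar = float(rbar.mean())
    sigma2_hat = float(rbar.var(ddof=1))
    if sigma2_hat == 0.0:
        raise ValueError(
            "all rank means identical (zero variance): f-values undefined"
        )
    return RankSummary(
        rbar=rbar, a=a, b=b, delta_hat=delta_hat,
        R_bar=R_bar, sigma2_hat=sigma2_hat, trim=trim,
    )


# ---------------------------------------------------------------------------
# steps 4-5: f-values, classification


def compute_f_values(rbar: np.ndarray, summary: RankSummary) -> np.ndarray:
    """Normal CDF of the standardized rank means under the fitted model.

    ``f_i = Phi((rbar_i - R_bar) / sigma_hat)``.  Values are clipped away
    from exact 0/1 only by floating point, never by policy: they are
    strictly inside (0, 1) for finite inputs.
    """
    if summary.sigma2_hat <= 0:
        raise ValueError("degenerate rank-model variance")
    z = (np.asarray(rbar, dtype=float) - summary.R_bar) / np.sqrt(summary.sigma2_hat)
    return stats.norm.cdf(z)


def selection_error_percent(alpha1: float, alpha2: float) -> float:
    """Expected selection error 100*(alpha1 + 1 - alpha2) in percent."""
    if not 0 < alpha1 < alpha2 < 1:
        raise ValueError(
            f"need 0 < alpha1 < alpha2 < 1, got ({alpha1}, {alpha2})"
        )
    return 100.0 * (alpha1 + 1.0 - alpha2)


def classify_genes(
    f_values: np.ndarray, alpha1: float = 0.025, alpha2: float = 0.975
) -> tuple[np.ndarray, float]:
    """Three-way call per gene from its f-value.

    Genes with ``f <= alpha1`` are called down-regulated, ``f >= alpha2``
    up-regulated, the rest equally expressed; the expected error of the
    selection is ``100*(alpha1 + 1 - alpha2)`` percent.
    """
    err = selection_error_percent(alpha1, alpha2)
    f = np.asarray(f_values, dtype=float)
    call = np.full(f.shape, "EE", dtype=object)
    call[f <= alpha1] = "down"
    call[f >= alpha2] = "up"
    return call, err


# ---------------------------------------------------------------------------
# fold change and theory


def fold_changes(data: ExpressionMatrix, geometric: bool = False) -> np.ndarray:
    """Per-gene fold change of test over control on the unlogged scale.

    For one-color (log2-intensity) data the classical ratio of arithmetic
    means of unlogged values is used:
    ``mean(2**x_test) / mean(2**x_control)``.  For two-color (log2-ratio)
    data absolute intensities are unavailable, so the geometric-mean form
    ``2**(mean(x_test) - mean(x_control))`` is reported instead; it is
    rank-equivalent.  ``geometric=True`` forces the latter for any input.
    """
    if geometric or data.scale_tag == "log2-ratio":
        return 2.0 ** (data.test_values.mean(axis=1) - data.control_values.mean(axis=1))
    num = np.exp2(data.test_values).mean(axis=1)
    den = np.exp2(data.control_values).mean(axis=1)
    return num / den


def gene_fold_change(data: ExpressionMatrix, gene_index: int, geometric: bool = False) -> float:
    """Fold change of a single gene; see :func:`fold_changes`."""
    if not 0 <= gene_index < data.n_genes:
        raise IndexError(f"gene index {gene_index} out of range")
    return float(fold_changes(data, geometric=geometric)[gene_index])


def theoretical_moments(
    a: float, b: float, n: int, delta: float
) -> tuple[float, float]:
    """Normal-model mean and variance for an equally spaced rank grid.

    For ordered rank means ``a, a+delta, ..., a+(n-1)delta = b`` the
    population mean is ``(a + b)/2`` and the population variance is
    ``(n**2 - 1)/12 * delta**2``; the ideal case ``a = delta = 1, b = n``
    gives ``(n+1)/2`` and ``(n**2 - 1)/12``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if b < a:
        raise ValueError("b must be >= a")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    return (a + b) / 2.0, (n * n - 1.0) / 12.0 * delta * delta


# ---------------------------------------------------------------------------
# pipelines


def _from_fc_columns(
    gene_ids: list[str],
    fc_cols: np.ndarray,
    pairing: list[tuple[int, int]],
    fold_change: np.ndarray,
    trim: float,
    alpha1: float,
    alpha2: float,
) -> FcrosResult:
    ranks = rank_columns(fc_cols)
    rbar = trimmed_rank_means(ranks, trim=trim)
    summary = fit_rank_model(rbar, trim=trim)
    f = compute_f_values(rbar, summary)
    call, err = classify_genes(f, alpha1, alpha2)
    return FcrosResult(
        gene_ids=gene_ids, rbar=rbar, f_value=f, fold_change=fold_change,
        call=call, alpha1=alpha1, alpha2=alpha2, error_percent=err,
        summary=summary,
    )


def fcros(
    data: ExpressionMatrix,
    trim: float = 0.3,
    k: int | str = "all",
    alpha1: float = 0.025,
    alpha2: float = 0.975,
) -> FcrosResult:
    """Run the full FCROS pipeline on a two-condition matrix.

    Deterministic: pairing, ranking, trimming, model fit and thresholds
    involve no randomness.

    Parameters
    ----------
    data
        Validated two-condition matrix.
    trim
        Fraction of ranks dropped from each end of every gene's sorted
        rank vector; ``k - 2*floor(k*trim)`` ranks are kept.  Default 0.3.
    k
        Number of pairwise comparisons, ``"all"`` for the full
        ``m1 * m2`` grid.
    alpha1, alpha2
        f-value thresholds for the down-/up-regulated calls.
    """
    pairing = build_pairing(data.m1, data.m2, k)
    fc_cols = compute_pairwise_fc(data, pairing)
    return _from_fc_columns(
        data.gene_ids, fc_cols, pairing, fold_changes(data),
        trim, alpha1, alpha2,
    )


def fcros2(
    batch1: ExpressionMatrix,
    batch2: ExpressionMatrix,
    trim: float = 0.3,
    alpha1: float = 0.025,
    alpha2: float = 0.975,
) -> FcrosResult:
    """Two-batch FCROS: pool within-batch comparisons, no normalization.

    Pairwise fold-change columns are formed strictly within each batch
    (``k = k1 + k2`` with ``k1 = m1*m2`` of batch 1 and ``k2`` of batch 2)
    and then ranked per column, so a global additive offset between batches
    cancels inside each comparison and never crosses batches.  Both batches
    must carry the same genes in the same order.

    The reported fold change averages the two per-batch fold changes
    geometrically, consistent with treating batches symmetrically.
    """
    if batch1.gene_ids != batch2.gene_ids:
        for g1, g2 in zip(batch1.gene_ids, batch2.gene_ids):
            if g1 != g2:
                raise ValueError(
                    f"gene id mismatch between batches: {g1!r} vs {g2!r}"
                )
        raise ValueError(
            "batches carry different numbers of genes: "
            f"{batch1.n_genes} vs {batch2.n_genes}"
        )
    p1 = build_pairing(batch1.m1, batch1.m2, "all")
    p2 = build_pairing(batch2.m1, batch2.m2, "all")
    fc_cols = np.hstack([
        compute_pairwise_fc(batch1, p1),
        compute_pairwise_fc(batch2, p2),
    ])
    fc_combined = np.sqrt(fold_changes(batch1) * fold_changes(batch2))
    return _from_fc_columns(
        batch1.gene_ids, fc_cols, p1 + p2, fc_combined, trim, alpha1, alpha2,
    )
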