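"""Two-condition expression matrix container.

The basic input object for all statistics in this package: a genes x samples
matrix of log2-scale expression values together with the assignment of
columns to the control and test groups.  For one-color platforms the values
are log2 intensities (``scale_tag="log2-intensity"``); for two-color
platforms they are log2 ratios (``scale_tag="log2-ratio"``), in which case
absolute intensities are unavailable and reported fold changes fall back to
the geometric-mean definition (see :func:`fcros.core.gene_fold_change`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

SCALE_TAGS = ("log2-intensity", "log2-ratio")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression values with group labels.

    Parameters
    ----------
    gene_ids
        Unique identifier per row (length ``n``).
    values
        ``(n, m1 + m2)`` array of finite log2-scale values.
    control_indices
        Column indices of the ``m1`` control samples.
    test_indices
        Column indices of the ``m2`` test samples (disjoint from control).
    scale_tag
        ``"log2-intensity"`` (one-color) or ``"log2-ratio"`` (two-color).
    sample_ids
        Optional column names; defaults to ``s0 .. s{m-1}``.
    """

    gene_ids: list[str]
    values: np.ndarray
    control_indices: list[int]
    test_indices: list[int]
    scale_tag: str = "log2-intensity"
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.control_indices = [int(i) for i in self.control_indices]
        self.test_indices = [int(i) for i in self.test_indices]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        n, m = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 genes, got {n}")
        if len(self.gene_ids) != n:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n} matrix rows"
            )
        if len(set(self.gene_ids)) != n:
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise ValueError(f"duplicate gene id: {dup!r}")
        if not self.control_indices or not self.test_indices:
            raise ValueError("both sample groups must be non-empty")
        ctl, tst = set(self.control_indices), set(self.test_indices)
        if len(ctl) != len(self.control_indices) or len(tst) != len(self.test_indices):
            raise ValueError("repeated column index within a group")
        if ctl & tst:
            raise ValueError(f"columns assigned to both groups: {sorted(ctl & tst)}")
        declared = ctl | tst
        if not declared <= set(range(m)):
            raise ValueError("group index out of range for matrix columns")
        if len(declared) != m:
            raise ValueError("every matrix column must belong to a group")
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"scale_tag must be one of {SCALE_TAGS}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value for gene {self.gene_ids[i]!r}, "
                f"sample column {j}"
            )
        if not self.sample_ids:
            self.sample_ids = [f"s{j}" for j in range(m)]
        elif len(self.sample_ids) != m:
            raise ValueError("sample_ids length does not match column count")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def m1(self) -> int:
        return len(self.control_indices)

    @property
    def m2(self) -> int:
        return len(self.test_indices)

    @property
    def control_values(self) -> np.ndarray:
        """(n, m1) view of the control columns."""
        return self.values[:, self.control_indices]

    @property
    def test_values(self) -> np.ndarray:
        """(n, m2) view of the test columns."""
        return self.values[:, self.test_indices]

    def swapped(self) -> "ExpressionMatrix":
        """Same data with the control and test roles exchanged."""
        return ExpressionMatrix(
            gene_ids=self.gene_ids,
            values=self.values.copy(),
            control_indices=self.test_indices,
            test_indices=self.control_indices,
            scale_tag=self.scale_tag,
            sample_ids=self.sample_ids,
        )


def from_groups(
    gene_ids: Sequence[str],
    control: np.ndarray,
    test: np.ndarray,
    scale_tag: str = "log2-intensity",
) -> ExpressionMatrix:
    """Build an :class:`ExpressionMatrix` from separate group matrices."""
    control = np.atleast_2d(np.asarray(control, dtype=float))
    test = np.atleast_2d(np.asarray(test, dtype=float))
    if control.shape[0] != test.shape[0]:
        raise ValueError("control and test must have the same gene count")
    m1, m2 = control.shape[1], test.shape[1]
    return ExpressionMatrix(
        gene_ids=list(gene_ids),
        values=np.hstack([control, test]),
        control_indices=list(range(m1)),
        test_indices=list(range(m1, m1 + m2)),
        scale_tag=scale_tag,
    )
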