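"""Readers and writers for expression tables, designs, results and truth.

All formats are plain text: TSV/CSV matrices (first column gene id, one
column per sample), a two-column design file mapping sample ids to
``control``/``test``, a per-gene result TSV with a key-value summary
sidecar, and a truth TSV for simulated data.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import FcrosResult
from .matrix import ExpressionMatrix
from .synthetic import SyntheticDataset

__all__ = ["read_design", "read_expression_table", "write_expression_table",
           "write_results", "read_results", "write_truth", "read_truth"]

_SEP = {".csv": ",", ".tsv": "\t", ".txt": "\t"}


def _sep_for(path: Path) -> str:
    return _SEP.get(path.suffix.lower(), "\t")


def read_design(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group) table; group is control/test."""
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     comment="#", skip_blank_lines=True)
    if df.shape[1] != 2:
        raise ValueError(f"design file must have 2 columns, got {df.shape[1]}")
    if {"sample_id", "group"} == set(str(x).strip() for x in df.iloc[0]):
        df = df.iloc[1:]
    design = {}
    for _, (sid, grp) in df.iterrows():
        grp = str(grp).strip().lower()
        if grp not in ("control", "test"):
            raise ValueError(f"group for sample {sid!r} must be control or test, got {grp!r}")
        design[str(sid).strip()] = grp
    return design


def read_expression_table(
    path: str | Path,
    design: dict[str, str] | str | Path | None = None,
    control: Sequence[str] | None = None,
    test: Sequence[str] | None = None,
    scale_tag: str = "log2-intensity",
) -> ExpressionMatrix:
    """Read a TSV/CSV expression table into a validated matrix.

    The first column holds gene ids, remaining columns one sample each.
    Groups come either from a design mapping/file or from explicit
    ``control``/``test`` sample-id lists; samples named in neither are an
    error, as is a duplicated gene id or a non-numeric cell.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=0, dtype={0: str},
                     float_precision="round_trip")
    if df.shape[1] < 3:
        raise ValueError("expression table needs a gene id column and >= 2 samples")
    gene_ids = df.iloc[:, 0].astype(str).tolist()
    dup = df.iloc[:, 0][df.iloc[:, 0].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene id: {dup.iloc[0]!r}")
    sample_ids = [str(c) for c in df.columns[1:]]
    try:
        values = df.iloc[:, 1:].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        for j, col in enumerate(df.columns[1:], start=1):
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                i = int(bad.isna().idxmax())
                raise ValueError(
                    f"non-numeric value {df.iloc[i, j]!r} at gene "
                    f"{gene_ids[i]!r}, sample {col!r}"
                ) from exc
        raise

    if design is not None:
        if not isinstance(design, dict):
            design = read_design(design)
        missing = [s for s in design if s not in sample_ids]
        if missing:
            raise ValueError(f"design names absent samples: {missing}")
        control = [s for s in sample_ids if design.get(s) == "control"]
        test = [s for s in sample_ids if design.get(s) == "test"]
    if control is None or test is None:
        raise ValueError("provide a design or explicit control/test sample lists")
    unknown = [s for s in list(control) + list(test) if s not in sample_ids]
    if unknown:
        raise ValueError(f"unknown sample ids: {unknown}")
    col_of = {s: j for j, s in enumerate(sample_ids)}
    return ExpressionMatrix(
        gene_ids=gene_ids,
        values=values,
        control_indices=[col_of[s] for s in control],
        test_indices=[col_of[s] for s in test],
        scale_tag=scale_tag,
        sample_ids=sample_ids,
    )


def write_expression_table(data: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix back to TSV/CSV at full float precision."""
    path = Path(path)
    df = pd.DataFrame(data.values, columns=data.sample_ids)
    df.insert(0, "gene_id", data.gene_ids)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def write_results(result: FcrosResult, path: str | Path) -> None:
    """Write per-gene results as TSV plus a key-value summary sidecar.

    The sidecar (``<path>.summary.txt``) records the fitted rank-model
    diagnostics (a, b, delta, R_bar, sigma2) and the run parameters so the
    normal-model quality can be audited after the fact.
    """
    path = Path(path)
    df = pd.DataFrame({
        "gene_id": result.gene_ids,
        "rbar": result.rbar,
        "f_value": result.f_value,
        "fold_change": result.fold_change,
        "call": result.call,
    })
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")
    s = result.summary
    sidecar = path.with_name(path.name + ".summary.txt")
    lines = {
        "n_genes": result.n_genes,
        "trim": s.trim,
        "a": s.a,
        "b": s.b,
        "delta_hat": s.delta_hat,
        "delta": s.delta,
        "R_bar": s.R_bar,
        "sigma2_hat": s.sigma2_hat,
        "alpha1": result.alpha1,
        "alpha2": result.alpha2,
        "error_percent": result.error_percent,
        "n_down": int(np.count_nonzero(result.call == "down")),
        "n_up": int(np.count_nonzero(result.call == "up")),
    }
    sidecar.write_text(
        "".join(f"{k}\t{v!r}\n" if isinstance(v, str) else f"{k}\t{v:.17g}\n"
                for k, v in lines.items())
    )


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a per-gene result TSV back into a DataFrame."""
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")


def write_truth(ds: SyntheticDataset, path: str | Path) -> None:
    """Write simulation ground truth: gene_id, is_de, true_lfc."""
    path = Path(path)
    is_de = np.zeros(ds.matrix.n_genes, dtype=int)
    is_de[ds.de_indices] = 1
    pd.DataFrame({
        "gene_id": ds.matrix.gene_ids,
        "is_de": is_de,
        "true_lfc": ds.true_lfc,
    }).to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def read_truth(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
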