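"""Matrix-equivalence metrics.

Quantifies agreement between two result matrices — e.g. two implementations
of the same import pipeline, or two serializations of one result — as the
Pearson correlation, mean absolute error and mean squared error over all
matrix cells (flattened).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import ValidationError
from .export import FORMATS, read_result

__all__ = ["ComparisonMetrics", "compare_matrices", "compare_trees"]


@dataclass
class ComparisonMetrics:
    """Cell-wise agreement between two equally shaped matrices.

    ``pearson_r`` is ``None`` when either flattened matrix is constant
    (zero variance makes the correlation undefined).
    """

    pearson_r: Optional[float]
    mae: float
    mse: float
    n_cells: int

    def as_row(self) -> dict:
        return {
            "pearson_r": np.nan if self.pearson_r is None else self.pearson_r,
            "mae": self.mae,
            "mse": self.mse,
            "n_cells": self.n_cells,
        }


def _to_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def compare_matrices(X, Y, align: bool = False) -> ComparisonMetrics:
    """Compare two matrices cell by cell.

    With ``align``, both are sorted by row and column labels first; label
    sets must then match exactly.  Without ``align``, shapes must match and
    cells are compared positionally.
    """
    X = _to_frame(X)
    Y = _to_frame(Y)
    if align:
        missing_rows = set(X.index) ^ set(Y.index)
        missing_cols = set(X.columns) ^ set(Y.columns)
        if missing_rows or missing_cols:
            raise ValidationError(
                "label mismatch between matrices; differing row labels: "
                f"{sorted(missing_rows)[:10]}, differing column labels: "
                f"{sorted(missing_cols)[:10]}"
            )
        X = X.sort_index(axis=0).sort_index(axis=1)
        Y = Y.sort_index(axis=0).sort_index(axis=1)
    if X.shape != Y.shape:
        raise ValidationError(f"shape mismatch: {X.shape} vs {Y.shape}")
    x = X.to_numpy(dtype=float).ravel()
    y = Y.to_numpy(dtype=float).ravel()
    diff = x - y
    mae = float(np.mean(np.abs(diff)))
    mse = float(np.mean(diff ** 2))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r: Optional[float] = None
    elif np.array_equal(x, y):
        r = 1.0  # correlation with itself is exactly 1 by definition
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return ComparisonMetrics(pearson_r=r, mae=mae, mse=mse, n_cells=x.size)


def compare_trees(path_a: str | Path, path_b: str | Path,
                  fmt_a: str = "tsv", fmt_b: Optional[str] = None) -> pd.DataFrame:
    """Compare the abundance/counts/length matrices of two stored results.

    Reads both results (CSV/TSV prefixes or h5ad files, possibly of
    different formats), aligns by feature and sample labels, and returns a
    tidy per-matrix report with columns ``matrix``, ``pearson_r``, ``mae``,
    ``mse``, ``n_cells``.
    """
    if fmt_b is None:
        fmt_b = fmt_a
    for f in (fmt_a, fmt_b):
        if f not in FORMATS:
            raise ValidationError(f"unknown format {f!r}; valid formats: {FORMATS}")
    a = read_result(path_a, fmt_a)
    b = read_result(path_b, fmt_b)
    rows = []
    for name in ("abundance", "counts", "length"):
        m = compare_matrices(a[name], b[name], align=True)
        rows.append({"matrix": name, **m.as_row()})
    return pd.DataFrame(rows)
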