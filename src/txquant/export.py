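"""Serialization of quantification results.

A :class:`~txquant.core.QuantResult` can be exported as an AnnData container
(samples-by-features, with counts in ``X`` and abundance/length as layers —
the scverse convention) or as plain CSV/TSV matrices (features-by-samples —
the convention of R-side differential-expression tools).
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from . import __version__
from .core import ParseError, QuantResult, ValidationError

__all__ = ["to_annotated", "write_result", "read_result", "FORMATS"]

FORMATS = ("h5ad", "csv", "tsv")
MATRIX_SUFFIXES = ("counts", "abundance", "length")
_TEXT_FMT = "%.15g"  # full double precision in text output


def to_annotated(result: QuantResult) -> ad.AnnData:
    """Build an AnnData: X = counts (samples x features), layers for the rest.

    Unreduced inferential replicates cannot be carried in the flat
    container; reduce them (``var_reduce``) or drop them first.  A variance
    matrix, when present, is stored as the layer ``"inf_rep_variance"``.
    """
    if result.inf_reps is not None:
        raise ValidationError(
            "result carries raw inferential replicates; apply a replicate "
            "policy first (drop_inf_reps, var_reduce or inf_rep_stat)"
        )
    obs = pd.DataFrame(index=pd.Index(result.sample_ids, name="sample_id"))
    obs["source_path"] = (result.source_paths
                          if len(result.source_paths) == len(result.sample_ids)
                          else [""] * len(result.sample_ids))
    obs["tool"] = result.tool
    var = pd.DataFrame(index=pd.Index(result.feature_ids, name="feature_id"))
    var["level"] = result.level
    layers = {
        "abundance": result.abundance.to_numpy(dtype=float).T,
        "length": result.length.to_numpy(dtype=float).T,
    }
    if result.inf_rep_variance is not None:
        layers["inf_rep_variance"] = result.inf_rep_variance.to_numpy(dtype=float).T
    adata = ad.AnnData(
        X=result.counts.to_numpy(dtype=float).T,
        obs=obs,
        var=var,
        layers=layers,
    )
    adata.uns["counts_from_abundance"] = result.counts_from_abundance
    adata.uns["tool"] = result.tool
    adata.uns["txquant_version"] = __version__
    return adata


def _matrix_paths(prefix: Path, sep_name: str) -> dict[str, Path]:
    return {m: prefix.with_name(prefix.name + f".{m}") for m in MATRIX_SUFFIXES}


def write_result(result: QuantResult, out_path: str | Path, fmt: str,
                 force: bool = False) -> list[Path]:
    """Write a result to disk; returns the paths written.

    ``h5ad`` writes one annotated container.  ``csv``/``tsv`` write three
    files ``<prefix>.counts``, ``<prefix>.abundance``, ``<prefix>.length``
    with features as rows, samples as columns and a header of sample ids.
    Existing files are only replaced with ``force``.
    """
    if fmt not in FORMATS:
        raise ValidationError(f"unknown format {fmt!r}; valid formats: {FORMATS}")
    if len(result.feature_ids) == 0:
        raise ValidationError("result contains no features; nothing written")
    out_path = Path(out_path)
    if fmt == "h5ad":
        if out_path.exists() and not force:
            raise ValidationError(f"{out_path} exists; pass force to overwrite")
        out_path.parent.mkdir(parents=True, exist_ok=True)
        to_annotated(result).write_h5ad(out_path)
        return [out_path]
    sep = "," if fmt == "csv" else "\t"
    paths = _matrix_paths(out_path, fmt)
    for p in paths.values():
        if p.exists() and not force:
            raise ValidationError(f"{p} exists; pass force to overwrite")
    out_path.parent.mkdir(parents=True, exist_ok=True)
    for name, p in paths.items():
        df = getattr(result, name)
        df.to_csv(p, sep=sep, float_format=_TEXT_FMT, index_label="feature_id")
    return list(paths.values())


def read_result(path: str | Path, fmt: str) -> dict[str, pd.DataFrame]:
    """Read matrices written by :func:`write_result`.

    Returns features-by-samples DataFrames keyed ``counts``, ``abundance``,
    ``length``.  For ``csv``/``tsv``, ``path`` is the prefix used when
    writing; for ``h5ad`` it is the container file.
    """
    if fmt not in FORMATS:
        raise ValidationError(f"unknown format {fmt!r}; valid formats: {FORMATS}")
    path = Path(path)
    if fmt == "h5ad":
        if not path.exists():
            raise ParseError(f"result file not found: {path}")
        adata = ad.read_h5ad(path)
        idx = adata.var_names
        cols = adata.obs_names
        return {
            "counts": pd.DataFrame(np.asarray(adata.X).T, index=idx, columns=cols),
            "abundance": pd.DataFrame(adata.layers["abundance"].T,
                                      index=idx, columns=cols),
            "length": pd.DataFrame(adata.layers["length"].T,
                                   index=idx, columns=cols),
        }
    sep = "," if fmt == "csv" else "\t"
    out = {}
    for name, p in _matrix_paths(path, fmt).items():
        if not p.exists():
            raise ParseError(f"result matrix file not found: {p}")
        out[name] = pd.read_csv(p, sep=sep, index_col=0)
    return out
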