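"""Transcript-to-gene summarization and count scaling.

Implements the aggregation rules used throughout the RNA-seq ecosystem:
gene abundance and gene counts are sums over member transcripts; gene
effective length is the abundance-weighted mean of member-transcript
effective lengths, with a geometric-mean imputation when a gene has zero
abundance in a sample; counts-from-abundance rescales TPM back to each
sample's total count (optionally weighting by the across-sample mean
length) so downstream models need no length offset.  Inferential replicates
(bootstrap or Gibbs re-estimates) can be summarized alongside, reduced to a
variance matrix, or collapsed to a point estimate.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    InfReps,
    QuantResult,
    Tx2Gene,
    ValidationError,
    match_tx2gene,
    strip_ids,
)

__all__ = [
    "sum_by_gene",
    "gene_effective_length",
    "replace_missing_length",
    "counts_from_abundance",
    "summarize_infreps",
    "var_reduce",
    "apply_infrep_stat",
    "summarize_to_gene",
]

CFA_MODES = ("no", "scaledTPM", "lengthScaledTPM")


def _gene_indicator(assignment: Sequence[Optional[str]],
                    gene_order: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Rows to keep and the gene row index each kept transcript maps to."""
    gene_pos = {g: i for i, g in enumerate(gene_order)}
    keep = np.array([a is not None for a in assignment], dtype=bool)
    idx = np.array([gene_pos[a] for a in assignment if a is not None], dtype=int)
    return keep, idx


def sum_by_gene(M: np.ndarray, assignment: Sequence[Optional[str]],
                gene_order: Sequence[str]) -> np.ndarray:
    """Sum transcript rows into gene rows.

    ``out[g, j] = sum over transcripts t assigned to g of M[t, j]``;
    transcripts with ``None`` assignment are excluded.  Rows follow
    ``gene_order``.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValidationError("matrix must be 2-D (features x samples)")
    if M.shape[0] != len(assignment):
        raise ValidationError(
            f"matrix has {M.shape[0]} rows but assignment has {len(assignment)}"
        )
    keep, idx = _gene_indicator(assignment, gene_order)
    out = np.zeros((len(gene_order), M.shape[1]), dtype=float)
    np.add.at(out, idx, M[keep])
    return out


def gene_effective_length(A_tx: np.ndarray, L_tx: np.ndarray,
                          assignment: Sequence[Optional[str]],
                          gene_order: Sequence[str]) -> np.ndarray:
    """Abundance-weighted mean effective length per gene.

    ``L_gene[g, j] = sum_t A[t,j] L[t,j] / sum_t A[t,j]`` over member
    transcripts.  Cells where the gene's abundance is zero are returned as
    NaN and must be imputed by :func:`replace_missing_length` before use.
    """
    A_tx = np.asarray(A_tx, dtype=float)
    L_tx = np.asarray(L_tx, dtype=float)
    if A_tx.shape != L_tx.shape:
        raise ValidationError("abundance and length matrices must share shape")
    if np.any(A_tx < 0):
        raise ValidationError("negative abundance encountered")
    weighted = sum_by_gene(A_tx * L_tx, assignment, gene_order)
    total = sum_by_gene(A_tx, assignment, gene_order)
    with np.errstate(invalid="ignore", divide="ignore"):
        L_gene = weighted / total
    L_gene[total == 0] = np.nan
    return L_gene


def replace_missing_length(L_gene: np.ndarray,
                           ave_len_gene: np.ndarray) -> np.ndarray:
    """Impute NaN cells of a gene-level length matrix.

    For a gene row with at least one defined cell, NaNs become the geometric
    mean ``exp(mean(log L))`` of the row's defined cells.  A fully undefined
    row is filled with ``ave_len_gene[g]``, the mean over member transcripts
    of each transcript's across-sample mean effective length.  The result is
    strictly positive.
    """
    L = np.array(L_gene, dtype=float)
    ave = np.asarray(ave_len_gene, dtype=float)
    if L.shape[0] != len(ave):
        raise ValidationError("ave_len_gene length mismatch")
    for g in range(L.shape[0]):
        row = L[g]
        defined = ~np.isnan(row)
        if defined.all():
            continue
        if defined.any():
            vals = row[defined]
            if np.any(vals <= 0):
                raise ValidationError(
                    f"nonpositive defined length in gene row {g}; "
                    "cannot take geometric mean"
                )
            row[~defined] = np.exp(np.mean(np.log(vals)))
        else:
            row[:] = ave[g]
    if np.any(~(L > 0)):
        raise ValidationError("imputed length matrix is not strictly positive")
    return L


def counts_from_abundance(C: np.ndarray, A: np.ndarray, L: np.ndarray,
                          mode: str) -> np.ndarray:
    """Rescale abundance into counts, preserving per-sample totals.

    ``scaledTPM`` allocates each sample's original total count proportionally
    to abundance; ``lengthScaledTPM`` first multiplies abundance by the
    across-sample mean length of each feature, then rescales.  Library sizes
    are always the ORIGINAL count column sums.  ``no`` returns counts
    unchanged.
    """
    if mode == "dtuScaledTPM":
        raise ValidationError("unsupported counts-from-abundance mode: dtuScaledTPM")
    if mode not in CFA_MODES:
        raise ValidationError(
            f"unknown counts-from-abundance mode {mode!r}; valid: {CFA_MODES}"
        )
    C = np.asarray(C, dtype=float)
    if mode == "no":
        return C.copy()
    A = np.asarray(A, dtype=float)
    L = np.asarray(L, dtype=float)
    if C.shape != A.shape or C.shape != L.shape:
        raise ValidationError("count, abundance and length matrices must share shape")
    if mode == "lengthScaledTPM":
        B = A * L.mean(axis=1, keepdims=True)
    else:
        B = A
    lib_size = C.sum(axis=0)
    denom = B.sum(axis=0)
    bad = (denom == 0) & (lib_size > 0)
    if np.any(bad):
        j = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"sample column {j} has zero total abundance but nonzero counts; "
            "cannot derive counts from abundance"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(denom > 0, lib_size / np.where(denom > 0, denom, 1.0), 0.0)
    return B * scale


def summarize_infreps(reps: InfReps, assignment: Sequence[Optional[str]],
                      gene_order: Sequence[str]) -> InfReps:
    """Sum each replicate's transcript row into genes (same rule as counts)."""
    out = []
    for m in reps.per_sample:
        if m.shape[1] != len(assignment):
            raise ValidationError(
                f"replicate matrix has {m.shape[1]} features but assignment "
                f"has {len(assignment)}"
            )
        out.append(sum_by_gene(m.T, assignment, gene_order).T)
    return InfReps(n_reps=reps.n_reps, per_sample=out, rep_type=reps.rep_type)


def var_reduce(reps: InfReps) -> np.ndarray:
    """Per-feature, per-sample variance across replicates (n-1 denominator)."""
    if reps.n_reps < 2:
        raise ValidationError("var_reduce requires at least 2 inferential replicates")
    cols = [m.var(axis=0, ddof=1) for m in reps.per_sample]
    return np.column_stack(cols)


def apply_infrep_stat(reps: InfReps, stat: str,
                      L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse replicates to a point estimate and rebuild abundance.

    Counts become the per-cell ``mean`` or ``median`` over replicates;
    abundance is recomputed by TPM normalization against ``L`` (the matching
    feature-by-sample effective lengths), with 0/0 rate terms treated as 0.
    """
    if stat not in ("mean", "median"):
        raise ValidationError(f"unknown inferential-replicate statistic {stat!r}")
    fn = np.mean if stat == "mean" else np.median
    C = np.column_stack([fn(m, axis=0) for m in reps.per_sample])
    L = np.asarray(L, dtype=float)
    if L.shape != C.shape:
        raise ValidationError("length matrix shape mismatch")
    A = abundance_from_counts(C, L)
    return C, A


def abundance_from_counts(C: np.ndarray, L: np.ndarray) -> np.ndarray:
    """TPM normalization: ``A = (C/L) / sum(C/L) * 1e6`` with 0/0 -> 0."""
    C = np.asarray(C, dtype=float)
    L = np.asarray(L, dtype=float)
    bad = (L <= 0) & (C > 0)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"nonpositive effective length with positive count at "
            f"feature {i}, sample {j}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(C > 0, C / L, 0.0)
    total = rate.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(total > 0, rate / np.where(total > 0, total, 1.0) * 1e6, 0.0)
    return A


def summarize_to_gene(tx_result: QuantResult, tx2gene: Tx2Gene,
                      counts_from_abundance_mode: str = "no",
                      ignore_tx_version: bool = False,
                      ignore_after_bar: bool = False) -> QuantResult:
    """Aggregate a transcript-level result to gene level.

    Pipeline: strip and match transcript ids against the mapping; sum
    abundance and counts by gene; compute the abundance-weighted gene
    effective length and impute undefined cells; summarize inferential
    replicates if present; finally apply counts-from-abundance at gene
    level using the gene-level count column sums.
    """
    if tx_result.level != "transcript":
        raise ValidationError("summarize_to_gene requires a transcript-level result")
    tx_ids = strip_ids(tx_result.feature_ids,
                       ignore_tx_version=ignore_tx_version,
                       ignore_after_bar=ignore_after_bar)
    mapping = tx2gene.stripped(ignore_tx_version=ignore_tx_version,
                               ignore_after_bar=ignore_after_bar)
    assignment, _, gene_order = match_tx2gene(tx_ids, mapping)

    A_tx = tx_result.abundance.to_numpy(dtype=float)
    C_tx = tx_result.counts.to_numpy(dtype=float)
    L_tx = tx_result.length.to_numpy(dtype=float)

    A_gene = sum_by_gene(A_tx, assignment, gene_order)
    C_gene = sum_by_gene(C_tx, assignment, gene_order)
    L_gene = gene_effective_length(A_tx, L_tx, assignment, gene_order)

    # fallback average length: mean over member transcripts of each
    # transcript's across-sample mean effective length
    tx_mean_len = L_tx.mean(axis=1)
    gene_pos = {g: i for i, g in enumerate(gene_order)}
    sums = np.zeros(len(gene_order))
    ns = np.zeros(len(gene_order))
    for a, ml in zip(assignment, tx_mean_len):
        if a is not None:
            sums[gene_pos[a]] += ml
            ns[gene_pos[a]] += 1
    ave_len_gene = sums / ns
    L_gene = replace_missing_length(L_gene, ave_len_gene)

    gene_reps = None
    if tx_result.inf_reps is not None:
        gene_reps = summarize_infreps(tx_result.inf_reps, assignment, gene_order)

    C_gene = counts_from_abundance(C_gene, A_gene, L_gene,
                                   counts_from_abundance_mode)

    cols = tx_result.sample_ids
    return QuantResult(
        abundance=pd.DataFrame(A_gene, index=gene_order, columns=cols),
        counts=pd.DataFrame(C_gene, index=gene_order, columns=cols),
        length=pd.DataFrame(L_gene, index=gene_order, columns=cols),
        level="gene",
        counts_from_abundance=counts_from_abundance_mode,
        inf_reps=gene_reps,
        tool=tx_result.tool,
        source_paths=list(tx_result.source_paths),
    )
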