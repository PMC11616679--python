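"""Core domain types shared across txquant.

The central objects are :class:`SampleQuant` (one sample's transcript-level
estimates as parsed from a quantifier's output), :class:`QuantResult` (the
assembled multi-sample abundance/counts/length matrices at transcript or gene
level) and :class:`Tx2Gene` (an ordered transcript-to-gene mapping).  This
module also owns identifier normalization (version/annotation suffix
stripping) and transcript-to-gene matching, which every summarization path
goes through.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TxquantError",
    "ParseError",
    "ValidationError",
    "SampleQuant",
    "QuantResult",
    "Tx2Gene",
    "InfReps",
    "strip_ids",
    "match_tx2gene",
    "read_tx2gene",
]


class TxquantError(Exception):
    """Base class for all txquant errors."""


class ParseError(TxquantError):
    """A quantifier output file could not be parsed."""


class ValidationError(TxquantError):
    """Parsed data violates an internal consistency requirement."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    if np.any(arr < 0):
        raise ValidationError(f"{name} contains negative values")
    return arr


@dataclass
class SampleQuant:
    """Transcript-level estimates for a single sample.

    Parameters
    ----------
    tx_ids
        Ordered transcript identifiers, no duplicates.
    eff_length
        Effective length per transcript (bases, >= 0). The number of valid
        fragment start positions, used to convert counts to abundance.
    counts
        Estimated read count per transcript (>= 0, may be fractional).
    abundance
        Relative abundance in transcripts per million (TPM).
    ref_length
        Reference (annotated) transcript length in bases; ``None`` for
        generic inputs that do not report it.
    inf_reps
        Optional inferential-replicate count matrix, shape
        ``(n_reps, n_transcripts)``.
    inf_rep_type
        ``"none"``, ``"bootstrap"`` or ``"gibbs"``.
    """

    tx_ids: list[str]
    eff_length: np.ndarray
    counts: np.ndarray
    abundance: np.ndarray
    ref_length: Optional[np.ndarray] = None
    inf_reps: Optional[np.ndarray] = None
    inf_rep_type: str = "none"

    def __post_init__(self) -> None:
        self.tx_ids = list(self.tx_ids)
        n = len(self.tx_ids)
        if n == 0:
            raise ValidationError("sample contains no transcripts")
        seen: set[str] = set()
        for t in self.tx_ids:
            if t in seen:
                raise ValidationError(f"duplicate transcript id {t!r} in sample")
            seen.add(t)
        self.eff_length = _as_float_array(self.eff_length, "eff_length")
        self.counts = _as_float_array(self.counts, "counts")
        self.abundance = _as_float_array(self.abundance, "abundance")
        for name in ("eff_length", "counts", "abundance"):
            if len(getattr(self, name)) != n:
                raise ValidationError(
                    f"{name} has length {len(getattr(self, name))}, expected {n}"
                )
        if self.ref_length is not None:
            self.ref_length = _as_float_array(self.ref_length, "ref_length")
            if len(self.ref_length) != n:
                raise ValidationError("ref_length length mismatch")
        if self.inf_reps is not None:
            reps = np.asarray(self.inf_reps, dtype=float)
            if reps.ndim != 2 or reps.shape[1] != n:
                raise ValidationError(
                    f"inf_reps must be (n_reps, {n}), got {reps.shape}"
                )
            if not np.all(np.isfinite(reps)) or np.any(reps < 0):
                raise ValidationError("inf_reps contains non-finite or negative values")
            self.inf_reps = reps
        if self.inf_rep_type not in ("none", "bootstrap", "gibbs"):
            raise ValidationError(f"unknown inf_rep_type {self.inf_rep_type!r}")

    @property
    def n_transcripts(self) -> int:
        return len(self.tx_ids)


@dataclass
class InfReps:
    """Per-sample inferential-replicate matrices.

    ``per_sample[j]`` holds the replicate-by-feature count matrix of sample
    ``j``; all samples share ``n_reps`` and the feature dimension.
    """

    n_reps: int
    per_sample: list[np.ndarray]
    rep_type: str = "bootstrap"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")
        if not self.per_sample:
            raise ValidationError("per_sample must be nonempty")
        n_feat = self.per_sample[0].shape[1]
        mats = []
        for j, m in enumerate(self.per_sample):
            m = np.asarray(m, dtype=float)
            if m.shape != (self.n_reps, n_feat):
                raise ValidationError(
                    f"replicate matrix {j} has shape {m.shape}, "
                    f"expected {(self.n_reps, n_feat)}"
                )
            if not np.all(np.isfinite(m)) or np.any(m < 0):
                raise ValidationError(
                    f"replicate matrix {j} has non-finite or negative entries"
                )
            mats.append(m)
        self.per_sample = mats
        if self.rep_type not in ("bootstrap", "gibbs"):
            raise ValidationError(f"unknown rep_type {self.rep_type!r}")

    @property
    def n_features(self) -> int:
        return self.per_sample[0].shape[1]


@dataclass
class QuantResult:
    """Multi-sample quantification matrices at transcript or gene level.

    The three matrices (``abundance`` in TPM, ``counts`` in estimated reads,
    ``length`` in bases of effective length) are pandas DataFrames indexed by
    ``feature_ids`` with columns ``sample_ids``.  ``counts_from_abundance``
    records which scaling, if any, produced the count matrix.
    """

    abundance: pd.DataFrame
    counts: pd.DataFrame
    length: pd.DataFrame
    level: str = "transcript"
    counts_from_abundance: str = "no"
    inf_reps: Optional[InfReps] = None
    inf_rep_variance: Optional[pd.DataFrame] = None
    tool: str = "unknown"
    source_paths: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        shape = self.counts.shape
        if self.abundance.shape != shape or self.length.shape != shape:
            raise ValidationError(
                "abundance, counts and length matrices must share shape"
            )
        for name in ("abundance", "counts", "length"):
            df = getattr(self, name)
            vals = df.to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValidationError(f"{name} matrix contains non-finite values")
            if name != "length" and np.any(vals < 0):
                raise ValidationError(f"{name} matrix contains negative values")
        if self.level not in ("transcript", "gene"):
            raise ValidationError(f"unknown level {self.level!r}")
        if self.counts_from_abundance not in ("no", "scaledTPM", "lengthScaledTPM"):
            raise ValidationError(
                f"unknown counts_from_abundance {self.counts_from_abundance!r}"
            )
        if self.inf_reps is not None and self.inf_rep_variance is not None:
            raise ValidationError(
                "inf_reps and inf_rep_variance are mutually exclusive"
            )
        if self.inf_reps is not None:
            if self.inf_reps.n_features != shape[0]:
                raise ValidationError("inf_reps feature dimension mismatch")
            if len(self.inf_reps.per_sample) != shape[1]:
                raise ValidationError("inf_reps sample dimension mismatch")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class Tx2Gene:
    """Ordered transcript-to-gene mapping (one gene per transcript)."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValidationError("tx2gene mapping must contain at least one pair")
        seen: set[str] = set()
        for tx, gene in self.pairs:
            if not tx or not gene:
                raise ValidationError("tx2gene mapping contains an empty identifier")
            if tx in seen:
                raise ValidationError(
                    f"transcript {tx!r} appears more than once in tx2gene mapping"
                )
            seen.add(tx)

    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)

    def stripped(self, ignore_tx_version: bool = False,
                 ignore_after_bar: bool = False) -> "Tx2Gene":
        """Return a copy with transcript ids stripped consistently."""
        if not (ignore_tx_version or ignore_after_bar):
            return self
        txs = strip_ids([t for t, _ in self.pairs],
                        ignore_tx_version=ignore_tx_version,
                        ignore_after_bar=ignore_after_bar)
        return Tx2Gene(list(zip(txs, [g for _, g in self.pairs])))


def strip_ids(ids: Sequence[str], ignore_tx_version: bool = False,
              ignore_after_bar: bool = False) -> list[str]:
    """Normalize identifiers by removing annotation suffixes.

    With ``ignore_after_bar``, everything from the first ``|`` on is dropped
    (GENCODE-style composite headers); then with ``ignore_tx_version``,
    everything from the first ``.`` on is dropped (Ensembl-style version
    suffixes).  Must be applied identically to quantified ids and to the
    tx2gene mapping so they can be matched.
    """
    if len(ids) == 0:
        raise ValidationError("strip_ids requires a nonempty id list")
    out = []
    for raw in ids:
        s = raw
        if ignore_after_bar:
            s = s.split("|", 1)[0]
        if ignore_tx_version:
            s = s.split(".", 1)[0]
        if not s:
            raise ValidationError(
                f"stripping produced an empty identifier from {raw!r}"
            )
        out.append(s)
    return out


def match_tx2gene(tx_ids: Sequence[str],
                  mapping: Tx2Gene) -> tuple[list[Optional[str]], int, list[str]]:
    """Assign each transcript to its gene.

    Returns ``(assignment, n_missing, gene_order)`` where ``assignment[i]``
    is the gene of ``tx_ids[i]`` or ``None`` when the transcript is absent
    from the mapping, and ``gene_order`` is the lexicographically sorted list
    of genes that received at least one transcript.  Missing transcripts are
    reported with a warning and are excluded from summarization downstream.
    """
    lookup = mapping.as_dict()
    assignment: list[Optional[str]] = []
    genes: set[str] = set()
    n_missing = 0
    for t in tx_ids:
        g = lookup.get(t)
        if g is None:
            n_missing += 1
        else:
            genes.add(g)
        assignment.append(g)
    if n_missing == len(assignment):
        raise ValidationError("no transcripts matched tx2gene")
    if n_missing:
        warnings.warn(
            f"{n_missing} transcripts missing from tx2gene; "
            "they will be excluded from gene-level summarization",
            stacklevel=2,
        )
    return assignment, n_missing, sorted(genes)


def read_tx2gene(path: str | Path,
                 known_tx_ids: Optional[Sequence[str]] = None) -> Tx2Gene:
    """Read a two-column transcript-to-gene table (CSV or TSV).

    The delimiter is auto-detected from the first line (tab preferred over
    comma).  An optional header row is detected when the file has more than
    one row and the first row's column-1 value does not occur among
    ``known_tx_ids`` (the quantified transcript ids); without known ids the
    first row is treated as data.  Extra columns are ignored with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"tx2gene file not found: {path}")
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"tx2gene file is empty: {path}")
    sep = "\t" if "\t" in lines[0] else ","
    rows = [ln.split(sep) for ln in lines]
    if any(len(r) < 2 for r in rows):
        raise ParseError(
            f"tx2gene file {path} has rows with fewer than two columns"
        )
    if any(len(r) > 2 for r in rows):
        warnings.warn(
            f"tx2gene file {path} has extra columns; only the first two are used",
            stacklevel=2,
        )
    start = 0
    if len(rows) > 1 and known_tx_ids is not None:
        if rows[0][0].strip() not in set(known_tx_ids):
            start = 1
    pairs = [(r[0].strip(), r[1].strip()) for r in rows[start:]]
    return Tx2Gene(pairs)
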