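"""Parsers for quantifier output formats.

Each ``read_*_sample`` function turns one sample's output (a Salmon or
Sailfish directory, a Kallisto ``abundance.tsv``/``abundance.h5``, an RSEM
results file, or a generic delimited table) into a
:class:`~txquant.core.SampleQuant`.  :func:`import_quant` drives the whole
pipeline: it reads every sample, stacks transcript-level matrices, applies
inferential-replicate policies, summarizes to gene level and applies
counts-from-abundance scaling.
"""

from __future__ import annotations

import gzip
import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .core import (
    InfReps,
    ParseError,
    QuantResult,
    SampleQuant,
    Tx2Gene,
    ValidationError,
    strip_ids,
)
from .summarize import (
    abundance_from_counts,
    counts_from_abundance,
    summarize_to_gene,
    var_reduce,
)

__all__ = [
    "ReaderConfig",
    "read_salmon_sample",
    "read_salmon_infreps",
    "read_kallisto_sample",
    "read_rsem_sample",
    "read_generic_table",
    "import_quant",
]

SALMON_COLUMNS = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]
KALLISTO_COLUMNS = ["target_id", "length", "eff_length", "est_counts", "tpm"]
RSEM_GENE_COLUMNS = ["gene_id", "transcript_id(s)", "length", "effective_length",
                     "expected_count", "TPM", "FPKM"]
RSEM_ISOFORM_COLUMNS = ["transcript_id", "gene_id", "length", "effective_length",
                        "expected_count", "TPM", "FPKM", "IsoPct"]


@dataclass
class ReaderConfig:
    """Options controlling how quantifier outputs are parsed.

    ``tool`` selects the dialect.  ``generic_colmap`` names the id /
    length / eff_length / counts / abundance columns of a generic table and
    is required iff ``tool == "generic"``; ``rsem_level`` is required iff
    ``tool == "rsem"``.
    """

    tool: str = "salmon"
    kallisto_format: str = "auto"
    rsem_level: Optional[str] = None
    generic_colmap: Optional[dict[str, str]] = None
    read_inf_reps: bool = False

    def __post_init__(self) -> None:
        if self.tool not in ("salmon", "sailfish", "kallisto", "rsem", "generic"):
            raise ValidationError(f"unknown tool {self.tool!r}")
        if self.kallisto_format not in ("tsv", "h5", "auto"):
            raise ValidationError(f"unknown kallisto format {self.kallisto_format!r}")
        if self.tool == "generic" and not self.generic_colmap:
            raise ValidationError("generic_colmap is required for tool='generic'")
        if self.tool == "rsem":
            if self.rsem_level not in ("genes", "isoforms"):
                raise ValidationError(
                    "rsem_level must be 'genes' or 'isoforms' for tool='rsem'"
                )


def _read_table(path: Path, sep: str = "\t",
                skip_comments: bool = False) -> pd.DataFrame:
    """Read a delimited text table, transparently handling ``.gz``.

    With ``skip_comments``, leading ``#`` lines are dropped, but a
    ``# Name ...`` style comment header (old Sailfish dialect) is recognised
    and reused as the header row.
    """
    opener = gzip.open if path.suffix == ".gz" else open
    try:
        with opener(path, "rt") as fh:
            text = fh.read()
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if skip_comments:
        lines = text.splitlines()
        header = None
        body_start = 0
        for i, ln in enumerate(lines):
            if ln.startswith("#"):
                stripped = ln.lstrip("#").strip()
                if stripped.split("\t")[0].strip() == "Name":
                    header = stripped
            else:
                body_start = i
                break
        else:
            body_start = len(lines)
        body = lines[body_start:]
        if header is not None:
            body = [header] + body
        text = "\n".join(body)
    try:
        return pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse {path}: {exc}") from exc


def _numeric(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric value {df[col].iloc[row]!r} in column {col!r} "
            f"at data row {row + 1} of {path}"
        )
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna().to_numpy())[0])
        raise ParseError(f"missing value in column {col!r} at data row "
                         f"{row + 1} of {path}")
    return vals.to_numpy(dtype=float)


def _require_columns(df: pd.DataFrame, required: Sequence[str],
                     path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required column(s) {missing}; "
            f"found columns {list(df.columns)}"
        )


def read_salmon_sample(directory: str | Path,
                       config: Optional[ReaderConfig] = None) -> SampleQuant:
    """Parse a Salmon (or Sailfish) quantification directory.

    Expects ``quant.sf`` (optionally gzipped) with tab-separated columns
    Name, Length, EffectiveLength, TPM, NumReads.  The Sailfish dialect with
    leading ``#`` comment lines and a ``# Name ...`` comment header is
    accepted.  Inferential replicates are loaded separately by
    :func:`read_salmon_infreps`.
    """
    config = config or ReaderConfig(tool="salmon")
    directory = Path(directory)
    path = directory / "quant.sf"
    if not path.exists():
        gz = directory / "quant.sf.gz"
        if gz.exists():
            path = gz
        else:
            raise ParseError(f"quantification file not found: {path}")
    df = _read_table(path, skip_comments=True)
    _require_columns(df, SALMON_COLUMNS, path)
    if len(df) == 0:
        raise ParseError(f"no transcripts in {path}")
    sample = SampleQuant(
        tx_ids=[str(x) for x in df["Name"]],
        ref_length=_numeric(df, "Length", path),
        eff_length=_numeric(df, "EffectiveLength", path),
        abundance=_numeric(df, "TPM", path),
        counts=_numeric(df, "NumReads", path),
    )
    if config.read_inf_reps:
        reps = read_salmon_infreps(directory)
        if reps is not None:
            if reps.matrix.shape[1] != sample.n_transcripts:
                raise ParseError(
                    f"{directory}: replicate matrix has {reps.matrix.shape[1]} "
                    f"transcripts, quant.sf has {sample.n_transcripts}"
                )
            if reps.names is not None and reps.names != sample.tx_ids:
                raise ParseError(
                    f"{directory}: bootstrap transcript names do not match "
                    "quant.sf order"
                )
            sample.inf_reps = reps.matrix
            sample.inf_rep_type = reps.rep_type
    return sample


@dataclass
class _SalmonReps:
    matrix: np.ndarray
    rep_type: str
    names: Optional[list[str]] = None


def read_salmon_infreps(directory: str | Path) -> Optional[_SalmonReps]:
    """Load Salmon inferential replicates, or ``None`` when absent.

    The replicate count comes from ``aux_info/meta_info.json``
    (``num_bootstraps``); the type from ``samp_type`` (``gibbs_samples`` /
    ``gibbs`` mean Gibbs, anything else bootstrap).  The stream
    ``aux_info/bootstrap/bootstraps.gz`` is decoded as 8-byte little-endian
    reals, row-major replicates-by-transcripts, with a 4-byte little-endian
    integer fallback chosen by exact byte count.
    """
    directory = Path(directory)
    meta_path = directory / "aux_info" / "meta_info.json"
    if not meta_path.exists():
        return None
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"cannot parse {meta_path}: {exc}") from exc
    n_reps = int(meta.get("num_bootstraps", 0))
    if n_reps == 0:
        return None
    samp_type = str(meta.get("samp_type", "bootstrap"))
    rep_type = "gibbs" if samp_type.startswith("gibbs") else "bootstrap"
    boot_path = directory / "aux_info" / "bootstrap" / "bootstraps.gz"
    names_path = directory / "aux_info" / "bootstrap" / "names.tsv.gz"
    if not boot_path.exists():
        return None
    names = None
    if names_path.exists():
        with gzip.open(names_path, "rt") as fh:
            names = fh.read().strip("\n").split("\t")
    with gzip.open(boot_path, "rb") as fh:
        raw = fh.read()
    if names is not None:
        n_tx = len(names)
    else:
        # without names the transcript count must divide the stream evenly
        if len(raw) % (8 * n_reps) == 0:
            n_tx = len(raw) // (8 * n_reps)
        elif len(raw) % (4 * n_reps) == 0:
            n_tx = len(raw) // (4 * n_reps)
        else:
            raise ParseError(
                f"{boot_path}: stream of {len(raw)} bytes is not divisible "
                f"into {n_reps} replicates"
            )
    expected8 = n_reps * n_tx * 8
    expected4 = n_reps * n_tx * 4
    if len(raw) == expected8:
        flat = np.frombuffer(raw, dtype="<f8")
    elif len(raw) == expected4:
        flat = np.frombuffer(raw, dtype="<i4").astype(float)
    else:
        raise ParseError(
            f"{boot_path}: stream has {len(raw)} bytes; expected {expected8} "
            f"(8-byte reals) or {expected4} (4-byte integers) for "
            f"{n_reps} replicates x {n_tx} transcripts"
        )
    return _SalmonReps(matrix=flat.reshape(n_reps, n_tx),
                       rep_type=rep_type, names=names)


def read_kallisto_sample(path: str | Path,
                         config: Optional[ReaderConfig] = None) -> SampleQuant:
    """Parse Kallisto output (``abundance.tsv`` or ``abundance.h5``).

    ``path`` may be the output directory or a direct file path.  The HDF5
    dialect carries no TPM column, so abundance is recomputed from counts
    and effective lengths by TPM normalization; bootstraps (HDF5 only) are
    loaded when ``config.read_inf_reps``.
    """
    config = config or ReaderConfig(tool="kallisto")
    path = Path(path)
    if path.is_dir():
        h5 = path / "abundance.h5"
        tsv = path / "abundance.tsv"
        fmt = config.kallisto_format
        if fmt == "auto":
            if h5.exists():
                path, fmt = h5, "h5"
            elif tsv.exists():
                path, fmt = tsv, "tsv"
            else:
                raise ParseError(
                    f"neither abundance.h5 nor abundance.tsv found in {path}"
                )
        elif fmt == "h5":
            path = h5
        else:
            path = tsv
    else:
        fmt = "h5" if path.suffix == ".h5" else "tsv"
    if not path.exists():
        raise ParseError(f"quantification file not found: {path}")
    if fmt == "tsv":
        df = _read_table(path)
        _require_columns(df, KALLISTO_COLUMNS, path)
        if len(df) == 0:
            raise ParseError(f"no transcripts in {path}")
        return SampleQuant(
            tx_ids=[str(x) for x in df["target_id"]],
            ref_length=_numeric(df, "length", path),
            eff_length=_numeric(df, "eff_length", path),
            counts=_numeric(df, "est_counts", path),
            abundance=_numeric(df, "tpm", path),
        )
    with h5py.File(path, "r") as f:
        for ds in ("est_counts", "aux/ids", "aux/eff_lengths", "aux/lengths"):
            if ds not in f:
                raise ParseError(f"{path}: missing HDF5 dataset /{ds}")
        counts = np.asarray(f["est_counts"], dtype=float)
        ids = [x.decode() if isinstance(x, bytes) else str(x)
               for x in f["aux/ids"][()]]
        eff_len = np.asarray(f["aux/eff_lengths"], dtype=float)
        ref_len = np.asarray(f["aux/lengths"], dtype=float)
        bad = (eff_len <= 0) & (counts > 0)
        if np.any(bad):
            t = ids[int(np.flatnonzero(bad)[0])]
            raise ParseError(
                f"{path}: transcript {t!r} has positive counts but "
                "nonpositive effective length"
            )
        abundance = abundance_from_counts(counts[:, None],
                                          eff_len[:, None])[:, 0]
        inf_reps = None
        if config.read_inf_reps and "bootstrap" in f:
            n_boot = int(np.asarray(f["aux/num_bootstrap"]).ravel()[0]) \
                if "aux/num_bootstrap" in f else len(f["bootstrap"])
            if n_boot > 0:
                rows = [np.asarray(f[f"bootstrap/bs{i}"], dtype=float)
                        for i in range(n_boot)]
                inf_reps = np.vstack(rows)
    return SampleQuant(
        tx_ids=ids,
        ref_length=ref_len,
        eff_length=eff_len,
        counts=counts,
        abundance=abundance,
        inf_reps=inf_reps,
        inf_rep_type="bootstrap" if inf_reps is not None else "none",
    )


def read_rsem_sample(path: str | Path,
                     config: Optional[ReaderConfig] = None) -> SampleQuant:
    """Parse an RSEM ``*.genes.results`` or ``*.isoforms.results`` file.

    Identifiers come from the level's primary id column; FPKM and IsoPct
    are ignored.  Gene-level files yield gene ids directly (no further
    summarization is needed downstream).
    """
    config = config or ReaderConfig(tool="rsem", rsem_level="isoforms")
    path = Path(path)
    if not path.exists():
        raise ParseError(f"quantification file not found: {path}")
    df = _read_table(path)
    if config.rsem_level == "genes":
        _require_columns(df, RSEM_GENE_COLUMNS, path)
        id_col = "gene_id"
    else:
        _require_columns(df, RSEM_ISOFORM_COLUMNS, path)
        id_col = "transcript_id"
    if len(df) == 0:
        raise ParseError(f"no transcripts in {path}")
    return SampleQuant(
        tx_ids=[str(x) for x in df[id_col]],
        ref_length=_numeric(df, "length", path),
        eff_length=_numeric(df, "effective_length", path),
        counts=_numeric(df, "expected_count", path),
        abundance=_numeric(df, "TPM", path),
    )


def read_generic_table(path: str | Path, colmap: dict[str, str],
                       allow_derived_counts: bool = False) -> SampleQuant:
    """Parse an arbitrary delimited quantification table via a column map.

    ``colmap`` maps the roles ``id``, ``eff_length``, and optionally
    ``length``, ``counts``, ``abundance`` to the file's column names.
    Abundance, when unmapped, is derived from counts and effective length
    by TPM normalization.  Counts cannot be derived; an unmapped counts
    column is an error unless ``allow_derived_counts`` (set when
    counts-from-abundance scaling is requested at import, in which case the
    abundance column stands in for counts with the TPM total as library
    size).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"quantification file not found: {path}")
    for role in ("id", "eff_length"):
        if role not in colmap:
            raise ParseError(f"generic column map must name the {role!r} column")
    sep = "\t"
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.readline()
    if "\t" not in first and "," in first:
        sep = ","
    df = _read_table(path, sep=sep)
    needed = [colmap[r] for r in colmap]
    _require_columns(df, needed, path)
    if len(df) == 0:
        raise ParseError(f"no transcripts in {path}")
    eff_len = _numeric(df, colmap["eff_length"], path)
    counts = (_numeric(df, colmap["counts"], path)
              if "counts" in colmap else None)
    abundance = (_numeric(df, colmap["abundance"], path)
                 if "abundance" in colmap else None)
    if abundance is None:
        if counts is None:
            raise ParseError(
                f"{path}: column map provides neither counts nor abundance"
            )
        abundance = abundance_from_counts(counts[:, None],
                                          eff_len[:, None])[:, 0]
    if counts is None:
        if not allow_derived_counts:
            raise ParseError(
                f"{path}: no counts column mapped and counts are not "
                "derivable; request counts-from-abundance scaling to use "
                "abundance-proportional counts"
            )
        counts = abundance.copy()
    ref_len = (_numeric(df, colmap["length"], path)
               if "length" in colmap else None)
    return SampleQuant(
        tx_ids=[str(x) for x in df[colmap["id"]]],
        ref_length=ref_len,
        eff_length=eff_len,
        counts=counts,
        abundance=abundance,
    )


def _default_sample_id(path: Path, tool: str) -> str:
    if path.is_dir():
        return path.name
    name = path.name
    for suffix in (".genes.results", ".isoforms.results", ".tsv", ".h5",
                   ".csv", ".txt", ".gz", ".sf"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


def _read_one(path: Path, config: ReaderConfig,
              allow_derived_counts: bool) -> SampleQuant:
    if config.tool in ("salmon", "sailfish"):
        return read_salmon_sample(path, config)
    if config.tool == "kallisto":
        return read_kallisto_sample(path, config)
    if config.tool == "rsem":
        return read_rsem_sample(path, config)
    return read_generic_table(path, config.generic_colmap,
                              allow_derived_counts=allow_derived_counts)


def import_quant(files: Sequence[str | Path],
                 config: ReaderConfig,
                 sample_ids: Optional[Sequence[str]] = None,
                 tx2gene: Optional[Tx2Gene] = None,
                 tx_out: bool = False,
                 counts_from_abundance_mode: str = "no",
                 ignore_tx_version: bool = False,
                 ignore_after_bar: bool = False,
                 drop_inf_reps: bool = False,
                 var_reduce_reps: bool = False,
                 inf_rep_stat: Optional[str] = None) -> QuantResult:
    """Import one or more samples and assemble a :class:`QuantResult`.

    All samples must yield the identical stripped transcript id vector (same
    set and order); a mismatch raises, naming the first differing sample.
    With ``tx_out=False`` the result is summarized to gene level using
    ``tx2gene``.  ``inf_rep_stat`` (mean/median over replicates) is applied
    at transcript level before summarization; ``drop_inf_reps`` and
    ``var_reduce_reps`` are applied last and the former is incompatible with
    the other replicate policies.
    """
    files = [Path(f) for f in files]
    if not files:
        raise ValidationError("at least one input file is required")
    if drop_inf_reps and (var_reduce_reps or inf_rep_stat is not None):
        raise ValidationError(
            "drop_inf_reps cannot be combined with var_reduce or inf_rep_stat"
        )
    if sample_ids is None:
        sample_ids = [_default_sample_id(f, config.tool) for f in files]
    sample_ids = [str(s) for s in sample_ids]
    if len(sample_ids) != len(files):
        raise ValidationError("sample_ids length does not match files")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError("sample_ids must be unique")

    rsem_gene_level = config.tool == "rsem" and config.rsem_level == "genes"
    if not tx_out and tx2gene is None and not rsem_gene_level:
        raise ValidationError(
            "gene-level output requested (tx_out=False) but no tx2gene "
            "mapping was provided"
        )

    allow_derived = counts_from_abundance_mode != "no"
    samples = [_read_one(f, config, allow_derived) for f in files]

    ref_ids = strip_ids(samples[0].tx_ids, ignore_tx_version=ignore_tx_version,
                        ignore_after_bar=ignore_after_bar)
    for sid, s in zip(sample_ids[1:], samples[1:]):
        ids = strip_ids(s.tx_ids, ignore_tx_version=ignore_tx_version,
                        ignore_after_bar=ignore_after_bar)
        if ids != ref_ids:
            raise ValidationError(
                f"sample {sid!r} has a different transcript id vector than "
                f"sample {sample_ids[0]!r} (sets and order must match exactly)"
            )
    dup = len(ref_ids) != len(set(ref_ids))
    if dup:
        raise ValidationError(
            "stripped transcript ids contain duplicates; adjust stripping flags"
        )

    A = np.column_stack([s.abundance for s in samples])
    C = np.column_stack([s.counts for s in samples])
    L = np.column_stack([s.eff_length for s in samples])

    inf_reps = None
    rep_counts = {s.inf_reps.shape[0] for s in samples if s.inf_reps is not None}
    if config.read_inf_reps and rep_counts:
        if any(s.inf_reps is None for s in samples):
            warnings.warn(
                "inferential replicates are present for only a subset of "
                "samples; dropping them",
                stacklevel=2,
            )
        elif len(rep_counts) > 1:
            raise ValidationError(
                f"samples disagree on replicate count: {sorted(rep_counts)}"
            )
        else:
            rep_type = samples[0].inf_rep_type
            inf_reps = InfReps(
                n_reps=rep_counts.pop(),
                per_sample=[s.inf_reps for s in samples],
                rep_type=rep_type if rep_type != "none" else "bootstrap",
            )

    if inf_rep_stat is not None:
        if inf_reps is None:
            raise ValidationError(
                "inf_rep_stat requested but no inferential replicates found"
            )
        from .summarize import apply_infrep_stat
        C, A = apply_infrep_stat(inf_reps, inf_rep_stat, L)

    level = "gene" if rsem_gene_level else "transcript"
    result = QuantResult(
        abundance=pd.DataFrame(A, index=ref_ids, columns=sample_ids),
        counts=pd.DataFrame(C, index=ref_ids, columns=sample_ids),
        length=pd.DataFrame(L, index=ref_ids, columns=sample_ids),
        level=level,
        counts_from_abundance="no",
        inf_reps=inf_reps,
        tool=config.tool,
        source_paths=[str(f) for f in files],
    )

    if not tx_out and not rsem_gene_level:
        result = summarize_to_gene(result, tx2gene,
                                   counts_from_abundance_mode,
                                   ignore_tx_version=ignore_tx_version,
                                   ignore_after_bar=ignore_after_bar)
    elif counts_from_abundance_mode != "no":
        C2 = counts_from_abundance(
            result.counts.to_numpy(), result.abundance.to_numpy(),
            result.length.to_numpy(), counts_from_abundance_mode)
        result = QuantResult(
            abundance=result.abundance, length=result.length,
            counts=pd.DataFrame(C2, index=result.feature_ids,
                                columns=result.sample_ids),
            level=result.level,
            counts_from_abundance=counts_from_abundance_mode,
            inf_reps=result.inf_reps, tool=result.tool,
            source_paths=result.source_paths,
        )

    if drop_inf_reps and result.inf_reps is not None:
        result = QuantResult(
            abundance=result.abundance, counts=result.counts,
            length=result.length, level=result.level,
            counts_from_abundance=result.counts_from_abundance,
            inf_reps=None, tool=result.tool,
            source_paths=result.source_paths,
        )
    if var_reduce_reps:
        if result.inf_reps is None:
            raise ValidationError(
                "var_reduce requested but no inferential replicates found"
            )
        V = var_reduce(result.inf_reps)
        result = QuantResult(
            abundance=result.abundance, counts=result.counts,
            length=result.length, level=result.level,
            counts_from_abundance=result.counts_from_abundance,
            inf_reps=None,
            inf_rep_variance=pd.DataFrame(V, index=result.feature_ids,
                                          columns=result.sample_ids),
            tool=result.tool, source_paths=result.source_paths,
        )
    return result
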