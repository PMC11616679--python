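"""Synthetic quantifier outputs with known ground truth.

:func:`simulate_truth` samples a transcript-level experiment — negative
binomial counts over genes with a handful of isoforms each, per-sample
effective lengths, TPM abundances derived by construction, and optional
Poisson bootstrap replicates — and the ``write_*`` functions serialize it as
structurally valid Salmon, Kallisto (TSV or HDF5) and RSEM output trees.
:func:`oracle_summarize` is the independent test authority: a deliberately
naive per-gene loop implementation of the summarization rules that shares no
code with :mod:`txquant.summarize`.
"""

from __future__ import annotations

import gzip
import json
import math
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .core import Tx2Gene, ValidationError

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_truth",
    "write_salmon_tree",
    "write_kallisto_tree",
    "write_rsem_files",
    "write_tx2gene",
    "oracle_summarize",
]

FLOAT_FMT = "%.12g"  # >= 12 significant digits in all text output


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    ``tx_per_gene`` is either a fixed integer or an inclusive ``(lo, hi)``
    range sampled uniformly per gene.  Counts follow a negative binomial
    with per-transcript mean (log-normal across transcripts, median
    ``mean_count``) and common ``dispersion``; a ``zero_fraction`` of
    transcripts is silenced entirely to exercise the zero-abundance length
    imputation.  Effective lengths are per-transcript base lengths drawn
    uniformly from ``eff_length_range`` with a small per-sample
    multiplicative jitter (fragment-length variation between libraries).
    """

    n_genes: int = 250
    tx_per_gene: int | tuple[int, int] = (1, 4)
    n_samples: int = 6
    seed: int = 0
    mean_count: float = 100.0
    dispersion: float = 0.1
    zero_fraction: float = 0.1
    eff_length_range: tuple[float, float] = (200.0, 2000.0)
    n_bootstraps: int = 0
    bootstrap_noise: bool = True

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValidationError("n_genes and n_samples must be >= 1")
        if self.eff_length_range[0] <= 0:
            raise ValidationError("minimum effective length must be positive")
        if isinstance(self.tx_per_gene, tuple):
            lo, hi = self.tx_per_gene
            if lo < 1 or hi < lo:
                raise ValidationError("invalid tx_per_gene range")
        elif self.tx_per_gene < 1:
            raise ValidationError("tx_per_gene must be >= 1")
        if not 0 <= self.zero_fraction <= 1:
            raise ValidationError("zero_fraction must lie in [0, 1]")
        if self.n_bootstraps < 0:
            raise ValidationError("n_bootstraps must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment.

    ``eff_length``, ``counts`` and ``abundance`` are transcripts-by-samples
    arrays; abundance satisfies the TPM identity by construction (columns
    sum to 1e6 whenever the sample has any count).  ``bootstraps``, when
    present, has shape ``(n_bootstraps, n_tx, n_samples)``.
    """

    tx_ids: list[str]
    gene_ids: list[str]  # gene of each transcript, parallel to tx_ids
    sample_ids: list[str]
    ref_length: np.ndarray
    eff_length: np.ndarray
    counts: np.ndarray
    abundance: np.ndarray
    bootstraps: Optional[np.ndarray] = None

    @property
    def tx2gene(self) -> Tx2Gene:
        return Tx2Gene(list(zip(self.tx_ids, self.gene_ids)))

    @property
    def n_tx(self) -> int:
        return len(self.tx_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _tpm(counts: np.ndarray, eff_length: np.ndarray) -> np.ndarray:
    rate = np.where(counts > 0, counts / eff_length, 0.0)
    total = rate.sum(axis=0)
    return np.where(total > 0, rate / np.where(total > 0, total, 1.0) * 1e6, 0.0)


def simulate_truth(config: SimConfig) -> SimTruth:
    """Sample a ground-truth experiment; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    tx_ids: list[str] = []
    gene_ids: list[str] = []
    for g in range(config.n_genes):
        gene = f"GENE{g + 1:05d}"
        if isinstance(config.tx_per_gene, tuple):
            lo, hi = config.tx_per_gene
            k = int(rng.integers(lo, hi + 1))
        else:
            k = config.tx_per_gene
        for i in range(k):
            tx_ids.append(f"TX{g + 1:05d}T{i + 1}")
            gene_ids.append(gene)
    n_tx = len(tx_ids)
    n_s = config.n_samples
    sample_ids = [f"sample{j + 1}" for j in range(n_s)]

    base_len = rng.uniform(*config.eff_length_range, size=n_tx)
    jitter = rng.uniform(0.95, 1.05, size=n_s)
    eff_length = np.outer(base_len, jitter)
    ref_length = np.round(base_len + rng.uniform(50, 150, size=n_tx))

    mu = np.exp(rng.normal(math.log(config.mean_count), 1.0, size=n_tx)) \
        if config.mean_count > 0 else np.zeros(n_tx)
    silent = rng.random(n_tx) < config.zero_fraction
    mu[silent] = 0.0
    depth = rng.uniform(0.8, 1.2, size=n_s)
    counts = np.zeros((n_tx, n_s))
    if config.mean_count > 0:
        r = 1.0 / config.dispersion
        for j in range(n_s):
            mean_j = mu * depth[j]
            active = mean_j > 0
            p = r / (r + mean_j[active])
            counts[active, j] = rng.negative_binomial(r, p)
    abundance = _tpm(counts, eff_length)

    bootstraps = None
    if config.n_bootstraps > 0:
        if config.bootstrap_noise:
            bootstraps = rng.poisson(
                counts[None, :, :],
                size=(config.n_bootstraps, n_tx, n_s)).astype(float)
        else:
            bootstraps = np.broadcast_to(
                counts, (config.n_bootstraps, n_tx, n_s)).copy()

    return SimTruth(tx_ids=tx_ids, gene_ids=gene_ids, sample_ids=sample_ids,
                    ref_length=ref_length, eff_length=eff_length,
                    counts=counts, abundance=abundance, bootstraps=bootstraps)


def _prepare_dir(directory: Path, force: bool) -> None:
    if directory.exists() and any(directory.iterdir()):
        if not force:
            raise ValidationError(
                f"directory {directory} exists and is nonempty; pass force=True"
            )
        shutil.rmtree(directory)
    directory.mkdir(parents=True, exist_ok=True)


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def write_salmon_tree(truth: SimTruth, directory: str | Path,
                      force: bool = False, sailfish_style: bool = False,
                      gzip_quant: bool = False) -> list[Path]:
    """Write one Salmon-style directory per sample under ``directory``.

    Each sample directory contains ``quant.sf`` (tab-separated Name, Length,
    EffectiveLength, TPM, NumReads) plus ``aux_info/meta_info.json`` and,
    when the truth carries bootstraps, the gzipped little-endian float64
    replicate stream and transcript-name file.  ``sailfish_style`` writes a
    ``# Name ...`` comment header instead of a plain one.
    """
    directory = Path(directory)
    _prepare_dir(directory, force)
    sample_dirs = []
    for j, sid in enumerate(truth.sample_ids):
        sdir = directory / sid
        (sdir / "aux_info").mkdir(parents=True)
        header = "Name\tLength\tEffectiveLength\tTPM\tNumReads"
        lines = []
        if sailfish_style:
            lines.append("# salmon/sailfish-style quantification")
            lines.append("# " + header)
        else:
            lines.append(header)
        for i, tx in enumerate(truth.tx_ids):
            lines.append("\t".join([
                tx, _fmt(truth.ref_length[i]), _fmt(truth.eff_length[i, j]),
                _fmt(truth.abundance[i, j]), _fmt(truth.counts[i, j]),
            ]))
        text = "\n".join(lines) + "\n"
        if gzip_quant:
            with gzip.open(sdir / "quant.sf.gz", "wt") as fh:
                fh.write(text)
        else:
            (sdir / "quant.sf").write_text(text)
        n_boot = 0 if truth.bootstraps is None else truth.bootstraps.shape[0]
        meta = {"num_bootstraps": n_boot, "samp_type": "bootstrap"}
        (sdir / "aux_info" / "meta_info.json").write_text(json.dumps(meta))
        if n_boot > 0:
            bdir = sdir / "aux_info" / "bootstrap"
            bdir.mkdir()
            reps = np.ascontiguousarray(truth.bootstraps[:, :, j], dtype="<f8")
            with gzip.open(bdir / "bootstraps.gz", "wb") as fh:
                fh.write(reps.tobytes())
            with gzip.open(bdir / "names.tsv.gz", "wt") as fh:
                fh.write("\t".join(truth.tx_ids))
        sample_dirs.append(sdir)
    return sample_dirs


def write_kallisto_tree(truth: SimTruth, directory: str | Path,
                        fmt: str = "tsv", force: bool = False) -> list[Path]:
    """Write one Kallisto-style directory per sample (``tsv`` or ``h5``)."""
    if fmt not in ("tsv", "h5"):
        raise ValidationError(f"unknown kallisto format {fmt!r}")
    directory = Path(directory)
    _prepare_dir(directory, force)
    sample_dirs = []
    for j, sid in enumerate(truth.sample_ids):
        sdir = directory / sid
        sdir.mkdir(parents=True)
        if fmt == "tsv":
            lines = ["target_id\tlength\teff_length\test_counts\ttpm"]
            for i, tx in enumerate(truth.tx_ids):
                lines.append("\t".join([
                    tx, _fmt(truth.ref_length[i]),
                    _fmt(truth.eff_length[i, j]),
                    _fmt(truth.counts[i, j]), _fmt(truth.abundance[i, j]),
                ]))
            (sdir / "abundance.tsv").write_text("\n".join(lines) + "\n")
        else:
            with h5py.File(sdir / "abundance.h5", "w") as f:
                f.create_dataset("est_counts", data=truth.counts[:, j])
                aux = f.create_group("aux")
                aux.create_dataset(
                    "ids", data=np.array([t.encode() for t in truth.tx_ids]))
                aux.create_dataset("eff_lengths", data=truth.eff_length[:, j])
                aux.create_dataset("lengths", data=truth.ref_length)
                n_boot = (0 if truth.bootstraps is None
                          else truth.bootstraps.shape[0])
                aux.create_dataset("num_bootstrap", data=np.array([n_boot]))
                if n_boot > 0:
                    boot = f.create_group("bootstrap")
                    for b in range(n_boot):
                        boot.create_dataset(
                            f"bs{b}", data=truth.bootstraps[b, :, j])
        sample_dirs.append(sdir)
    return sample_dirs


def write_rsem_files(truth: SimTruth, directory: str | Path,
                     level: str = "isoforms", force: bool = False) -> list[Path]:
    """Write one RSEM results file per sample.

    Isoform level writes the truth verbatim; gene level writes the
    oracle-summarized matrices (one row per gene), since RSEM reports
    genes directly in ``*.genes.results``.
    """
    if level not in ("genes", "isoforms"):
        raise ValidationError(f"unknown RSEM level {level!r}")
    directory = Path(directory)
    _prepare_dir(directory, force)
    paths = []
    if level == "genes":
        gene_mats = oracle_summarize(truth)
        genes = list(gene_mats["abundance"].index)
        members: dict[str, list[str]] = {}
        for tx, g in zip(truth.tx_ids, truth.gene_ids):
            members.setdefault(g, []).append(tx)
    for j, sid in enumerate(truth.sample_ids):
        path = directory / f"{sid}.{level}.results"
        if level == "isoforms":
            lines = ["\t".join(["transcript_id", "gene_id", "length",
                                "effective_length", "expected_count", "TPM",
                                "FPKM", "IsoPct"])]
            for i, tx in enumerate(truth.tx_ids):
                tpm = truth.abundance[i, j]
                fpkm = tpm * 1e3 / 1e6 * 1e3  # placeholder scale; ignored by readers
                lines.append("\t".join([
                    tx, truth.gene_ids[i], _fmt(truth.ref_length[i]),
                    _fmt(truth.eff_length[i, j]), _fmt(truth.counts[i, j]),
                    _fmt(tpm), _fmt(fpkm), _fmt(0.0),
                ]))
        else:
            lines = ["\t".join(["gene_id", "transcript_id(s)", "length",
                                "effective_length", "expected_count", "TPM",
                                "FPKM"])]
            for g in genes:
                lines.append("\t".join([
                    g, ",".join(members[g]),
                    _fmt(gene_mats["length"].loc[g].iloc[j]),
                    _fmt(gene_mats["length"].loc[g].iloc[j]),
                    _fmt(gene_mats["counts"].loc[g].iloc[j]),
                    _fmt(gene_mats["abundance"].loc[g].iloc[j]),
                    _fmt(0.0),
                ]))
        path.write_text("\n".join(lines) + "\n")
        paths.append(path)
    return paths


def write_tx2gene(truth: SimTruth, path: str | Path, sep: str = "\t",
                  header: bool = False) -> Path:
    """Write the truth's transcript-to-gene mapping as a 2-column table."""
    path = Path(path)
    lines = []
    if header:
        lines.append(sep.join(["transcript_id", "gene_id"]))
    for tx, g in zip(truth.tx_ids, truth.gene_ids):
        lines.append(sep.join([tx, g]))
    path.write_text("\n".join(lines) + "\n")
    return path


def oracle_summarize(truth: SimTruth) -> dict[str, pd.DataFrame]:
    """Gene-level summarization by explicit loops — the test authority.

    Uses only elementary operations (per-gene Python loops over member
    transcripts): abundance and counts are summed; length is the
    abundance-weighted mean of member effective lengths, imputed per row by
    the geometric mean of defined cells, falling back to the mean of member
    transcripts' across-sample mean lengths.  Shares no code with the
    vectorized implementation it validates.
    """
    genes = sorted(set(truth.gene_ids))
    members = {g: [] for g in genes}
    for i, g in enumerate(truth.gene_ids):
        members[g].append(i)
    n_s = truth.n_samples
    A = pd.DataFrame(0.0, index=genes, columns=truth.sample_ids)
    C = pd.DataFrame(0.0, index=genes, columns=truth.sample_ids)
    L = pd.DataFrame(0.0, index=genes, columns=truth.sample_ids)
    for g in genes:
        idx = members[g]
        row_len: list[Optional[float]] = []
        for j in range(n_s):
            col = truth.sample_ids[j]
            a_sum = 0.0
            c_sum = 0.0
            wl = 0.0
            for i in idx:
                a_sum += truth.abundance[i, j]
                c_sum += truth.counts[i, j]
                wl += truth.abundance[i, j] * truth.eff_length[i, j]
            A.at[g, col] = a_sum
            C.at[g, col] = c_sum
            row_len.append(wl / a_sum if a_sum > 0 else None)
        defined = [x for x in row_len if x is not None]
        if defined:
            log_sum = 0.0
            for x in defined:
                log_sum += math.log(x)
            fill = math.exp(log_sum / len(defined))
        else:
            acc = 0.0
            for i in idx:
                m = 0.0
                for j in range(n_s):
                    m += truth.eff_length[i, j]
                acc += m / n_s
            fill = acc / len(idx)
        for j in range(n_s):
            col = truth.sample_ids[j]
            L.at[g, col] = row_len[j] if row_len[j] is not None else fill
    return {"abundance": A, "counts": C, "length": L}
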