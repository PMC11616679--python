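# Methods

## Model and procedure

txquant operates on the standard quantities every transcript quantifier
reports per sample: estimated read counts `c_t` (real-valued — quantifiers
distribute multi-mapping reads probabilistically), effective lengths `l_t`
(the number of positions where a fragment of the observed length
distribution can start) and TPM abundances. The TPM identity links them:

    TPM_t = (c_t / l_t) / Σ_u (c_u / l_u) × 10⁶

Where a format does not store TPM (Kallisto HDF5, generic tables without an
abundance column), abundance is rebuilt from this identity with the
convention that a 0/0 rate term contributes 0. Columns of a rebuilt
abundance matrix therefore sum to 10⁶ exactly whenever the sample has any
count.

Gene-level summarization assumes a many-to-one transcript→gene mapping
(many-to-many mappings are out of scope):

- abundance and counts: per-gene sums over member transcripts;
- effective length: the abundance-weighted mean of member-transcript
  effective lengths. This is the length that, used as an offset in a count
  model, absorbs length-driven apparent expression changes caused by
  isoform switching.

Counts-from-abundance replaces the count matrix by abundance rescaled to
each sample's original total count. `scaledTPM` uses abundance directly;
`lengthScaledTPM` first multiplies each feature's abundance by its
across-sample mean length, so the resulting counts retain length information
and need no offset downstream. Both modes preserve per-sample totals by
construction. The scaling is applied after gene summarization, using the
gene-level count column sums as library sizes (for a complete mapping these
equal the transcript-level sums; the order matters for `lengthScaledTPM`
because the row-mean length differs between levels).

Inferential replicates are replicate count matrices (bootstrap resamples or
Gibbs draws) expressing quantification uncertainty. They are summarized to
gene level row by row with the same summation rule. `varReduce` reduces
them to the unbiased (n−1 denominator) per-cell sample variance;
`infRepStat` collapses them to a mean or median point estimate at
transcript level *before* summarization, rebuilding abundance from the
collapsed counts via the TPM identity — the statistic changes the point
estimates, so every derived quantity is recomputed from it.

## Length imputation

A gene with zero abundance in a sample has no defined weighted length
there. Cells are imputed per gene row: the geometric mean of the row's
defined cells (lengths are multiplicative quantities, so the log-scale mean
is the appropriate summary), or, for a row with no defined cell, the mean
over member transcripts of each transcript's across-sample mean effective
length. The imputed matrix is strictly positive; a nonpositive defined
length aborts with an error rather than propagating a meaningless geometric
mean.

## Identifier handling

Quantified ids and the tx2gene mapping are normalized identically before
matching: optionally everything from the first `|` is removed (composite
FASTA headers), then everything from the first `.` (version suffixes).
First-dot semantics are deliberate — "version" could plausibly mean
last-dot, but ecosystem convention is first-dot. Stripping that empties an
identifier is an error naming the offending input. Transcripts absent from
the mapping are excluded from summarization with a warning carrying the
count; a mapping that matches nothing is an error. Gene rows are emitted in
lexicographic order, chosen for reproducibility across platforms — no
ordering is canonical in the wild, so cross-checks against other
implementations should align by label before comparing (the metrics module
does this with `align=True`).

Within one quant file, duplicate transcript rows are a hard error
(ambiguous provenance), not silently aggregated. Across samples, the
stripped transcript id vectors must match exactly in set *and* order; a
mismatch almost always signals mixed reference transcriptomes, and silent
reindexing would hide it.

## Readers

- **Salmon/Sailfish**: `quant.sf` (transparently gzipped as
  `quant.sf.gz`), tab-separated Name/Length/EffectiveLength/TPM/NumReads;
  the old Sailfish dialect with leading `#` comment lines and a `# Name …`
  comment header is accepted. Inferential replicates come from
  `aux_info/meta_info.json` (`num_bootstraps`, `samp_type`) plus the
  gzipped stream `aux_info/bootstrap/bootstraps.gz`, decoded as 8-byte
  little-endian reals row-major replicates×transcripts, with a 4-byte
  little-endian integer fallback selected by exact byte count (both
  dialects exist in the wild; the byte count disambiguates). Replicate
  transcript names are validated against quant.sf order.
- **Kallisto**: `abundance.tsv` or `abundance.h5`; `auto` prefers the HDF5
  file when both exist because only it carries bootstraps.
- **RSEM**: `*.isoforms.results` or `*.genes.results`; the gene-level file
  is already summarized, so it yields a gene-level result directly.
- **Generic tables**: a column map names the id/length/eff_length/counts/
  abundance columns. Abundance is derivable from counts and lengths;
  counts are not derivable from abundance (the library size is unknown), so
  an unmapped counts column is an error unless counts-from-abundance
  scaling was requested, in which case the abundance column stands in with
  the TPM total (10⁶) as library size.

Numeric text is parsed at full decimal precision; any non-numeric cell is a
typed error with its row number. Reader output never contains NaN or Inf.

## Synthetic data generator

`simulate_truth` emulates the *structure* of quantifier output, not read
-level biology. Defaults define the desk-scale study conditions: 250 genes
with 1–4 transcripts each (uniform), 6 samples, negative binomial counts
(per-transcript log-normal mean with median 100 and log-sd 1, dispersion
0.1, per-sample depth factors uniform in 0.8–1.2), 10% of transcripts
silenced to exercise the zero-abundance length imputation, effective
lengths uniform in 200–2000 bases with a ±5% per-sample multiplicative
jitter standing in for fragment-length variation, and Poisson bootstrap
replicates around the true counts (simple, nonnegative, mean-preserving).
Abundance is computed from the TPM identity, so all consistency relations
hold by construction and the truth is a valid oracle for every reader
round-trip.

What the generator does **not** model: estimation error (counts are the
truth, not noisy estimates of it), GC/positional bias, multi-mapping
ambiguity structure, correlated isoform expression. Passing tests
demonstrate that parsing, assembly and aggregation are exact — they say
nothing about quantifier accuracy on real reads.

`oracle_summarize` is the independent test authority: per-gene Python loops
over member transcripts implementing the same summation, weighting and
imputation rules with elementary operations only, sharing no code with the
vectorized implementation it validates.

## Numerical choices

- Text output uses ≥12 significant digits (`%.12g` in fixtures, `%.15g` in
  result export), bounding text round-trip error near 1e-12 relative.
- Variance uses the unbiased n−1 denominator and requires ≥2 replicates.
- Pearson correlation in the metrics module is computed over the flattened
  cell vector of the whole matrix (a global rather than per-column
  summary); two element-wise identical matrices report r = 1 exactly, and a
  constant matrix reports the correlation as undefined (`None`) rather than
  propagating NaN.
- `dtuScaledTPM` is deliberately unimplemented; requesting it raises an
  explicit unsupported-mode error.

## Problem sizes

The default test and acceptance workloads use 50 simulated experiments of
250 genes × 6 samples (roughly 600 transcripts each) plus one
bootstrap-carrying experiment round-tripped through all four formats; the
whole suite runs in a few seconds on one CPU. These sizes were chosen as
the smallest at which every code path (multi-isoform genes, silenced
transcripts, replicate tensors) is exercised densely.

## Known limitations

- Many-to-many transcript→gene mappings and genome-coordinate awareness
  are unsupported.
- Single-cell (alevin) and StringTie imports are out of scope.
- Inter-sample transcript sets must match exactly; there is no reordering
  escape hatch.
- The AnnData export cannot carry raw replicate tensors, only the reduced
  variance layer; a replicate policy must be chosen before export.
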