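# txquant

Import transcript-level RNA-seq quantifications into Python and summarize
them to gene level.

Quantifiers such as Salmon, Sailfish, Kallisto and RSEM estimate, per
sample, a count `c_t`, an effective length `l_t` and an abundance
(transcripts per million, TPM) for every transcript `t`. Differential
expression is usually modelled per gene, so these transcript-level estimates
have to be aggregated consistently before analysis. txquant parses each
tool's native output, assembles multi-sample matrices, and applies the
standard aggregation rules:

- **Gene counts and abundance** are sums over member transcripts:
  `C_g = Σ_{t∈g} c_t`, `A_g = Σ_{t∈g} TPM_t`.
- **Gene effective length** is the abundance-weighted mean
  `L_g = Σ_{t∈g} TPM_t · l_t / Σ_{t∈g} TPM_t`; samples where a gene has
  zero abundance get the geometric mean of the gene's defined lengths
  across the other samples (falling back to the mean transcript length).
- **Counts-from-abundance** rescales TPM back to each sample's total count,
  either directly (`scaledTPM`) or after weighting by each feature's
  across-sample mean length (`lengthScaledTPM`), so downstream models need
  no length offset. Per-sample count totals are preserved exactly.
- **Inferential replicates** (bootstrap or Gibbs re-estimates of counts)
  can be carried through gene summarization, reduced to a variance matrix
  (`varReduce`), collapsed to a mean/median point estimate (`infRepStat`),
  or dropped (`dropInfReps`).

Results can be exported as an AnnData container (samples × features, counts
in `X`, abundance and length as layers — ready for scanpy or PyDESeq2) or
as plain CSV/TSV matrices (features × samples, the convention of R-side DE
tools). A synthetic-data module generates structurally valid quantifier
output trees with known ground truth, and a metrics module quantifies
agreement between any two result matrices (Pearson correlation, MAE, MSE).

## Worked example

```python
import txquant as tq

# simulate a 20-gene, 3-sample experiment and write Salmon-style output
truth = tq.simulate_truth(tq.SimConfig(n_genes=20, n_samples=3, seed=1))
dirs = tq.write_salmon_tree(truth, "scratch/salmon_demo")

res = tq.import_quant(dirs, tq.ReaderConfig(tool="salmon"),
                      tx2gene=truth.tx2gene)
print(res.level, res.counts.shape)
print(res.counts.head(3).round(2))
```

prints

```
gene (20, 3)
           sample1  sample2  sample3
GENE00001    274.0    203.0    203.0
GENE00002    193.0    300.0    169.0
GENE00003    671.0    590.0    632.0
```

i.e. a gene-by-sample count matrix (here each gene's estimated reads per
sample, summed over its transcripts; rows are lexicographically sorted gene
ids). `res.abundance` holds the summed TPM and `res.length` the
abundance-weighted effective lengths used as DE offsets.

The same pipeline is available from the shell:

```sh
txquant simulate --genes 250 --samples 6 --seed 1 --out scratch/sim \
        --formats salmon --tx2gene-out scratch/t2g.tsv
txquant import --type salmon --files scratch/sim/salmon/sample1,... \
        --tx2gene scratch/t2g.tsv --out scratch/res --format tsv
txquant compare --a scratch/res --b scratch/res --format tsv
```

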