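"""Reader tests: format dialects, error paths, and fixture round-trips."""

import gzip
import json

import h5py
import numpy as np
import pytest

from txquant import (
    ParseError,
    ReaderConfig,
    SimConfig,
    ValidationError,
    import_quant,
    oracle_summarize,
    read_generic_table,
    read_kallisto_sample,
    read_rsem_sample,
    read_salmon_infreps,
    read_salmon_sample,
    simulate_truth,
    write_kallisto_tree,
    write_rsem_files,
    write_salmon_tree,
)

from conftest import max_rel_err


def write_quant_sf(directory, rows, header="Name\tLength\tEffectiveLength\tTPM\tNumReads"):
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "quant.sf").write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
    return directory


class TestSalmonReader:
    def test_single_row_field_mapping(self, tmp_path):
        d = write_quant_sf(tmp_path / "s1", ["t1\t100\t75.0\t1000000.0\t10.0"])
        s = read_salmon_sample(d)
        assert s.tx_ids == ["t1"]
        assert s.ref_length[0] == 100.0
        assert s.eff_length[0] == 75.0
        assert s.abundance[0] == 1e6
        assert s.counts[0] == 10.0

    def test_header_only_file_is_error(self, tmp_path):
        d = write_quant_sf(tmp_path / "s1", [])
        with pytest.raises(ParseError, match="no transcripts"):
            read_salmon_sample(d)

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(ParseError, match="quant.sf"):
            read_salmon_sample(tmp_path / "nope")

    def test_renamed_column_lists_found_columns(self, tmp_path):
        d = write_quant_sf(tmp_path / "s1", ["t1\t1\t1\t1\t1"],
                           header="Name\tLen\tEffectiveLength\tTPM\tNumReads")
        with pytest.raises(ParseError, match="Length.*found columns"):
            read_salmon_sample(d)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        d = write_quant_sf(tmp_path / "s1",
                           ["t1\t100\t75.0\t1.0\t2.0",
                            "t2\t100\tabc\t1.0\t2.0"])
        with pytest.raises(ParseError, match="row 2"):
            read_salmon_sample(d)

    def test_sailfish_comment_header(self, tmp_path):
        d = tmp_path / "s1"
        d.mkdir()
        (d / "quant.sf").write_text(
            "# sailfish v0.x\n"
            "# Name\tLength\tEffectiveLength\tTPM\tNumReads\n"
            "t1\t100\t75.0\t1000000.0\t10.0\n")
        s = read_salmon_sample(d, ReaderConfig(tool="sailfish"))
        assert s.counts[0] == 10.0

    def test_gzipped_quant_sf(self, tmp_path):
        d = tmp_path / "s1"
        d.mkdir()
        with gzip.open(d / "quant.sf.gz", "wt") as fh:
            fh.write("Name\tLength\tEffectiveLength\tTPM\tNumReads\n"
                     "t1\t100\t75.0\t1000000.0\t10.0\n")
        assert read_salmon_sample(d).counts[0] == 10.0

    def test_roundtrip_against_truth(self, small_truth, tmp_path):
        dirs = write_salmon_tree(small_truth, tmp_path / "salmon")
        for j, d in enumerate(dirs):
            s = read_salmon_sample(d)
            assert s.tx_ids == small_truth.tx_ids
            assert max_rel_err(s.counts, small_truth.counts[:, j]) < 1e-6
            assert max_rel_err(s.abundance, small_truth.abundance[:, j]) < 1e-6
            assert max_rel_err(s.eff_length, small_truth.eff_length[:, j]) < 1e-6


class TestSalmonInfReps:
    def _write_meta(self, d, n, samp_type="bootstrap"):
        (d / "aux_info").mkdir(parents=True, exist_ok=True)
        (d / "aux_info" / "meta_info.json").write_text(
            json.dumps({"num_bootstraps": n, "samp_type": samp_type}))

    def test_zero_bootstraps_gives_none(self, tmp_path):
        self._write_meta(tmp_path, 0)
        assert read_salmon_infreps(tmp_path) is None

    def test_roundtrip_float64(self, tmp_path):
        vals = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        self._write_meta(tmp_path, 3)
        bdir = tmp_path / "aux_info" / "bootstrap"
        bdir.mkdir()
        with gzip.open(bdir / "bootstraps.gz", "wb") as fh:
            fh.write(vals.astype("<f8").tobytes())
        with gzip.open(bdir / "names.tsv.gz", "wt") as fh:
            fh.write("t1\tt2")
        reps = read_salmon_infreps(tmp_path)
        np.testing.assert_array_equal(reps.matrix, vals)
        assert reps.rep_type == "bootstrap"
        assert reps.names == ["t1", "t2"]

    def test_int32_fallback_dialect(self, tmp_path):
        vals = np.array([[1, 2], [3, 4]], dtype="<i4")
        self._write_meta(tmp_path, 2, samp_type="gibbs")
        bdir = tmp_path / "aux_info" / "bootstrap"
        bdir.mkdir()
        with gzip.open(bdir / "bootstraps.gz", "wb") as fh:
            fh.write(vals.tobytes())
        with gzip.open(bdir / "names.tsv.gz", "wt") as fh:
            fh.write("t1\tt2")
        reps = read_salmon_infreps(tmp_path)
        np.testing.assert_array_equal(reps.matrix, vals.astype(float))
        assert reps.rep_type == "gibbs"

    def test_truncated_stream_reports_both_sizes(self, tmp_path):
        self._write_meta(tmp_path, 2)
        bdir = tmp_path / "aux_info" / "bootstrap"
        bdir.mkdir()
        with gzip.open(bdir / "bootstraps.gz", "wb") as fh:
            fh.write(b"\x00" * 13)
        with gzip.open(bdir / "names.tsv.gz", "wt") as fh:
            fh.write("t1\tt2")
        with pytest.raises(ParseError, match="expected 32 .*or 16"):
            read_salmon_infreps(tmp_path)

    def test_names_mismatch_is_error(self, small_truth, tmp_path):
        dirs = write_salmon_tree(small_truth, tmp_path / "salmon")
        names = dirs[0] / "aux_info" / "bootstrap" / "names.tsv.gz"
        with gzip.open(names, "wt") as fh:
            fh.write("\t".join(reversed(small_truth.tx_ids)))
        with pytest.raises(ParseError, match="names do not match"):
            read_salmon_sample(dirs[0], ReaderConfig(tool="salmon",
                                                     read_inf_reps=True))


class TestKallistoReader:
    def test_h5_abundance_normalization(self, tmp_path):
        p = tmp_path / "abundance.h5"
        with h5py.File(p, "w") as f:
            f.create_dataset("est_counts", data=[10.0, 10.0])
            aux = f.create_group("aux")
            aux.create_dataset("ids", data=[b"t1", b"t2"])
            aux.create_dataset("eff_lengths", data=[100.0, 300.0])
            aux.create_dataset("lengths", data=[150.0, 350.0])
        s = read_kallisto_sample(p)
        # (10/100)/(10/100 + 10/300) * 1e6 = 750000
        np.testing.assert_allclose(s.abundance, [750000.0, 250000.0])

    def test_h5_all_zero_counts_gives_zero_abundance(self, tmp_path):
        p = tmp_path / "abundance.h5"
        with h5py.File(p, "w") as f:
            f.create_dataset("est_counts", data=[0.0, 0.0])
            aux = f.create_group("aux")
            aux.create_dataset("ids", data=[b"t1", b"t2"])
            aux.create_dataset("eff_lengths", data=[100.0, 300.0])
            aux.create_dataset("lengths", data=[150.0, 350.0])
        s = read_kallisto_sample(p)
        np.testing.assert_array_equal(s.abundance, [0.0, 0.0])

    def test_nonpositive_eff_length_with_counts_is_error(self, tmp_path):
        p = tmp_path / "abundance.h5"
        with h5py.File(p, "w") as f:
            f.create_dataset("est_counts", data=[5.0])
            aux = f.create_group("aux")
            aux.create_dataset("ids", data=[b"t1"])
            aux.create_dataset("eff_lengths", data=[0.0])
            aux.create_dataset("lengths", data=[10.0])
        with pytest.raises(ParseError, match="t1"):
            read_kallisto_sample(p)

    def test_auto_prefers_h5_and_errors_when_neither(self, small_truth, tmp_path):
        with pytest.raises(ParseError, match="neither"):
            read_kallisto_sample(tmp_path)
        write_kallisto_tree(small_truth, tmp_path / "k", fmt="tsv")
        write_kallisto_tree(small_truth, tmp_path / "k2", fmt="h5")

    def test_tsv_and_h5_agree_on_same_truth(self, small_truth, tmp_path):
        tsv_dirs = write_kallisto_tree(small_truth, tmp_path / "tsv", fmt="tsv")
        h5_dirs = write_kallisto_tree(small_truth, tmp_path / "h5", fmt="h5")
        for dt, dh in zip(tsv_dirs, h5_dirs):
            st = read_kallisto_sample(dt)
            sh = read_kallisto_sample(dh)
            assert st.tx_ids == sh.tx_ids
            assert max_rel_err(st.counts, sh.counts) < 1e-6
            assert max_rel_err(st.abundance, sh.abundance) < 1e-6

    def test_h5_bootstraps_roundtrip(self, small_truth, tmp_path):
        dirs = write_kallisto_tree(small_truth, tmp_path / "h5", fmt="h5")
        s = read_kallisto_sample(dirs[0], ReaderConfig(tool="kallisto",
                                                       read_inf_reps=True))
        np.testing.assert_allclose(s.inf_reps, small_truth.bootstraps[:, :, 0])


class TestRsemReader:
    def test_isoforms_roundtrip(self, small_truth, tmp_path):
        paths = write_rsem_files(small_truth, tmp_path / "rsem",
                                 level="isoforms")
        cfg = ReaderConfig(tool="rsem", rsem_level="isoforms")
        for j, p in enumerate(paths):
            s = read_rsem_sample(p, cfg)
            assert s.tx_ids == small_truth.tx_ids
            assert max_rel_err(s.counts, small_truth.counts[:, j]) < 1e-6

    def test_genes_level_one_row_per_gene(self, small_truth, tmp_path):
        paths = write_rsem_files(small_truth, tmp_path / "rsem", level="genes")
        cfg = ReaderConfig(tool="rsem", rsem_level="genes")
        s = read_rsem_sample(paths[0], cfg)
        assert s.tx_ids == sorted(set(small_truth.gene_ids))

    def test_fractional_expected_count(self, tmp_path):
        p = tmp_path / "x.genes.results"
        p.write_text("gene_id\ttranscript_id(s)\tlength\teffective_length\t"
                     "expected_count\tTPM\tFPKM\n"
                     "g1\tt1,t2\t500\t400\t12.5\t1000000\t0\n")
        s = read_rsem_sample(p, ReaderConfig(tool="rsem", rsem_level="genes"))
        assert s.counts[0] == 12.5


class TestGenericReader:
    def test_colmap_matches_salmon_reader(self, small_truth, tmp_path):
        dirs = write_salmon_tree(small_truth, tmp_path / "salmon")
        colmap = {"id": "Name", "length": "Length",
                  "eff_length": "EffectiveLength", "abundance": "TPM",
                  "counts": "NumReads"}
        direct = read_salmon_sample(dirs[0])
        generic = read_generic_table(dirs[0] / "quant.sf", colmap)
        assert generic.tx_ids == direct.tx_ids
        np.testing.assert_array_equal(generic.counts, direct.counts)
        np.testing.assert_array_equal(generic.abundance, direct.abundance)

    def test_abundance_derived_by_normalization(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("id\tel\tn\nt1\t100\t10\nt2\t300\t10\n")
        s = read_generic_table(p, {"id": "id", "eff_length": "el",
                                   "counts": "n"})
        np.testing.assert_allclose(s.abundance, [750000.0, 250000.0])

    def test_missing_counts_and_abundance_is_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("id\tel\nt1\t100\n")
        with pytest.raises(ParseError, match="neither counts nor abundance"):
            read_generic_table(p, {"id": "id", "eff_length": "el"})

    def test_missing_counts_requires_cfa_opt_in(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("id\tel\ttpm\nt1\t100\t600000\nt2\t300\t400000\n")
        with pytest.raises(ParseError, match="counts-from-abundance"):
            read_generic_table(p, {"id": "id", "eff_length": "el",
                                   "abundance": "tpm"})
        s = read_generic_table(p, {"id": "id", "eff_length": "el",
                                   "abundance": "tpm"},
                               allow_derived_counts=True)
        np.testing.assert_array_equal(s.counts, s.abundance)


class TestImportQuant:
    def test_single_sample_tx_out_identity(self, small_truth, tmp_path):
        dirs = write_salmon_tree(small_truth, tmp_path / "salmon")
        res = import_quant([dirs[0]], ReaderConfig(tool="salmon"),
                           tx_out=True)
        assert res.level == "transcript"
        assert res.sample_ids == [dirs[0].name]
        s = read_salmon_sample(dirs[0])
        np.testing.assert_array_equal(res.counts.to_numpy()[:, 0], s.counts)

    def test_columns_follow_file_order(self, small_truth, tmp_path):
        dirs = write_salmon_tree(small_truth, tmp_path / "salmon")
        res = import_quant(dirs, ReaderConfig(tool="salmon"), tx_out=True)
        for j in range(len(dirs)):
            assert max_rel_err(res.counts.to_numpy()[:, j],
                               small_truth.counts[:, j]) < 1e-6

    def test_shuffled_file_order_permutes_columns_only(self, small_truth,
                                                       tmp_path):
        dirs = write_salmon_tree(small_truth, tmp_path / "salmon")
        fwd = import_quant(dirs, ReaderConfig(tool="salmon"), tx_out=True)
        rev = import_quant(dirs[::-1], ReaderConfig(tool="salmon"),
                           tx_out=True)
        np.testing.assert_array_equal(
            rev.counts[fwd.sample_ids].to_numpy(), fwd.counts.to_numpy())

    def test_gene_level_import_matches_oracle(self, small_truth, tmp_path):
        dirs = write_salmon_tree(small_truth, tmp_path / "salmon")
        res = import_quant(dirs, ReaderConfig(tool="salmon"),
                           tx2gene=small_truth.tx2gene)
        oracle = oracle_summarize(small_truth)
        for name in ("abundance", "counts", "length"):
            # text round-trip in the fixture tree bounds the error
            assert max_rel_err(getattr(res, name).to_numpy(),
                               oracle[name].to_numpy()) < 1e-6

    def test_mismatched_ids_name_offending_sample(self, small_truth, tmp_path):
        dirs = write_salmon_tree(small_truth, tmp_path / "salmon")
        quant = dirs[1] / "quant.sf"
        text = quant.read_text().replace(small_truth.tx_ids[0], "ROGUE", 1)
        quant.write_text(text)
        with pytest.raises(ValidationError, match=dirs[1].name):
            import_quant(dirs, ReaderConfig(tool="salmon"), tx_out=True)

    def test_gene_level_without_tx2gene_is_error(self, small_truth, tmp_path):
        dirs = write_salmon_tree(small_truth, tmp_path / "salmon")
        with pytest.raises(ValidationError, match="tx2gene"):
            import_quant(dirs, ReaderConfig(tool="salmon"))

    def test_drop_with_var_reduce_is_contradictory(self, small_truth,
                                                   tmp_path):
        dirs = write_salmon_tree(small_truth, tmp_path / "salmon")
        with pytest.raises(ValidationError, match="drop_inf_reps"):
            import_quant(dirs, ReaderConfig(tool="salmon"), tx_out=True,
                         drop_inf_reps=True, var_reduce_reps=True)

    def test_var_reduce_produces_variance_matrix(self, small_truth, tmp_path):
        dirs = write_salmon_tree(small_truth, tmp_path / "salmon")
        res = import_quant(dirs, ReaderConfig(tool="salmon",
                                              read_inf_reps=True),
                           tx2gene=small_truth.tx2gene, var_reduce_reps=True)
        assert res.inf_reps is None
        assert res.inf_rep_variance is not None
        assert res.inf_rep_variance.shape == res.counts.shape
        assert (res.inf_rep_variance.to_numpy() >= 0).all()

    def test_version_stripping_harmonizes_ids(self, tmp_path):
        d = write_quant_sf(tmp_path / "s1",
                           ["t1.2\t100\t75.0\t600000\t10",
                            "t2.1\t100\t75.0\t400000\t5"])
        from txquant import Tx2Gene
        mapping = Tx2Gene([("t1", "g1"), ("t2", "g1")])
        res = import_quant([d], ReaderConfig(tool="salmon"), tx2gene=mapping,
                           ignore_tx_version=True)
        assert res.feature_ids == ["g1"]
        assert res.counts.to_numpy()[0, 0] == 15.0
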