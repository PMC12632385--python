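import json

import numpy as np
import pandas as pd
import pytest

from exlnc import chromatin_link, diff_sets, genome_io
from exlnc.synthetic_data import (SynthConfig, generate_dataset,
                                  generate_sequences, write_dataset,
                                  write_fasta)


def tiny_cfg(**kw):
    base = dict(n_lnc=30, n_coding=60, n_peaks=100, n_tissues=1, seed=9)
    base.update(kw)
    return SynthConfig(**base)


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        a = generate_dataset(tiny_cfg())
        b = generate_dataset(tiny_cfg())
        assert a.genes == b.genes
        assert a.peaks == b.peaks
        for t in a.config.tissues:
            pd.testing.assert_frame_equal(a.diff_tables[t], b.diff_tables[t])
            pd.testing.assert_frame_equal(a.lnc_trajectories[t],
                                          b.lnc_trajectories[t])
        assert a.truth.coupled_pairs == b.truth.coupled_pairs

    def test_same_seed_identical_files(self, tmp_path):
        pa = write_dataset(generate_dataset(tiny_cfg()), str(tmp_path / "a"))
        pb = write_dataset(generate_dataset(tiny_cfg()), str(tmp_path / "b"))
        for key in pa:
            with open(pa[key]) as fa, open(pb[key]) as fb:
                assert fa.read() == fb.read(), key

    def test_different_seed_differs(self):
        a = generate_dataset(tiny_cfg(seed=1))
        b = generate_dataset(tiny_cfg(seed=2))
        assert a.genes != b.genes


class TestAnnotation:
    def test_full_coupling_places_partner_peaks_in_window(self):
        ds = generate_dataset(tiny_cfg(frac_coupled=1.0))
        assert len(ds.truth.coupled_pairs) == len(ds.lnc_models)
        peak_by_id = {p.peak_id: p for p in ds.peaks}
        gene_by_id = {g.gene_id: g for g in ds.genes}
        for ln, pk in ds.truth.coupled_pairs:
            d = abs(gene_by_id[ln].interval.midpoint
                    - peak_by_id[pk].interval.midpoint)
            # trimming the raw partner peak can shift its midpoint slightly
            assert d <= ds.config.coupling_max_dist + 200

    def test_truth_pairs_recovered_by_local_pairing(self):
        ds = generate_dataset(tiny_cfg(frac_coupled=0.5))
        found = {(p.lnc_id, p.peak_id) for p in
                 chromatin_link.find_local_pairs(ds.lnc_models, ds.peaks)}
        assert ds.truth.coupled_pairs <= found

    def test_excessive_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            generate_dataset(tiny_cfg(n_lnc=5000, n_coding=5000,
                                      chrom_lengths={"chr1": 1_000_000}))


class TestDiffTables:
    def test_planted_null_separation(self):
        ds = generate_dataset(tiny_cfg())
        t = ds.config.tissues[0]
        recs = ds.diff_tables[t]
        truth = ds.truth.diff_cells[t]
        keyed = recs.set_index(["feature_id", "sex", "week"])
        for key, row in keyed.iterrows():
            if key in truth:
                assert row["p_value"] < 1e-4
                assert abs(row["log2fc"]) >= 1.0
                assert row["mean_fpkm"] >= 1.0
            else:
                assert row["p_value"] > 0.1

    def test_truth_survives_expression_and_threshold_gates(self):
        ds = generate_dataset(tiny_cfg())
        t = ds.config.tissues[0]
        recs = ds.diff_tables[t]
        expressed = diff_sets.filter_expressed(recs)
        called = diff_sets.call_differential(
            recs[recs["feature_id"].isin(expressed)]).members
        assert called == ds.truth.diff_cells[t]

    def test_no_planting_yields_no_calls(self):
        ds = generate_dataset(tiny_cfg(frac_diff=0.0, frac_coupled=0.0))
        t = ds.config.tissues[0]
        assert ds.truth.diff_cells[t] == set()
        called = diff_sets.call_differential(ds.diff_tables[t]).members
        assert called == set()

    def test_noise_free_coupling_is_perfectly_correlated(self):
        ds = generate_dataset(tiny_cfg(noise_sd=0.0, frac_coupled=0.5,
                                       guarantee_separation=False))
        t = ds.config.tissues[0]
        for ln, pk in ds.truth.coupled_pairs:
            r = chromatin_link.correlate_pair(
                ds.lnc_trajectories[t].loc[ln].to_numpy(),
                ds.peak_trajectories[t].loc[pk].to_numpy())
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_coupling_calibration_near_target(self):
        from exlnc.experiments import coupling_calibration
        res = coupling_calibration(seed=11, n_seeds=5)
        assert abs(res["mean_r"] - res["target_r"]) <= 0.05


class TestFileRoundTrip:
    def test_outputs_parse_through_readers(self, tmp_path, small_dataset):
        paths = write_dataset(small_dataset, str(tmp_path))
        genes = genome_io.read_gene_models(paths["gtf"])
        assert genes == small_dataset.genes
        raw = genome_io.read_peaks(paths["peaks"])
        assert raw == small_dataset.raw_peaks
        counts = genome_io.read_peak_counts(paths["counts"])
        assert set(counts) == set(small_dataset.peak_counts)
        truth = json.load(open(paths["truth"]))
        assert len(truth["coupled_pairs"]) == \
            len(small_dataset.truth.coupled_pairs)
        t = small_dataset.config.tissues[0]
        back = diff_sets.read_diff_table(paths[f"{t}.diff"])
        assert len(back) == len(small_dataset.diff_tables[t])


class TestSequences:
    def test_gc_concentrates_around_target(self):
        from exlnc.seq_features import gc_content
        records, _ = generate_sequences(100, (500, 500), 0.5, seed=3)
        mean_gc = np.mean([gc_content(s) for _, s in records])
        assert 45 <= mean_gc <= 55

    def test_planted_orf_is_found_at_recorded_offset(self):
        from exlnc.seq_features import find_smorfs
        records, planted = generate_sequences(20, (300, 600), 0.5, seed=4,
                                              planted_orf_len=60)
        seqs = dict(records)
        for sid, offset, nt_len in planted:
            orfs = find_smorfs(seqs[sid], min_len=30, seq_id=sid)
            assert any(o.start_nt == offset for o in orfs)

    def test_same_seed_identical_fasta(self, tmp_path):
        for sub in ("a", "b"):
            records, _ = generate_sequences(10, (100, 200), 0.4, seed=8)
            write_fasta(records, str(tmp_path / f"{sub}.fa"))
        assert (tmp_path / "a.fa").read_text() == \
            (tmp_path / "b.fa").read_text()

    def test_bad_gc_target_rejected(self):
        with pytest.raises(ValueError):
            generate_sequences(1, (100, 100), 1.5, seed=0)
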