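import numpy as np
import pytest

from exlnc import genome_io, reference
from exlnc.genome_io import (BIOTYPE_CODING, BIOTYPE_LNCRNA, BIOTYPE_OTHER,
                             GenomicInterval, Peak, PeakCounts)

from conftest import make_peak


GTF_LINES = [
    'chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "g_plus"; gene_biotype "lncRNA";',
    'chr1\tsrc\tgene\t101\t200\t.\t-\t.\tgene_id "g_minus"; gene_biotype "lncRNA";',
    'chr1\tsrc\tgene\t301\t500\t.\t+\t.\tgene_id "g_pc"; gene_biotype "protein_coding";',
    'chr1\tsrc\tgene\t601\t700\t.\t+\t.\tgene_id "g_misc"; gene_biotype "snoRNA";',
]


def write_gtf(tmp_path, lines):
    path = tmp_path / "test.gtf"
    path.write_text("\n".join(lines) + "\n")
    return str(path)


class TestReadGeneModels:
    def test_coordinate_conversion_and_tss(self, tmp_path):
        """GTF 1-based closed becomes 0-based half-open; TSS is strand-aware."""
        models = {g.gene_id: g for g in
                  genome_io.read_gene_models(write_gtf(tmp_path, GTF_LINES))}
        plus = models["g_plus"]
        assert (plus.interval.start, plus.interval.end) == (100, 200)
        assert plus.tss == 100
        assert models["g_minus"].tss == 199
        assert plus.biotype == BIOTYPE_LNCRNA
        assert models["g_pc"].biotype == BIOTYPE_CODING
        assert models["g_misc"].biotype == BIOTYPE_OTHER

    def test_malformed_line_reports_line_number(self, tmp_path):
        lines = GTF_LINES[:1] + ["chr1\tonly\tthree"]
        with pytest.raises(ValueError, match="line 2"):
            genome_io.read_gene_models(write_gtf(tmp_path, lines))

    def test_duplicate_gene_id_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate gene_id"):
            genome_io.read_gene_models(
                write_gtf(tmp_path, GTF_LINES[:1] + GTF_LINES[:1]))

    def test_round_trip(self, tmp_path, small_dataset):
        path = str(tmp_path / "rt.gtf")
        genome_io.write_gene_models(small_dataset.genes, path)
        back = genome_io.read_gene_models(path)
        assert back == small_dataset.genes


class TestReadPeaks:
    def test_bed3_midpoint_fallback(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t900\t1100\n")
        (peak,) = genome_io.read_peaks(str(p))
        assert (peak.interval.start, peak.interval.end) == (900, 1100)
        assert peak.summit == 1000

    def test_narrowpeak_summit_offset(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t900\t1100\tpk1\t0\t.\t5.0\t-1\t-1\t50\n")
        (peak,) = genome_io.read_peaks(str(p))
        assert peak.summit == 950
        assert peak.peak_id == "pk1"

    def test_negative_offset_falls_back_to_midpoint(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t900\t1100\tpk1\t0\t.\t5.0\t-1\t-1\t-1\n")
        (peak,) = genome_io.read_peaks(str(p))
        assert peak.summit == 1000

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1100\t900\n")
        with pytest.raises(ValueError, match="start"):
            genome_io.read_peaks(str(p))

    def test_round_trip(self, tmp_path, small_dataset):
        path = str(tmp_path / "rt.narrowPeak")
        genome_io.write_peaks(small_dataset.raw_peaks, path)
        assert genome_io.read_peaks(path) == small_dataset.raw_peaks


class TestTrimAndMerge:
    def test_single_peak_trimmed_to_200(self):
        (out,) = genome_io.trim_and_merge_peaks(
            [make_peak("p", "chr1", 800, 1300, summit=1000)])
        assert (out.interval.start, out.interval.end) == (900, 1100)
        assert len(out.interval) == 200

    def test_overlapping_and_bookended_merge(self):
        peaks = [make_peak("a", "chr1", 900, 1100, summit=1000),
                 make_peak("b", "chr1", 1050, 1250, summit=1150),
                 make_peak("c", "chr1", 1350, 1450, summit=1400)]
        out = genome_io.trim_and_merge_peaks(peaks)
        spans = [(p.interval.start, p.interval.end) for p in out]
        assert spans == [(900, 1250), (1300, 1500)]
        # book-ended: [900,1100) + [1100,1300) merge
        out2 = genome_io.trim_and_merge_peaks(
            [make_peak("a", "chr1", 900, 1100, summit=1000),
             make_peak("b", "chr1", 1100, 1300, summit=1200)])
        assert [(p.interval.start, p.interval.end) for p in out2] == \
            [(900, 1300)]

    def test_clamped_at_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="exlnc.genome_io"):
            (out,) = genome_io.trim_and_merge_peaks(
                [make_peak("p", "chr1", 0, 100, summit=30)])
        assert out.interval.start == 0
        assert "clamped" in caplog.text

    def test_idempotent_on_master_list(self, small_dataset):
        master = genome_io.trim_and_merge_peaks(small_dataset.raw_peaks)
        again = genome_io.trim_and_merge_peaks(master)
        assert [(p.chrom, p.interval.start, p.interval.end) for p in again] \
            == [(p.chrom, p.interval.start, p.interval.end) for p in master]

    def test_output_sorted_and_nonoverlapping(self, small_dataset):
        master = genome_io.trim_and_merge_peaks(small_dataset.raw_peaks)
        prev = {}
        for p in master:
            if p.chrom in prev:
                assert p.interval.start > prev[p.chrom]
            prev[p.chrom] = p.interval.end


class TestCountFilter:
    @pytest.mark.parametrize("counts,kept", [
        ([12, 11, 10, 10, 0], True),   # 4 samples >= 10
        ([9, 9, 9, 9, 9], False),
        ([10, 10, 10, 2, 2], False),   # only 3 samples
    ])
    def test_threshold_examples(self, counts, kept):
        peak = make_peak("p1", "chr1", 0, 200)
        out = genome_io.filter_peaks_by_counts(
            [peak], [PeakCounts("p1", tuple(counts))])
        assert (len(out) == 1) == kept

    def test_nonstandard_contig_dropped(self):
        peaks = [make_peak("a", "chr1", 0, 200),
                 make_peak("b", "chrX", 0, 200),
                 make_peak("c", "chrUn_scaffold12", 0, 200),
                 make_peak("d", "chrM", 0, 200)]
        counts = {p.peak_id: np.full(5, 50) for p in peaks}
        out = genome_io.filter_peaks_by_counts(peaks, counts)
        assert [p.peak_id for p in out] == ["a", "b"]
        # explicit allow-list overrides the default
        out2 = genome_io.filter_peaks_by_counts(
            peaks, counts, allowed_chroms=["chrM"])
        assert [p.peak_id for p in out2] == ["d"]

    def test_missing_counts_row_names_peak(self):
        with pytest.raises(ValueError, match="orphan"):
            genome_io.filter_peaks_by_counts(
                [make_peak("orphan", "chr1", 0, 200)], {})

    def test_matches_bruteforce_on_random_matrix(self, rng, small_dataset):
        peaks = small_dataset.peaks
        counts = {p.peak_id: rng.integers(0, 25, size=8) for p in peaks}
        fast = genome_io.filter_peaks_by_counts(peaks, counts)
        brute = reference.count_filter_bruteforce(peaks, counts)
        assert fast == brute
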