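import numpy as np
import pandas as pd
import pytest

from exlnc import chromatin_link as cl
from exlnc import reference
from exlnc.genome_io import BIOTYPE_CODING, BIOTYPE_LNCRNA

from conftest import make_gene, make_peak


class TestFindLocalPairs:
    def test_window_boundary_inclusive(self):
        lnc = make_gene("L", "chr1", 99_000, 101_000)  # midpoint 100,000
        peaks = [make_peak("in", "chr1", 549_000, 551_000),      # 450 kb
                 make_peak("edge", "chr1", 599_000, 601_000),    # 500 kb exact
                 make_peak("out", "chr1", 649_000, 651_000),     # 550 kb
                 make_peak("otherchrom", "chr2", 100_000, 102_000)]
        pairs = cl.find_local_pairs([lnc], peaks)
        got = {(p.peak_id, p.midpoint_distance) for p in pairs}
        assert got == {("in", 450_000), ("edge", 500_000)}

    def test_zero_window_only_coincident_midpoints(self):
        lnc = make_gene("L", "chr1", 1000, 3000)  # midpoint 2000
        peaks = [make_peak("same", "chr1", 1900, 2100),
                 make_peak("near", "chr1", 1910, 2100)]
        pairs = cl.find_local_pairs([lnc], peaks, window=0)
        assert [p.peak_id for p in pairs] == ["same"]

    def test_matches_bruteforce(self, small_dataset):
        lncs = small_dataset.lnc_models
        peaks = small_dataset.peaks
        fast = {(p.lnc_id, p.peak_id, p.midpoint_distance)
                for p in cl.find_local_pairs(lncs, peaks)}
        assert fast == reference.local_pairs_bruteforce(lncs, peaks, 500_000)


class TestCorrelatePair:
    def test_exact_examples(self):
        assert cl.correlate_pair([1, 2, 3, 4, 1, 2, 3, 4],
                                 [2, 4, 6, 8, 2, 4, 6, 8]) == pytest.approx(1.0)
        x = np.arange(8.0)
        assert cl.correlate_pair(x, -x) == pytest.approx(-1.0)
        assert cl.correlate_pair([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_matches_definitional_formula(self, rng):
        for _ in range(200):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            r = cl.correlate_pair(x, y)
            assert r == pytest.approx(
                reference.pearson_definitional(list(x), list(y)), abs=1e-12)

    def test_zero_variance_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="exlnc.chromatin_link"):
            r = cl.correlate_pair([1.0] * 8, list(range(8)))
        assert r is None
        assert "zero-variance" in caplog.text

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            cl.correlate_pair([1, 2], [3, 4])


class TestNearestCodingTSS:
    def test_ignores_noncoding_neighbors(self):
        peak = make_peak("p", "chr1", 9900, 10100, summit=10_000)
        genes = [make_gene("pc_far", "chr1", 12_500, 13_000, "+",
                           BIOTYPE_CODING),
                 make_gene("pc_near", "chr1", 9_000, 9_500, "+",
                           BIOTYPE_CODING),
                 make_gene("lnc_nearest", "chr1", 10_100, 10_200, "+",
                           BIOTYPE_LNCRNA)]
        assert cl.nearest_coding_tss(peak, genes) == ("pc_near", 1000)

    def test_summit_on_tss_distance_zero(self):
        peak = make_peak("p", "chr1", 9900, 10100, summit=10_000)
        genes = [make_gene("pc", "chr1", 10_000, 11_000, "+", BIOTYPE_CODING)]
        assert cl.nearest_coding_tss(peak, genes) == ("pc", 0)

    def test_minus_strand_tss_is_right_end(self):
        peak = make_peak("p", "chr1", 9900, 10100, summit=10_000)
        genes = [make_gene("pc", "chr1", 5_000, 10_001, "-", BIOTYPE_CODING)]
        assert cl.nearest_coding_tss(peak, genes) == ("pc", 0)

    def test_tie_broken_lexicographically(self):
        peak = make_peak("p", "chr1", 9900, 10100, summit=10_000)
        # TSSs at 11,000 and 9,000: both exactly 1,000 bp from the summit
        genes = [make_gene("pc_b", "chr1", 11_000, 12_000, "+", BIOTYPE_CODING),
                 make_gene("pc_a", "chr1", 9_000, 9_500, "+", BIOTYPE_CODING)]
        assert cl.nearest_coding_tss(peak, genes) == ("pc_a", 1000)

    def test_no_coding_gene_returns_none(self, caplog):
        peak = make_peak("p", "chr1", 9900, 10100)
        with caplog.at_level("WARNING", logger="exlnc.chromatin_link"):
            assert cl.nearest_coding_tss(peak, []) is None
        assert "no protein-coding" in caplog.text


class TestActivityScore:
    @pytest.mark.parametrize("r,d,expected", [
        (1.0, 0, 1.0), (0.8, 7, 0.1), (-0.5, 0, -0.5),
    ])
    def test_examples(self, r, d, expected):
        assert cl.activity_score(r, d) == pytest.approx(expected)

    def test_grid_properties(self):
        """Sign preserved, |score| <= |r|, strictly decreasing in distance."""
        for r in np.linspace(-1, 1, 41):
            prev = None
            for d in [0, 1, 2, 5, 10, 100, 1000, 10**6]:
                s = cl.activity_score(r, d)
                assert abs(s) <= abs(r) + 1e-15
                assert np.sign(s) == np.sign(r)
                if d == 0:
                    assert s == r
                if prev is not None and r > 0:
                    assert s < prev
                prev = s

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            cl.activity_score(0.5, -1)


class TestBuildTriads:
    def setup_method(self):
        self.genes = [
            make_gene("pcA", "chr1", 100_000, 110_000, "+", BIOTYPE_CODING),
            make_gene("pcB", "chr1", 500_000, 520_000, "+", BIOTYPE_CODING),
            make_gene("L1", "chr1", 90_000, 95_000),
            make_gene("L2", "chr1", 480_000, 485_000),
        ]
        self.peaks = [
            make_peak("pk1", "chr1", 99_850, 100_050, summit=99_950),
            make_peak("pk2", "chr1", 99_000, 99_200, summit=99_100),
            make_peak("pk3", "chr1", 499_900, 500_100, summit=500_000),
        ]

    def pairs(self, rs):
        return [cl.LocalPair(l, p, "chr1", 0, r) for (l, p), r in rs.items()]

    def test_r_threshold_and_direction(self):
        pairs = self.pairs({("L1", "pk1"): 0.6, ("L2", "pk3"): 0.4})
        triads = cl.build_triads(pairs, self.genes, self.peaks,
                                 {"pcA"}, set())
        assert len(triads) == 1
        t = triads[0]
        assert (t.lnc_id, t.gene_id, t.gene_direction) == ("L1", "pcA", "up")
        assert t.tss_distance == 50
        assert t.activity_score == pytest.approx(0.6 / 51)

    def test_per_gene_max_score_retained(self):
        # pk1 closer to pcA TSS (50 bp) than pk2 (900 bp): same gene, pk1 wins
        pairs = self.pairs({("L1", "pk1"): 0.6, ("L1", "pk2"): 0.9})
        triads = cl.build_triads(pairs, self.genes, self.peaks, set(), set())
        assert len(triads) == 1
        assert triads[0].peak_id == "pk1"  # 0.6/51 > 0.9/901
        assert triads[0].gene_direction == "ns"

    def test_each_gene_appears_once_sorted_by_score(self):
        pairs = self.pairs({("L1", "pk1"): 0.6, ("L1", "pk2"): 0.9,
                            ("L2", "pk3"): 1.0})
        triads = cl.build_triads(pairs, self.genes, self.peaks, set(), set())
        gene_ids = [t.gene_id for t in triads]
        assert sorted(gene_ids) == sorted(set(gene_ids))
        scores = [t.activity_score for t in triads]
        assert scores == sorted(scores, reverse=True)

    def test_missing_r_dropped(self):
        pairs = [cl.LocalPair("L1", "pk1", "chr1", 0, None)]
        assert cl.build_triads(pairs, self.genes, self.peaks, set(),
                               set()) == []

    def test_overlapping_direction_sets_rejected(self):
        with pytest.raises(ValueError):
            cl.build_triads([], self.genes, self.peaks, {"g"}, {"g"})
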