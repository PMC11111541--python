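"""Coordinate types, file round-trips, and interval algebra vs brute force."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromlink.genome import (
    Contact,
    Gene,
    GeneSet,
    GenomeLayout,
    GenomicInterval,
    ParseError,
    intersect_regions,
    make_promoters,
    merge_intervals,
    nearest_distance,
    normalize_chrom,
    read_bed,
    read_bedpe_contacts,
    read_gene_table,
    write_bed,
    write_bedpe_contacts,
    write_gene_table,
)

from conftest import random_intervals


class TestGenomicInterval:
    def test_rejects_degenerate_and_negative(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_half_open_abutment_does_not_overlap(self):
        a = GenomicInterval("chr1", 0, 100)
        b = GenomicInterval("chr1", 100, 200)
        assert not a.overlaps(b)
        assert a.overlap_length(GenomicInterval("chr1", 50, 150)) == 50


class TestGene:
    @pytest.mark.parametrize("strand,expected_tss", [("+", 1000), ("-", 4999)])
    def test_strand_aware_tss(self, strand, expected_tss):
        g = Gene("g1", GenomicInterval("chr1", 1000, 5000), strand)
        assert g.tss == expected_tss

    def test_duplicate_gene_id_rejected(self):
        g = Gene("g1", GenomicInterval("chr1", 0, 10), "+")
        with pytest.raises(ValueError, match="duplicate"):
            GeneSet([g, g])


class TestContact:
    def test_cis_distance_is_start_difference(self):
        c = Contact(GenomicInterval("chr1", 20_000, 40_000),
                    GenomicInterval("chr1", 120_000, 140_000), 0.001, 1.0)
        assert c.distance == 100_000

    def test_trans_contact_has_no_distance(self):
        c = Contact(GenomicInterval("chr1", 0, 20_000),
                    GenomicInterval("chr2", 0, 20_000), 0.001, 1.0)
        assert not c.is_cis and c.distance is None


class TestReaders:
    def test_gene_table_roundtrip(self, tmp_path):
        genes = GeneSet([
            Gene("g1", GenomicInterval("chr1", 1000, 5000), "+"),
            Gene("g2", GenomicInterval("chr2", 2000, 9000), "-"),
        ])
        path = tmp_path / "genes.tsv"
        write_gene_table(path, genes, ["test"])
        back = read_gene_table(path)
        assert [(g.gene_id, g.chrom, g.interval.start, g.interval.end, g.strand, g.tss)
                for g in back] == [("g1", "chr1", 1000, 5000, "+", 1000),
                                   ("g2", "chr2", 2000, 9000, "-", 8999)]

    def test_gene_table_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tstart\tend\tstrand\tgene_id\nchr1\tabc\t10\t+\tg1\n")
        with pytest.raises(ParseError, match=":2:"):
            read_gene_table(path)

    def test_bedpe_q_filter_and_roundtrip(self, tmp_path):
        rows = [
            ("chr1", 0, 20_000, "chr1", 100_000, 120_000, 0.001, 1.5),
            ("chr1", 0, 20_000, "chr1", 200_000, 220_000, 0.02, 2.0),
            ("chr1", 0, 20_000, "chr2", 0, 20_000, 0.009, 0.5),
        ]
        path = tmp_path / "c.bedpe"
        path.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
        contacts = read_bedpe_contacts(path, q_threshold=0.01)
        assert len(contacts) == 2
        assert contacts[0].distance == 100_000
        assert contacts[1].distance is None  # inter-chromosomal
        out = tmp_path / "c2.bedpe"
        write_bedpe_contacts(out, contacts)
        again = read_bedpe_contacts(out, q_threshold=0.01)
        assert [(c.anchor1, c.anchor2, c.qvalue, c.oe) for c in again] == \
               [(c.anchor1, c.anchor2, c.qvalue, c.oe) for c in contacts]

    def test_bedpe_bad_width_warns_or_rejects(self, tmp_path):
        path = tmp_path / "c.bedpe"
        path.write_text("chr1\t0\t15000\tchr1\t100000\t120000\t0.001\t1.0\n")
        with pytest.warns(UserWarning):
            kept = read_bedpe_contacts(path, q_threshold=0.01, on_bad_width="warn")
        assert len(kept) == 1
        with pytest.warns(UserWarning):
            dropped = read_bedpe_contacts(path, q_threshold=0.01, on_bad_width="reject")
        assert dropped == []

    def test_bed_roundtrip_and_errors(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr1\t0\t100\nchr2\t5\t10\tpeak1\t3.5\n")
        ivs = read_bed(path)
        assert ivs[0].length == 100 and ivs[1].name == "peak1" and ivs[1].score == 3.5
        out = tmp_path / "b.bed"
        write_bed(out, ivs)
        assert [(i.chrom, i.start, i.end) for i in read_bed(out)] == \
               [(i.chrom, i.start, i.end) for i in ivs]
        (tmp_path / "empty.bed").write_text("")
        assert read_bed(tmp_path / "empty.bed") == []
        (tmp_path / "zero.bed").write_text("chr1\t100\t100\n")
        with pytest.raises(ParseError):
            read_bed(tmp_path / "zero.bed")

    def test_one_based_conversion_and_chrom_style(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("1\t1\t100\n")
        iv = read_bed(path, one_based=True, chrom_style="chr")[0]
        assert (iv.chrom, iv.start, iv.end) == ("chr1", 0, 100)
        assert normalize_chrom("chrX", "plain") == "X"


class TestIntersect:
    def test_half_open_abutment(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 100, 200)]
        assert intersect_regions(a, b) == []

    def test_min_overlap_threshold(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 50, 150)]
        assert intersect_regions(a, b, min_overlap_bp=50) == [(0, 0)]
        assert intersect_regions(a, b, min_overlap_bp=51) == []

    def test_matches_all_pairs_brute_force(self, rng):
        query = random_intervals(rng, 300)
        subject = random_intervals(rng, 300)
        got = set(intersect_regions(query, subject))
        expected = {
            (i, j)
            for i, q in enumerate(query)
            for j, s in enumerate(subject)
            if q.chrom == s.chrom and min(q.end, s.end) - max(q.start, s.start) >= 1
        }
        assert got == expected


class TestNearestDistance:
    def test_overlap_and_gap(self):
        q = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 0, 100)]
        r = [GenomicInterval("chr1", 50, 60), GenomicInterval("chr1", 150, 160)]
        d = nearest_distance(q, r)
        assert d[0] == 0.0
        d2 = nearest_distance([GenomicInterval("chr1", 0, 100)],
                              [GenomicInterval("chr1", 150, 160)])
        assert d2[0] == 50.0

    def test_empty_reference_is_error(self):
        with pytest.raises(ValueError):
            nearest_distance([GenomicInterval("chr1", 0, 10)], [])

    def test_other_chromosome_gives_nan(self):
        d = nearest_distance([GenomicInterval("chr3", 0, 10)],
                             [GenomicInterval("chr1", 0, 10)])
        assert np.isnan(d[0])

    def test_matches_brute_force(self, rng):
        query = random_intervals(rng, 400)
        reference = random_intervals(rng, 150)
        got = nearest_distance(query, reference)
        for i, q in enumerate(query):
            dists = [
                max(r.start - q.end, q.start - r.end, 0)
                for r in reference if r.chrom == q.chrom
            ]
            if dists:
                assert got[i] == min(dists)
            else:
                assert np.isnan(got[i])

    @given(offset=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_shift_invariance(self, offset):
        q = [GenomicInterval("chr1", 500, 600)]
        r = [GenomicInterval("chr1", 900, 1000), GenomicInterval("chr1", 10, 20)]
        base = nearest_distance(q, r)[0]
        shifted = nearest_distance([q[0].shifted(offset)], [iv.shifted(offset) for iv in r])[0]
        assert shifted == base


class TestPromoters:
    def test_plus_strand_window(self):
        g = Gene("g1", GenomicInterval("chr1", 10_000, 20_000), "+")
        p = make_promoters([g], 2_000, 500)[0]
        assert (p.start, p.end) == (8_000, 10_500)

    def test_minus_strand_window_is_strand_flipped(self):
        g = Gene("g1", GenomicInterval("chr1", 2_000, 10_001), "-")  # tss = 10000
        p = make_promoters([g], 2_000, 500)[0]
        assert (p.start, p.end) == (9_501, 12_001)

    def test_clipped_at_chromosome_start(self):
        g = Gene("g1", GenomicInterval("chr1", 500, 5_000), "+")
        p = make_promoters([g], 2_000, 500)[0]
        assert p.start == 0


def test_merge_intervals_handles_overlap_and_abutment():
    merged = merge_intervals([
        GenomicInterval("chr1", 0, 100),
        GenomicInterval("chr1", 50, 150),
        GenomicInterval("chr1", 150, 200),
        GenomicInterval("chr2", 0, 10),
    ])
    assert [(m.chrom, m.start, m.end) for m in merged] == \
        [("chr1", 0, 200), ("chr2", 0, 10)]


def test_layout_validates_and_bins():
    layout = GenomeLayout({"chr1": 100_000}, bin_size=20_000)
    b = layout.bin_of("chr1", 45_000)
    assert (b.start, b.end) == (40_000, 60_000)
    with pytest.raises(ValueError):
        GenomeLayout({"chr1": 100}, bin_size=0)
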