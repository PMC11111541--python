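"""Mark-site annotation, mark-anchor association, and signal profiles."""

import numpy as np
import pytest

from chromlink.genome import Gene, GeneSet, GenomicInterval, make_promoters
from chromlink.marks import (
    MarkSite,
    classify_annotation,
    deg_mark_overlap,
    mark_target_association,
    read_mark_table,
    signal_profile_matrix,
    write_mark_table,
)


def _site(chrom, start, end, direction="up", kind="DMS"):
    return MarkSite(GenomicInterval(chrom, start, end), kind, direction)


class TestMarkSite:
    def test_direction_effect_consistency(self):
        with pytest.raises(ValueError, match="inconsistent"):
            MarkSite(GenomicInterval("chr1", 0, 1), "DMS", "up", effect=-12.0)
        MarkSite(GenomicInterval("chr1", 0, 1), "DMS", "down", effect=-12.0)

    def test_table_roundtrip(self, tmp_path):
        sites = [
            MarkSite(GenomicInterval("chr1", 5, 6), "DMS", "up", 15.0, 0.01),
            MarkSite(GenomicInterval("chr2", 100, 2_100), "DMS", "down", -22.5, 0.04),
        ]
        path = tmp_path / "dms.bed"
        write_mark_table(path, sites)
        back = read_mark_table(path, "DMS")
        assert [(s.interval, s.direction, s.effect, s.significance) for s in back] == \
               [(s.interval, s.direction, s.effect, s.significance) for s in sites]


@pytest.fixture
def annotation_setup():
    genes = GeneSet([
        Gene("g1", GenomicInterval("chr1", 100_000, 150_000), "+"),
        Gene("g2", GenomicInterval("chr1", 900_000, 950_000), "+"),
    ])
    promoters = make_promoters(genes, 2_000, 500)
    exons = [GenomicInterval("chr1", 100_000, 110_000),
             GenomicInterval("chr1", 140_000, 150_000),
             GenomicInterval("chr1", 900_000, 950_000)]
    return genes, promoters, exons


class TestClassifyAnnotation:
    def test_promoter_beats_exon(self, annotation_setup):
        genes, promoters, exons = annotation_setup
        # site inside both the promoter window and the first exon
        br = classify_annotation([_site("chr1", 100_100, 100_200)], genes, promoters, exons)
        assert br.counts["promoter"] == 1

    def test_exon_intron_intergenic_desert(self, annotation_setup):
        genes, promoters, exons = annotation_setup
        sites = [
            _site("chr1", 105_000, 105_100),   # exon
            _site("chr1", 120_000, 120_100),   # gene body, not exon -> intron
            _site("chr1", 200_000, 200_100),   # 50 kb from g1 -> intergenic
            _site("chr1", 500_000, 500_100),   # 350 kb from both -> desert
        ]
        br = classify_annotation(sites, genes, promoters, exons, desert_min_gap=100_000)
        assert br.categories == {0: "exon", 1: "intron", 2: "intergenic", 3: "gene_desert"}

    def test_partition_sums_to_one(self, annotation_setup, rng):
        genes, promoters, exons = annotation_setup
        sites = [_site("chr1", int(s), int(s) + 50)
                 for s in rng.integers(0, 1_000_000, 200)]
        br = classify_annotation(sites, genes, promoters, exons)
        assert br.n_sites == 200
        assert sum(br.fractions.values()) == pytest.approx(1.0)

    def test_whole_gene_is_exon_without_exon_model(self, annotation_setup):
        genes, promoters, _ = annotation_setup
        br = classify_annotation([_site("chr1", 120_000, 120_100)], genes, promoters)
        assert br.counts["exon"] == 1


class TestMarkTargetAssociation:
    def test_marks_on_targets_give_zero_distance(self, rng):
        targets = [GenomicInterval("chr1", s, s + 20_000)
                   for s in range(1_000_000, 2_000_000, 100_000)]
        decoys = [GenomicInterval("chr1", s, s + 20_000)
                  for s in range(5_000_000, 9_000_000, 50_000)]
        universe = targets + decoys
        marks = [_site("chr1", t.start + 500, t.start + 600, "down", "H3K9me3_locus")
                 for t in targets]
        res = mark_target_association(marks, targets, universe, n_perm=300, seed=4)
        assert res["mean_distance"].observed == 0.0
        assert res["mean_distance"].p_less < 0.05
        assert res["num_overlaps"].observed == len(targets)
        assert res["num_overlaps"].p_greater < 0.05

    def test_empty_inputs_are_errors(self):
        iv = [GenomicInterval("chr1", 0, 100)]
        with pytest.raises(ValueError):
            mark_target_association([], iv, iv)
        with pytest.raises(ValueError):
            mark_target_association([_site("chr1", 0, 1)], [], iv)

    def test_null_pvalues_roughly_uniform(self, rng):
        """Marks placed independently of targets: ~5% rejections at alpha=.05."""
        rejections = 0
        n_rep = 100
        for rep in range(n_rep):
            universe = [GenomicInterval("chr1", int(s), int(s) + 1_000)
                        for s in rng.integers(0, 9_990_000, 200)]
            idx = rng.choice(200, 25, replace=False)
            targets = [universe[i] for i in idx]
            marks = [_site("chr1", int(s), int(s) + 500)
                     for s in rng.integers(0, 9_990_000, 60)]
            res = mark_target_association(marks, targets, universe,
                                          n_perm=200, seed=rep)
            rejections += res["mean_distance"].p_less < 0.05
        assert 0.005 <= rejections / n_rep <= 0.12


class TestDegMarkOverlap:
    def test_identical_and_disjoint(self):
        uni = [f"g{i}" for i in range(100)]
        ov, fisher = deg_mark_overlap(uni[:10], uni[:10], uni)
        assert len(ov) == 10 and fisher.p_value < 1e-6
        ov2, _ = deg_mark_overlap(uni[:10], uni[50:60], uni)
        assert ov2 == []

    def test_overlap_matches_set_oracle(self, rng):
        uni = [f"g{i}" for i in range(500)]
        A = list(rng.choice(uni, 80, replace=False))
        B = list(rng.choice(uni, 120, replace=False))
        ov, fisher = deg_mark_overlap(A, B, uni)
        assert set(ov) == set(A) & set(B)
        # Fisher p equals the hypergeometric tail
        from scipy.stats import hypergeom
        expect = hypergeom.sf(len(ov) - 1, 500, len(B), len(A))
        assert fisher.p_value == pytest.approx(expect, rel=1e-9)


def constant_signal(chrom="chr1", length=1_000_000, value=1.0):
    return {chrom: (np.array([0]), np.array([length]), np.array([value]))}


class TestSignalProfile:
    def test_constant_signal_gives_constant_matrix(self):
        regions = [GenomicInterval("chr1", 50_000, 57_000),
                   GenomicInterval("chr1", 200_000, 204_321)]
        pm = signal_profile_matrix(constant_signal(), regions,
                                   body=5_000, flank=3_000, bin_size=50)
        assert pm.matrix.shape == (2, 5_000 // 50 + 2 * (3_000 // 50))
        assert np.allclose(pm.matrix, 1.0)

    def test_zero_signal_skip_zeros_drops_all(self):
        regions = [GenomicInterval("chr1", 50_000, 57_000)]
        sig = {"chr1": (np.array([0]), np.array([1_000]), np.array([0.0]))}
        with pytest.warns(UserWarning, match="zero"):
            pm = signal_profile_matrix(sig, regions)
        assert pm.matrix.shape[0] == 0

    def test_minus_strand_reverses_columns(self):
        sig = {"chr1": (np.array([0, 50_000]), np.array([50_000, 100_000]),
                        np.array([1.0, 2.0]))}
        region = [GenomicInterval("chr1", 45_000, 55_000)]
        fwd = signal_profile_matrix(sig, region, strands=["+"], skip_zeros=False)
        rev = signal_profile_matrix(sig, region, strands=["-"], skip_zeros=False)
        assert np.allclose(rev.matrix[0], fwd.matrix[0][::-1])

    def test_step_breakpoint_bins_match_integration_oracle(self):
        # step from 2.0 to 5.0 at 50,010: bin [50_000, 50_050) mixes 10 bp
        # of 2.0 with 40 bp of 5.0
        sig = {"chr1": (np.array([0, 50_010]), np.array([50_010, 100_000]),
                        np.array([2.0, 5.0]))}
        region = [GenomicInterval("chr1", 50_000, 55_000)]
        pm = signal_profile_matrix(sig, region, body=5_000, flank=3_000, bin_size=50,
                                   skip_zeros=False)
        body = pm.matrix[0][pm.n_flank_bins:pm.n_flank_bins + pm.n_body_bins]
        assert body[0] == pytest.approx((10 * 2.0 + 40 * 5.0) / 50)
        assert np.allclose(body[1:], 5.0)

    def test_short_region_warns_but_integrates(self):
        region = [GenomicInterval("chr1", 10_000, 10_030)]  # 30 bp < one 50-bp bin
        with pytest.warns(UserWarning, match="shorter"):
            pm = signal_profile_matrix(constant_signal(), region, skip_zeros=False)
        assert np.allclose(pm.matrix, 1.0)
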