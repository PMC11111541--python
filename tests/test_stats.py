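"""Resampling and classical statistics against independent oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from chromlink.genome import GenomeLayout, GenomicInterval
from chromlink.stats import (
    PermutationResult,
    child_seed,
    dunn_test,
    fisher_overlap_test,
    geneset_top_overlap_test,
    ks_two_sample,
    region_permutation_test,
)

from conftest import random_intervals


def test_child_seed_is_stable_and_distinct():
    assert child_seed(1, "a") == child_seed(1, "a")
    assert child_seed(1, "a") != child_seed(1, "b")
    assert child_seed(1, "a") != child_seed(2, "a")
    assert 0 <= child_seed(123456, "x") < 2 ** 31


class TestPermutationResult:
    def test_pseudocount_keeps_p_positive(self):
        r = PermutationResult.from_null(10.0, np.zeros(99), seed=0)
        assert r.p_greater == pytest.approx(1 / 100)
        assert r.p_less == 1.0

    def test_degenerate_null_equal_observed(self):
        r = PermutationResult.from_null(5.0, np.full(50, 5.0), seed=0)
        assert r.p_greater == 1.0 and r.p_less == 1.0 and r.z == 0.0


class TestGenesetOverlap:
    def test_candidate_equals_top_is_maximally_enriched(self):
        universe = [f"g{i}" for i in range(50)]
        top = universe[:5]
        r = geneset_top_overlap_test(top, universe, top, n_perm=200, seed=0)
        assert r.observed == 5
        assert r.p_greater >= 1 / 201  # only the all-top draw matches

    def test_disjoint_candidate_depleted(self):
        universe = [f"g{i}" for i in range(100)]
        top = universe[:50]
        candidate = universe[50:90]  # zero overlap where ~20 expected
        r = geneset_top_overlap_test(candidate, universe, top, n_perm=500, seed=0)
        assert r.observed == 0
        assert r.p_less < 0.01

    def test_candidate_outside_background_is_error(self):
        with pytest.raises(ValueError):
            geneset_top_overlap_test(["x"], ["a", "b"], ["a"], n_perm=100, seed=0)

    def test_null_mean_matches_hypergeometric(self):
        rng = np.random.default_rng(7)
        universe = [f"g{i}" for i in range(300)]
        top = list(rng.choice(universe, 30, replace=False))
        candidate = list(rng.choice(universe, 40, replace=False))
        r = geneset_top_overlap_test(candidate, universe, top, n_perm=5_000, seed=11)
        expected_mean = 40 * 30 / 300
        sd = math.sqrt(sps.hypergeom(300, 30, 40).var())
        assert abs(np.mean(r.null_sample) - expected_mean) < 3 * sd / math.sqrt(5_000)

    def test_reproducible_given_seed(self):
        universe = [f"g{i}" for i in range(100)]
        a = geneset_top_overlap_test(universe[:10], universe, universe[20:40],
                                     n_perm=300, seed=9)
        b = geneset_top_overlap_test(universe[:10], universe, universe[20:40],
                                     n_perm=300, seed=9)
        assert np.array_equal(a.null_sample, b.null_sample)


class TestRegionPermutation:
    def test_query_inside_reference_distance_zero(self):
        ref = [GenomicInterval("chr1", 0, 1_000_000)]
        query = [GenomicInterval("chr1", 100, 200)]
        universe = query + [GenomicInterval("chr1", 2_000_000 + i * 10_000,
                                            2_000_000 + i * 10_000 + 100)
                            for i in range(20)]
        r = region_permutation_test(query, ref, stat="mean_distance",
                                    universe=universe, n_perm=200, seed=0)
        assert r.observed == 0.0
        assert r.p_less < 0.05

    def test_reference_covering_genome_gives_degenerate_overlap_null(self):
        ref = [GenomicInterval("chr1", 0, 10_000_000)]
        universe = [GenomicInterval("chr1", i * 1_000, i * 1_000 + 500) for i in range(100)]
        query = universe[:10]
        r = region_permutation_test(query, ref, stat="num_overlaps",
                                    universe=universe, n_perm=100, seed=0)
        assert r.observed == 10
        assert r.p_greater == 1.0 and r.p_less == 1.0

    def test_universe_smaller_than_query_is_error(self):
        q = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)]
        with pytest.raises(ValueError):
            region_permutation_test(q, q, universe=q[:1], n_perm=100, seed=0)

    def test_null_matches_exhaustive_enumeration_small_case(self):
        """Fast resampling path agrees with brute-force subset enumeration."""
        rng = np.random.default_rng(3)
        universe = random_intervals(rng, 8, chroms=("chr1",), span=100_000, max_len=500)
        reference = random_intervals(rng, 4, chroms=("chr1",), span=100_000, max_len=500)
        query = universe[:3]
        r = region_permutation_test(query, reference, stat="mean_distance",
                                    universe=universe, n_perm=4_000, seed=5)
        # exhaustive null over all C(8,3) subsets
        from chromlink.genome import nearest_distance
        per_region = nearest_distance(universe, reference)
        exact = [np.mean(per_region[list(c)]) for c in itertools.combinations(range(8), 3)]
        # empirical null mean within 3 MC SE of the exact enumeration mean
        se = np.std(exact) / math.sqrt(4_000)
        assert abs(np.mean(r.null_sample) - np.mean(exact)) < 3 * se
        assert set(np.round(np.unique(r.null_sample), 9)) <= \
            set(np.round(np.unique(exact), 9))

    def test_random_placement_scheme_runs_and_preserves_widths(self):
        genome = GenomeLayout({"chr1": 1_000_000}, 20_000)
        rng = np.random.default_rng(0)
        query = random_intervals(rng, 10, chroms=("chr1",), span=900_000, max_len=2_000)
        ref = random_intervals(rng, 10, chroms=("chr1",), span=900_000, max_len=2_000)
        r = region_permutation_test(query, ref, stat="num_overlaps",
                                    scheme="random_placement", genome=genome,
                                    n_perm=150, seed=2)
        assert r.n_perm == 150
        assert np.all(r.null_sample >= 0) and np.all(r.null_sample <= 10)


class TestFisher:
    def test_disjoint_small_sets_not_enriched(self):
        r = fisher_overlap_test([f"a{i}" for i in range(5)],
                                [f"b{i}" for i in range(5)], 10_000)
        assert r.p_value > 0.99

    def test_complete_overlap_degenerate(self):
        u = [f"g{i}" for i in range(20)]
        r = fisher_overlap_test(u, u, 20)
        assert r.p_value == pytest.approx(1.0)

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            fisher_overlap_test([f"g{i}" for i in range(30)], [], 10)

    def test_symmetric_in_sets(self):
        rng = np.random.default_rng(1)
        uni = [f"g{i}" for i in range(200)]
        A = list(rng.choice(uni, 40, replace=False))
        B = list(rng.choice(uni, 60, replace=False))
        assert fisher_overlap_test(A, B, 200).p_value == \
            pytest.approx(fisher_overlap_test(B, A, 200).p_value, rel=1e-12)


def oracle_dunn_z(groups):
    """Brute-force Dunn z-scores with explicit midranks and tie correction."""
    names = list(groups)
    pooled = [(v, k) for k in names for v in groups[k]]
    values = sorted(v for v, _ in pooled)
    # midrank of a value = mean of the 1-based positions of its duplicates
    midrank = {}
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and values[j] == values[i]:
            j += 1
        midrank[values[i]] = (i + 1 + j) / 2
        i = j
    N = len(values)
    mean_rank = {k: sum(midrank[v] for v in groups[k]) / len(groups[k]) for k in names}
    ties = {}
    for v in values:
        ties[v] = ties.get(v, 0) + 1
    T = sum(t ** 3 - t for t in ties.values()) / (12 * (N - 1))
    out = {}
    for k1, k2 in itertools.combinations(names, 2):
        se = math.sqrt((N * (N + 1) / 12 - T) * (1 / len(groups[k1]) + 1 / len(groups[k2])))
        out[(k1, k2)] = (mean_rank[k1] - mean_rank[k2]) / se
    return out


class TestDunn:
    def test_identical_groups_give_z_zero(self):
        df = dunn_test({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert df["z"].iloc[0] == pytest.approx(0.0)
        assert df["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_simple_separation_matches_oracle(self):
        groups = {"lo": [1, 2, 3], "hi": [4, 5, 6]}
        df = dunn_test(groups, p_adjust="none")
        z = oracle_dunn_z(groups)[("lo", "hi")]
        assert df["z"].iloc[0] == pytest.approx(z, abs=1e-12)

    def test_shift_invariance(self):
        g1 = {"a": [1.0, 2.0, 5.0], "b": [2.0, 2.0, 7.0], "c": [0.5, 9.0]}
        g2 = {k: [v + 123.25 for v in vals] for k, vals in g1.items()}
        assert np.allclose(dunn_test(g1)["z"], dunn_test(g2)["z"])

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            dunn_test({"a": [1.0], "b": []})

    def test_bonferroni_adjustment(self):
        df = dunn_test({"a": [1, 2], "b": [10, 11], "c": [20, 21]})
        assert np.all(df["p_adjusted"] >= df["p_raw"])
        assert np.all(df["p_adjusted"] <= 1.0)


class TestKS:
    def test_identical_samples(self):
        D, _ = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert D == 0.0

    def test_disjoint_supports(self):
        D, p = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert D == 1.0

    def test_statistic_matches_breakpoint_enumeration(self, rng):
        x = rng.normal(0, 1, 80)
        y = rng.normal(0.5, 1.3, 60)
        D, _ = ks_two_sample(x, y)
        xs = np.sort(x)
        ys = np.sort(y)
        brute = max(
            abs(np.searchsorted(xs, t, side="right") / len(xs)
                - np.searchsorted(ys, t, side="right") / len(ys))
            for t in np.concatenate([xs, ys])
        )
        assert D == pytest.approx(brute, abs=1e-12)
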