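"""Resampling and classical statistics for the integrative analysis.

Implements the gene-set resampling enrichment used to test DEG
over-representation among high-interaction genes, regioneR-style genomic
region permutation tests (meanDistance / numOverlaps), Fisher's exact
overlap enrichment, Dunn's post-hoc rank test, and the two-sample
Kolmogorov-Smirnov test.

Empirical p-values use the +1 pseudo-count convention
p = (1 + #{null as-or-more extreme}) / (1 + n_perm), so p is never 0 and
both tails are always reported.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import GenomeLayout, GenomicInterval, build_trees, nearest_distance

REGION_STATS = ("mean_distance", "num_overlaps")
REGION_SCHEMES = ("resample_universe", "random_placement")


def child_seed(seed: int, name: str) -> int:
    """Derive a stable per-test seed (< 2**31) from a study seed and a label."""
    return int(np.random.SeedSequence(
        entropy=[int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]
    ).generate_state(1)[0] % (2 ** 31))


@dataclass
class PermutationResult:
    """Observed statistic with its permutation null.

    p_greater / p_less are +1-pseudo-count empirical tail probabilities;
    z is (observed - mean(null)) / sd(null).
    """

    observed: float
    null_sample: np.ndarray
    p_greater: float
    p_less: float
    z: float
    n_perm: int
    seed: int

    @classmethod
    def from_null(cls, observed: float, null: np.ndarray, seed: int) -> "PermutationResult":
        null = np.asarray(null, dtype=float)
        n = null.size
        p_greater = (1 + int(np.sum(null >= observed))) / (1 + n)
        p_less = (1 + int(np.sum(null <= observed))) / (1 + n)
        sd = float(np.std(null, ddof=1)) if n > 1 else 0.0
        mean = float(np.mean(null))
        if sd > 0:
            z = (observed - mean) / sd
        else:
            z = 0.0 if observed == mean else float(np.sign(observed - mean)) * np.inf
        return cls(float(observed), null, p_greater, p_less, float(z), n, int(seed))

    def to_dict(self, include_null: bool = False) -> dict:
        d = {
            "observed": self.observed,
            "null_mean": float(np.mean(self.null_sample)),
            "null_sd": float(np.std(self.null_sample, ddof=1)) if self.n_perm > 1 else 0.0,
            "z": self.z,
            "p_greater": self.p_greater,
            "p_less": self.p_less,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }
        if include_null:
            d["null_sample"] = self.null_sample.tolist()
        return d


# ---------------------------------------------------------------------------
# Gene-set resampling enrichment
# ---------------------------------------------------------------------------

def geneset_top_overlap_test(
    candidate_set: Sequence[str],
    background: Sequence[str],
    top_set: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Is a candidate gene set over/under-represented in the top-ranked set?

    Observed statistic: |candidate ∩ top|.  Each permutation draws
    |candidate| genes from the background universe without replacement
    and records the overlap with the top set.
    """
    bg = list(dict.fromkeys(background))
    cand = set(candidate_set)
    top = set(top_set)
    if not cand <= set(bg):
        raise ValueError("candidate_set must be a subset of background")
    if not top <= set(bg):
        raise ValueError("top_set must be a subset of background")
    k = len(cand)
    if k > len(bg):
        raise ValueError("candidate set larger than background")
    observed = len(cand & top)
    rng = np.random.default_rng(seed)
    top_mask = np.fromiter((g in top for g in bg), dtype=bool, count=len(bg))
    null = np.empty(n_perm, dtype=np.int64)
    n = len(bg)
    chunk = max(1, min(n_perm, 4_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # without-replacement draws: k smallest of iid uniforms per row
        u = rng.random((m, n))
        idx = np.argpartition(u, k - 1, axis=1)[:, :k]
        null[done:done + m] = top_mask[idx].sum(axis=1)
        done += m
    return PermutationResult.from_null(observed, null, seed)


# ---------------------------------------------------------------------------
# Region permutation tests (regioneR-style)
# ---------------------------------------------------------------------------

def _region_stat_values(regions: Sequence[GenomicInterval],
                        reference: Sequence[GenomicInterval],
                        stat: str) -> np.ndarray:
    """Per-region contribution to the statistic (decomposable stats)."""
    if stat == "mean_distance":
        return nearest_distance(regions, reference)
    if stat == "num_overlaps":
        trees = build_trees(reference)
        out = np.zeros(len(regions))
        for i, r in enumerate(regions):
            tree = trees.get(r.chrom)
            if tree is not None and tree.overlap(r.start, r.end):
                out[i] = 1.0
        return out
    raise ValueError(f"unknown region statistic {stat!r}; expected one of {REGION_STATS}")


def _aggregate(values: np.ndarray, stat: str) -> float:
    if stat == "mean_distance":
        return float(np.nanmean(values))
    return float(np.nansum(values))


def region_permutation_test(
    query: Sequence[GenomicInterval],
    reference: Sequence[GenomicInterval],
    stat: str = "mean_distance",
    scheme: str = "resample_universe",
    universe: Sequence[GenomicInterval] | None = None,
    genome: GenomeLayout | None = None,
    n_perm: int = 600,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of a query region set against a reference set.

    ``mean_distance`` is the mean distance from each query region to its
    nearest reference region; ``num_overlaps`` counts query regions
    overlapping at least one reference region.  Under
    ``resample_universe`` (default, mirroring a background of all genes)
    each permutation replaces the query by |query| regions drawn without
    replacement from the universe; ``random_placement`` re-places the
    query regions uniformly at random, width-preserved, within the
    genome's chromosomes.
    """
    if stat not in REGION_STATS:
        raise ValueError(f"unknown region statistic {stat!r}")
    if scheme not in REGION_SCHEMES:
        raise ValueError(f"unknown randomization scheme {scheme!r}")
    if len(query) == 0:
        raise ValueError("empty query region set")
    observed = _aggregate(_region_stat_values(query, reference, stat), stat)
    rng = np.random.default_rng(seed)
    k = len(query)

    if scheme == "resample_universe":
        if universe is None or len(universe) < k:
            raise ValueError("resample_universe needs a universe with >= |query| regions")
        per_region = _region_stat_values(universe, reference, stat)
        m = len(universe)
        null = np.empty(n_perm)
        chunk = max(1, min(n_perm, 4_000_000 // m))
        done = 0
        while done < n_perm:
            c = min(chunk, n_perm - done)
            u = rng.random((c, m))
            idx = np.argpartition(u, k - 1, axis=1)[:, :k]
            sampled = per_region[idx]
            if stat == "mean_distance":
                null[done:done + c] = np.nanmean(sampled, axis=1)
            else:
                null[done:done + c] = np.nansum(sampled, axis=1)
            done += c
    else:
        if genome is None:
            raise ValueError("random_placement needs a GenomeLayout")
        chroms = list(genome.chrom_lengths)
        lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
        probs = lengths / lengths.sum()
        widths = [r.length for r in query]
        null = np.empty(n_perm)
        for i in range(n_perm):
            placed = []
            ci = rng.choice(len(chroms), size=k, p=probs)
            for w, c in zip(widths, ci):
                limit = int(lengths[c]) - w
                s = int(rng.integers(0, max(limit, 0) + 1))
                placed.append(GenomicInterval(chroms[c], s, s + w))
            null[i] = _aggregate(_region_stat_values(placed, reference, stat), stat)
    return PermutationResult.from_null(observed, null, seed)


# ---------------------------------------------------------------------------
# Fisher overlap enrichment
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]

    @property
    def neglog10_p(self) -> float:
        return float(-np.log10(max(self.p_value, 1e-300)))


def fisher_overlap_test(setA: Sequence, setB: Sequence, universe_size: int) -> FisherResult:
    """One-sided (enrichment) Fisher exact test of two gene sets' overlap.

    The 2x2 table is (overlap, A-only, B-only, neither) over a universe
    of ``universe_size`` genes.
    """
    A, B = set(setA), set(setB)
    overlap = len(A & B)
    a_only = len(A) - overlap
    b_only = len(B) - overlap
    neither = universe_size - overlap - a_only - b_only
    if len(A) > universe_size or len(B) > universe_size or neither < 0:
        raise ValueError("set sizes inconsistent with universe_size")
    table = ((overlap, a_only), (b_only, neither))
    odds, p = sps.fisher_exact(table, alternative="greater")
    return FisherResult(float(odds), float(p), table)


# ---------------------------------------------------------------------------
# Dunn's test
# ---------------------------------------------------------------------------

def dunn_test(groups: Mapping[str, Sequence[float]], p_adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's (1964) post-hoc pairwise rank test with midranks and tie correction.

    For groups i, j:
    z_ij = (meanRank_i - meanRank_j) /
           sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),
    with tie correction T = sum(t^3 - t) / (12 (N - 1)) over tie groups.
    Two-sided normal p-values; Bonferroni adjustment by default.
    """
    if len(groups) < 2:
        raise ValueError("dunn_test needs at least two groups")
    names = list(groups)
    samples = {k: np.asarray(list(v), dtype=float) for k, v in groups.items()}
    for k, v in samples.items():
        if v.size == 0:
            raise ValueError(f"group {k!r} is empty")
    pooled = np.concatenate([samples[k] for k in names])
    ranks = sps.rankdata(pooled)  # midranks
    N = pooled.size
    mean_ranks = {}
    pos = 0
    for k in names:
        n = samples[k].size
        mean_ranks[k] = float(np.mean(ranks[pos:pos + n]))
        pos += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    T = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - T
    rows = []
    pairs = list(itertools.combinations(names, 2))
    for g1, g2 in pairs:
        n1, n2 = samples[g1].size, samples[g2].size
        se = np.sqrt(var_base * (1.0 / n1 + 1.0 / n2))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append((g1, g2, z, p))
    df = pd.DataFrame(rows, columns=["group1", "group2", "z", "p_raw"])
    if p_adjust == "bonferroni":
        df["p_adjusted"] = np.minimum(1.0, df["p_raw"] * len(pairs))
    elif p_adjust == "none":
        df["p_adjusted"] = df["p_raw"]
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    return df


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: (D, asymptotic p)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)
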