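"""Integration of differential methylation and histone-mark sites with genes
and chromatin-interaction anchors.

Covers genome annotation of differential sites (promoter / exon / intron /
intergenic / gene desert), permutation association between mark sites and
the anchors interacting with a gene set's promoters, and deeptools-style
scale-regions signal profile matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    Gene,
    GeneSet,
    GenomicInterval,
    ParseError,
    _data_lines,
    build_trees,
    nearest_distance,
    normalize_chrom,
)
from .interactions import GeneInteractionProfile
from .stats import PermutationResult, child_seed, region_permutation_test

MARK_KINDS = ("DMS", "H3K27me3_peak", "H3K9me3_locus")
ANNOTATION_CATEGORIES = ("promoter", "exon", "intron", "intergenic", "gene_desert")


@dataclass(frozen=True)
class MarkSite:
    """One differential site: a DMS, H3K27me3 peak, or H3K9me3 locus.

    ``direction`` is 'up' (hyper / increased) or 'down' (hypo / decreased)
    and must agree with the sign of ``effect`` when one is given.
    """

    interval: GenomicInterval
    kind: str
    direction: str
    effect: float | None = None
    significance: float | None = None

    def __post_init__(self):
        if self.kind not in MARK_KINDS:
            raise ValueError(f"unknown mark kind {self.kind!r}")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if self.effect is not None and self.effect != 0:
            if (self.effect > 0) != (self.direction == "up"):
                raise ValueError(
                    f"direction {self.direction!r} inconsistent with effect {self.effect}"
                )


def read_mark_table(path, kind: str, chrom_style: str | None = None) -> list[MarkSite]:
    """Read a BED-like differential-site table.

    Expected columns: chrom, start, end, direction, effect, q (a header
    line naming them is honoured; extra columns ignored).
    """
    sites: list[MarkSite] = []
    seen_header = False
    cols = {"chrom": 0, "start": 1, "end": 2, "direction": 3, "effect": 4, "q": 5}
    for lineno, fields in _data_lines(path):
        if not seen_header:
            seen_header = True
            if "direction" in fields:
                cols = {name: fields.index(name) for name in cols if name in fields}
                continue
        try:
            iv = GenomicInterval(
                normalize_chrom(fields[cols["chrom"]], chrom_style),
                int(fields[cols["start"]]),
                int(fields[cols["end"]]),
            )
            direction = fields[cols["direction"]]
            effect = float(fields[cols["effect"]]) if "effect" in cols and len(fields) > cols["effect"] else None
            q = float(fields[cols["q"]]) if "q" in cols and len(fields) > cols["q"] else None
            sites.append(MarkSite(iv, kind, direction, effect, q))
        except ParseError:
            raise
        except (ValueError, IndexError) as exc:
            raise ParseError(path, lineno, str(exc))
    return sites


def write_mark_table(path, sites: Sequence[MarkSite], header_comments: Sequence[str] = ()) -> None:
    with open(path, "wt") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        fh.write("chrom\tstart\tend\tdirection\teffect\tq\n")
        for s in sites:
            fh.write("\t".join([
                s.interval.chrom, str(s.interval.start), str(s.interval.end),
                s.direction,
                "" if s.effect is None else repr(s.effect),
                "" if s.significance is None else repr(s.significance),
            ]) + "\n")


# ---------------------------------------------------------------------------
# Genome annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationBreakdown:
    """Counts and fractions of sites per genomic category (a partition)."""

    counts: dict[str, int]
    categories: dict[int, str]  # site index -> category

    @property
    def n_sites(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        n = self.n_sites
        return {k: (v / n if n else 0.0) for k, v in self.counts.items()}


def classify_annotation(
    sites: Sequence[MarkSite] | Sequence[GenomicInterval],
    genes: GeneSet,
    promoters: Sequence[GenomicInterval],
    exons: Sequence[GenomicInterval] | None = None,
    desert_min_gap: int = 100_000,
) -> AnnotationBreakdown:
    """Assign each site to exactly one category by priority.

    promoter > exon > intron > intergenic; intergenic sites at least
    ``desert_min_gap`` bp from any gene are labeled gene_desert.  When no
    exon model is supplied the whole gene body counts as exonic.
    """
    if desert_min_gap <= 0:
        raise ValueError("desert_min_gap must be positive")
    intervals = [s.interval if isinstance(s, MarkSite) else s for s in sites]
    gene_ivs = genes.intervals()
    exon_ivs = list(exons) if exons is not None else gene_ivs
    prom_trees = build_trees(promoters)
    exon_trees = build_trees(exon_ivs)
    gene_trees = build_trees(gene_ivs)
    gene_dist = nearest_distance(intervals, gene_ivs) if intervals and gene_ivs else np.array([])

    def hits(trees, iv):
        tree = trees.get(iv.chrom)
        return tree is not None and bool(tree.overlap(iv.start, iv.end))

    counts = {c: 0 for c in ANNOTATION_CATEGORIES}
    categories: dict[int, str] = {}
    for i, iv in enumerate(intervals):
        if hits(prom_trees, iv):
            cat = "promoter"
        elif hits(exon_trees, iv):
            cat = "exon"
        elif hits(gene_trees, iv):
            cat = "intron"
        else:
            d = gene_dist[i]
            cat = "gene_desert" if (np.isnan(d) or d >= desert_min_gap) else "intergenic"
        counts[cat] += 1
        categories[i] = cat
    return AnnotationBreakdown(counts, categories)


# ---------------------------------------------------------------------------
# Mark <-> anchor association
# ---------------------------------------------------------------------------

def promoter_anchors(
    gene_ids: Iterable[str],
    profiles: Mapping[str, GeneInteractionProfile],
    promoters_by_gene: Mapping[str, GenomicInterval],
) -> list[GenomicInterval]:
    """Anchors interacting with the promoters of a gene set.

    Partner bins of contacts whose gene-side anchor overlaps the gene's
    promoter window; deduplicated by coordinate and sorted.
    """
    seen: set[tuple[str, int, int]] = set()
    for gid in gene_ids:
        prof = profiles.get(gid)
        prom = promoters_by_gene.get(gid)
        if prof is None or prom is None:
            continue
        for contact, partners in zip(prof.contacts, prof.partners):
            gene_side = [a for a in (contact.anchor1, contact.anchor2) if a not in partners]
            anchors = gene_side if gene_side else [contact.anchor1, contact.anchor2]
            if any(a.overlaps(prom) for a in anchors):
                for p in partners:
                    seen.add((p.chrom, p.start, p.end))
    return [GenomicInterval(c, s, e) for c, s, e in sorted(seen)]


def mark_target_association(
    marks: Sequence[MarkSite],
    targets: Sequence[GenomicInterval],
    universe: Sequence[GenomicInterval],
    n_perm: int = 600,
    seed: int = 0,
    label: str = "mark_target",
) -> dict[str, PermutationResult]:
    """Permutation association between mark sites and target anchor regions.

    Runs the region permutation test for both meanDistance and
    numOverlaps with query = targets, reference = mark intervals and the
    universe of all-gene promoter anchors as background.
    """
    if len(targets) == 0:
        raise ValueError("empty target region set")
    if len(marks) == 0:
        raise ValueError("empty mark set")
    reference = [m.interval for m in marks]
    out = {}
    for stat in ("mean_distance", "num_overlaps"):
        out[stat] = region_permutation_test(
            targets, reference, stat=stat, scheme="resample_universe",
            universe=universe, n_perm=n_perm,
            seed=child_seed(seed, f"{label}:{stat}"),
        )
    return out


def deg_mark_overlap(
    deg_genes: Iterable[str],
    mark_genes: Iterable[str],
    universe: Sequence[str],
):
    """Overlap between a DEG set and mark-associated genes, with Fisher enrichment."""
    from .stats import fisher_overlap_test

    deg = set(deg_genes)
    mark = set(mark_genes)
    uni = set(universe)
    if not deg <= uni or not mark <= uni:
        raise ValueError("gene sets must be drawn from the universe")
    overlap = sorted(deg & mark)
    fisher = fisher_overlap_test(deg, mark, len(uni))
    return overlap, fisher


# ---------------------------------------------------------------------------
# Signal profile matrix (scale-regions)
# ---------------------------------------------------------------------------

Signal = Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]


def _step_integral(signal: Signal, chrom: str, xs: np.ndarray) -> np.ndarray:
    """Integral of the step signal from 0 to each x (x may be fractional)."""
    if chrom not in signal:
        return np.zeros_like(xs, dtype=float)
    starts, ends, values = signal[chrom]
    mass = (ends - starts) * values
    cumprev = np.concatenate([[0.0], np.cumsum(mass)])
    xs = np.clip(xs, 0, None)
    idx = np.searchsorted(starts, xs, side="right") - 1
    out = np.where(idx >= 0, cumprev[np.clip(idx, 0, None)], 0.0)
    valid = idx >= 0
    if np.any(valid):
        iv = idx[valid]
        inside = np.clip(np.minimum(xs[valid], ends[iv]) - starts[iv], 0, None)
        out[valid] = cumprev[iv] + values[iv] * inside
    return out


@dataclass
class ProfileMatrix:
    """Binned signal over scaled region bodies with fixed flanks.

    Columns: upstream flank bins, body bins (each region's body rescaled
    to the same number of bins), downstream flank bins.  ``kept`` maps
    matrix rows back to input region indices (all-zero rows may be
    dropped).
    """

    matrix: np.ndarray
    kept: np.ndarray
    n_flank_bins: int
    n_body_bins: int
    bin_size: int

    @property
    def mean_profile(self) -> np.ndarray:
        if self.matrix.shape[0] == 0:
            return np.zeros(self.matrix.shape[1])
        return self.matrix.mean(axis=0)


def signal_profile_matrix(
    signal: Signal,
    regions: Sequence[GenomicInterval],
    strands: Sequence[str] | None = None,
    body: int = 5_000,
    flank: int = 3_000,
    bin_size: int = 50,
    skip_zeros: bool = True,
) -> ProfileMatrix:
    """Scale-regions signal matrix (deeptools computeMatrix semantics).

    Each region body is rescaled to ``body / bin_size`` bins; flanks of
    ``flank`` bp are appended unscaled on both sides.  Bin values are
    coverage-weighted means of the step signal (exact integrals, so a
    row's mass reproduces the signal integral over the region).  Regions
    on the '-' strand are reversed.  All-zero rows are dropped when
    ``skip_zeros`` is set.
    """
    if len(regions) == 0:
        raise ValueError("no regions supplied")
    if body % bin_size or flank % bin_size:
        raise ValueError("body and flank must be multiples of bin_size")
    nb = body // bin_size
    nf = flank // bin_size
    ncol = nb + 2 * nf
    rows = np.zeros((len(regions), ncol))
    for i, r in enumerate(regions):
        if r.length < bin_size:
            warnings.warn(
                f"region {r.chrom}:{r.start}-{r.end} shorter than one bin; "
                "body bins interpolate sub-bin coverage"
            )
        up_edges = np.linspace(r.start - flank, r.start, nf + 1)
        body_edges = np.linspace(r.start, r.end, nb + 1)
        down_edges = np.linspace(r.end, r.end + flank, nf + 1)
        edges = np.concatenate([up_edges, body_edges[1:], down_edges[1:]])
        integral = _step_integral(signal, r.chrom, edges)
        widths = np.diff(edges)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(widths > 0, np.diff(integral) / widths, 0.0)
        strand = strands[i] if strands is not None else "+"
        rows[i] = means[::-1] if strand == "-" else means
    if skip_zeros:
        kept = np.where(rows.any(axis=1))[0]
        if kept.size == 0:
            warnings.warn("all rows are zero; empty profile matrix")
    else:
        kept = np.arange(len(regions))
    return ProfileMatrix(rows[kept], kept, nf, nb, bin_size)


def profile_matrix_frame(pm: ProfileMatrix, region_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Profile matrix as a DataFrame with labeled flank/body columns."""
    cols = (
        [f"up_{i}" for i in range(pm.n_flank_bins)]
        + [f"body_{i}" for i in range(pm.n_body_bins)]
        + [f"down_{i}" for i in range(pm.n_flank_bins)]
    )
    idx = None
    if region_names is not None:
        idx = [region_names[i] for i in pm.kept]
    return pd.DataFrame(pm.matrix, columns=cols, index=idx)
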