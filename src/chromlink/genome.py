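"""Coordinate types and interval algebra for the chromatin-integration pipeline.

All coordinates are 0-based, half-open (BED convention).  Readers accept
1-based closed input only through an explicit ``one_based=True`` flag and
convert at the boundary.  Every reader is gzip-transparent.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree


class ParseError(ValueError):
    """Malformed line in a genomic text file; carries the line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def normalize_chrom(name: str, style: str | None = None) -> str:
    """Normalize chromosome-name dialects ('chr1' vs '1').

    style 'chr' forces the UCSC prefix, 'plain' strips it, None leaves
    the name untouched.
    """
    if style is None:
        return name
    bare = name[3:] if name.lower().startswith("chr") else name
    if style == "chr":
        return "chr" + bare
    if style == "plain":
        return bare
    raise ValueError(f"unknown chromosome-name style: {style!r}")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_overlap_bp: int = 1) -> bool:
        return self.overlap_length(other) >= min_overlap_bp

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset,
                               self.name, self.score)


@dataclass(frozen=True)
class Gene:
    """A gene model: an interval plus a strand-aware TSS."""

    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        """Transcription start site: start on '+', end-1 on '-'."""
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1


class GeneSet:
    """An ordered collection of genes with unique gene_ids."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: list[Gene] = list(genes)
        self.by_id: dict[str, Gene] = {}
        for g in self.genes:
            if g.gene_id in self.by_id:
                raise ValueError(f"duplicate gene_id: {g.gene_id}")
            self.by_id[g.gene_id] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.by_id

    def ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def intervals(self) -> list[GenomicInterval]:
        return [g.interval for g in self.genes]

    def subset(self, gene_ids: Iterable[str]) -> "GeneSet":
        wanted = set(gene_ids)
        missing = wanted - set(self.by_id)
        if missing:
            raise KeyError(f"unknown gene_ids: {sorted(missing)[:5]}")
        return GeneSet(g for g in self.genes if g.gene_id in wanted)


@dataclass(frozen=True)
class Contact:
    """One significant contact between two equal-width genomic bins.

    ``oe`` is the observed/expected intensity; ``distance`` is the
    separation of bin starts for intra-chromosomal contacts and None for
    trans contacts.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    qvalue: float
    oe: float

    def __post_init__(self):
        if not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(f"qvalue {self.qvalue} outside [0, 1]")
        if self.oe < 0:
            raise ValueError(f"negative O/E intensity: {self.oe}")

    @property
    def is_cis(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom

    @property
    def distance(self) -> int | None:
        if not self.is_cis:
            return None
        return abs(self.anchor1.start - self.anchor2.start)


@dataclass
class GenomeLayout:
    """Chromosome names/lengths and the contact-map bin size."""

    chrom_lengths: dict[str, int]
    bin_size: int = 20_000

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for c, n in self.chrom_lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {c} has non-positive length")

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def contains(self, iv: GenomicInterval) -> bool:
        n = self.chrom_lengths.get(iv.chrom)
        return n is not None and iv.end <= n

    def bin_of(self, chrom: str, pos: int) -> GenomicInterval:
        s = (pos // self.bin_size) * self.bin_size
        e = min(s + self.bin_size, self.chrom_lengths[chrom])
        return GenomicInterval(chrom, s, e)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path):
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track ", "browser ")):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def read_gene_table(path, one_based: bool = False, chrom_style: str | None = None) -> GeneSet:
    """Read a TSV gene table with columns chrom, start, end, strand, gene_id.

    A header line repeating those column names (in any order) is honoured;
    otherwise the fixed column order above is assumed.
    """
    required = ["chrom", "start", "end", "strand", "gene_id"]
    order = {name: i for i, name in enumerate(required)}
    genes: list[Gene] = []
    seen_header = False
    for lineno, fields in _data_lines(path):
        if not seen_header:
            seen_header = True
            if "gene_id" in fields:  # header line
                try:
                    order = {name: fields.index(name) for name in required}
                except ValueError as exc:
                    raise ParseError(path, lineno, f"incomplete header: {exc}")
                continue
        if max(order.values()) >= len(fields):
            raise ParseError(path, lineno, f"expected ≥{len(required)} columns, got {len(fields)}")
        try:
            chrom = normalize_chrom(fields[order["chrom"]], chrom_style)
            start = int(fields[order["start"]])
            end = int(fields[order["end"]])
            if one_based:
                start -= 1
            strand = fields[order["strand"]]
            gene_id = fields[order["gene_id"]]
            genes.append(Gene(gene_id, GenomicInterval(chrom, start, end, name=gene_id), strand))
        except ParseError:
            raise
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc))
    try:
        return GeneSet(genes)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}")


def write_gene_table(path, genes: GeneSet, header_comments: Sequence[str] = ()) -> None:
    with open(path, "wt") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        fh.write("chrom\tstart\tend\tstrand\tgene_id\n")
        for g in genes:
            fh.write(f"{g.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.strand}\t{g.gene_id}\n")


def read_bed(path, one_based: bool = False, chrom_style: str | None = None) -> list[GenomicInterval]:
    """Read a BED3+ file, preserving input order."""
    out: list[GenomicInterval] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(path, lineno, f"BED needs ≥3 columns, got {len(fields)}")
        try:
            chrom = normalize_chrom(fields[0], chrom_style)
            start = int(fields[1]) - (1 if one_based else 0)
            end = int(fields[2])
            name = fields[3] if len(fields) > 3 else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            out.append(GenomicInterval(chrom, start, end, name=name, score=score))
        except ParseError:
            raise
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc))
    return out


def write_bed(path, intervals: Sequence[GenomicInterval], header_comments: Sequence[str] = ()) -> None:
    with open(path, "wt") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                cols.append(repr(iv.score))
            fh.write("\t".join(cols) + "\n")


def read_bedpe_contacts(
    path,
    q_threshold: float = 0.01,
    bin_size: int | None = 20_000,
    on_bad_width: str = "warn",
    chrom_style: str | None = None,
) -> list[Contact]:
    """Read significant contacts from a BEDPE with q-value and O/E columns 7-8.

    Only rows with ``qvalue < q_threshold`` are kept (the screen applied to
    the contact caller's output).  Anchors whose width differs from
    ``bin_size`` trigger a warning (``on_bad_width='warn'``), are dropped
    (``'reject'``), or pass silently (``'keep'``).
    """
    if on_bad_width not in ("warn", "reject", "keep"):
        raise ValueError(f"on_bad_width must be warn/reject/keep, got {on_bad_width!r}")
    contacts: list[Contact] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 8:
            raise ParseError(path, lineno, f"contact BEDPE needs ≥8 columns, got {len(fields)}")
        try:
            a1 = GenomicInterval(normalize_chrom(fields[0], chrom_style), int(fields[1]), int(fields[2]))
            a2 = GenomicInterval(normalize_chrom(fields[3], chrom_style), int(fields[4]), int(fields[5]))
            q = float(fields[6])
            oe = float(fields[7])
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc))
        if q >= q_threshold:
            continue
        if bin_size is not None and (a1.length != bin_size or a2.length != bin_size):
            if on_bad_width == "reject":
                warnings.warn(f"{path}:{lineno}: anchor width != {bin_size}, row dropped")
                continue
            if on_bad_width == "warn":
                warnings.warn(f"{path}:{lineno}: anchor width != {bin_size}")
        contacts.append(Contact(a1, a2, q, oe))
    return contacts


def write_bedpe_contacts(path, contacts: Sequence[Contact], header_comments: Sequence[str] = ()) -> None:
    with open(path, "wt") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        for ct in contacts:
            fh.write("\t".join([
                ct.anchor1.chrom, str(ct.anchor1.start), str(ct.anchor1.end),
                ct.anchor2.chrom, str(ct.anchor2.start), str(ct.anchor2.end),
                repr(ct.qvalue), repr(ct.oe),
            ]) + "\n")


def read_bedgraph(path, chrom_style: str | None = None) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Read a bedGraph into per-chromosome (starts, ends, values) arrays.

    Intervals are sorted by start per chromosome; positions not covered by
    any interval carry signal 0.
    """
    acc: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(path, lineno, f"bedGraph needs 4 columns, got {len(fields)}")
        try:
            chrom = normalize_chrom(fields[0], chrom_style)
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc))
        if start >= end:
            raise ParseError(path, lineno, f"empty bedGraph interval {start}-{end}")
        acc.setdefault(chrom, []).append((start, end, value))
    out = {}
    for chrom, rows in acc.items():
        rows.sort()
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        values = np.array([r[2] for r in rows], dtype=float)
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{path}: overlapping bedGraph intervals on {chrom}")
        out[chrom] = (starts, ends, values)
    return out


def write_bedgraph(path, signal: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                   header_comments: Sequence[str] = ()) -> None:
    with open(path, "wt") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        for chrom in sorted(signal):
            starts, ends, values = signal[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{float(v):g}\n")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def build_trees(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees mapping to input indices."""
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def intersect_regions(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    min_overlap_bp: int = 1,
) -> list[tuple[int, int]]:
    """All (query_index, subject_index) pairs overlapping by >= min_overlap_bp.

    Half-open arithmetic: abutting intervals do not overlap.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees = build_trees(subject)
    pairs: list[tuple[int, int]] = []
    for qi, q in enumerate(query):
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(q.start, q.end):
            if min(q.end, hit.end) - max(q.start, hit.begin) >= min_overlap_bp:
                pairs.append((qi, hit.data))
    pairs.sort()
    return pairs


def _chrom_arrays(intervals: Sequence[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    acc: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        acc.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, rows in acc.items():
        rows.sort()
        out[chrom] = (np.array([r[0] for r in rows], dtype=np.int64),
                      np.array([r[1] for r in rows], dtype=np.int64))
    return out


def nearest_distance(
    query: Sequence[GenomicInterval],
    reference: Sequence[GenomicInterval],
) -> np.ndarray:
    """Distance from each query to its nearest reference interval (bp).

    Overlapping intervals score 0; queries on chromosomes with no
    reference get NaN (callers exclude them from means).
    """
    if len(reference) == 0:
        raise ValueError("reference interval set is empty")
    ref = _chrom_arrays(reference)
    # cummax of ends handles nested reference intervals
    prepared = {}
    for chrom, (starts, ends) in ref.items():
        prepared[chrom] = (starts, np.maximum.accumulate(ends))
    out = np.full(len(query), np.nan)
    for i, q in enumerate(query):
        arrs = prepared.get(q.chrom)
        if arrs is None:
            continue
        starts, cummax_ends = arrs
        j = np.searchsorted(starts, q.end, side="left")
        # gap to the nearest interval starting at/after q.end
        d_right = starts[j] - q.end if j < len(starts) else np.inf
        # any interval starting before q.end: overlap if its end > q.start
        if j > 0:
            d_left = max(0, q.start - int(cummax_ends[j - 1]))
        else:
            d_left = np.inf
        out[i] = min(d_left, d_right)
    return out


def make_promoters(
    genes: Iterable[Gene],
    upstream: int = 2_000,
    downstream: int = 500,
    layout: GenomeLayout | None = None,
) -> list[GenomicInterval]:
    """Strand-aware promoter windows around each TSS, clipped to bounds.

    On '+' the window is [tss - upstream, tss + downstream); on '-' it is
    the strand-flipped equivalent covering the same offsets relative to
    transcription.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be >= 0")
    if upstream == 0 and downstream == 0:
        raise ValueError("promoter window must have positive width")
    out = []
    for g in genes:
        tss = g.tss
        if g.strand == "+":
            start, end = tss - upstream, tss + downstream
        else:
            start, end = tss - downstream + 1, tss + upstream + 1
        start = max(0, start)
        if layout is not None:
            end = min(end, layout.chrom_lengths.get(g.chrom, end))
        if start < end:
            out.append(GenomicInterval(g.chrom, start, end, name=g.gene_id))
    return out


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or abutting intervals per chromosome; sorted output."""
    out: list[GenomicInterval] = []
    for chrom in sorted({iv.chrom for iv in intervals}):
        rows = sorted((iv.start, iv.end) for iv in intervals if iv.chrom == chrom)
        cur_s, cur_e = rows[0]
        for s, e in rows[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out
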