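"""Enrichment of region sets in a genome segmentation of chromatin states.

The segmentation is a set of non-overlapping labeled intervals (a
ChromHMM-style dense BED: the state label sits in the name field).  Fold
enrichment of a region set in state s is

    (region bp in s / total region bp) / (genome bp in s / genome bp),

and the heatmap scaling subtracts the column (state) minimum and divides
by the column maximum.  A conventional min-max scaling
((v - min)/(max - min)) is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeLayout, GenomicInterval, read_bed

SCALE_MODES = ("column_minmax", "column_range")


class StateSegmentation:
    """Non-overlapping labeled intervals partitioning the assayed genome."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        for iv in intervals:
            if iv.name is None:
                raise ValueError("segmentation intervals need a state label in the name field")
        self.intervals = sorted(intervals, key=lambda iv: (iv.chrom, iv.start))
        for a, b in zip(self.intervals, self.intervals[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(
                    f"overlapping segments {a.chrom}:{a.start}-{a.end} and "
                    f"{b.chrom}:{b.start}-{b.end}"
                )
        self.states = sorted({iv.name for iv in self.intervals})
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        for chrom in {iv.chrom for iv in self.intervals}:
            segs = [iv for iv in self.intervals if iv.chrom == chrom]
            self._by_chrom[chrom] = (
                np.array([s.start for s in segs], dtype=np.int64),
                np.array([s.end for s in segs], dtype=np.int64),
                [s.name for s in segs],
            )

    @classmethod
    def from_bed(cls, path, **kwargs) -> "StateSegmentation":
        return cls(read_bed(path, **kwargs))

    def state_bp(self) -> dict[str, int]:
        """Total bp covered by each state."""
        out = {s: 0 for s in self.states}
        for iv in self.intervals:
            out[iv.name] += iv.length
        return out

    def region_state_bp(self, regions: Sequence[GenomicInterval]) -> dict[str, int]:
        """bp of the (possibly overlapping) region set falling in each state.

        Regions are counted independently: splitting a region into
        adjacent pieces leaves the tally unchanged.
        """
        out = {s: 0 for s in self.states}
        for r in regions:
            arrs = self._by_chrom.get(r.chrom)
            if arrs is None:
                continue
            starts, ends, labels = arrs
            lo = int(np.searchsorted(ends, r.start, side="right"))
            hi = int(np.searchsorted(starts, r.end, side="left"))
            for i in range(lo, hi):
                ov = min(r.end, int(ends[i])) - max(r.start, int(starts[i]))
                if ov > 0:
                    out[labels[i]] += ov
        return out


def state_enrichment(
    regions: Sequence[GenomicInterval],
    segmentation: StateSegmentation,
    genome: GenomeLayout,
) -> pd.Series:
    """Per-state fold enrichment of one region set; NaN for uncovered states."""
    if len(regions) == 0:
        raise ValueError("empty region set")
    genome_bp = genome.total_bp
    seg_bp = segmentation.state_bp()
    reg_bp = segmentation.region_state_bp(regions)
    total_reg = sum(r.length for r in regions)
    vals = {}
    for s in segmentation.states:
        if seg_bp[s] == 0 or total_reg == 0:
            vals[s] = np.nan
            continue
        vals[s] = (reg_bp[s] / total_reg) / (seg_bp[s] / genome_bp)
    return pd.Series(vals, name="fold_enrichment")


@dataclass
class StateEnrichmentMatrix:
    """Region-set x state fold enrichments, raw and column-scaled."""

    raw: pd.DataFrame
    scaled: pd.DataFrame
    scale_mode: str


def enrichment_matrix(
    region_sets: Mapping[str, Sequence[GenomicInterval]],
    segmentation: StateSegmentation,
    genome: GenomeLayout,
    scale: str = "column_minmax",
) -> StateEnrichmentMatrix:
    """Fold-enrichment matrix over several region sets with column scaling.

    ``column_minmax`` (default) applies (v - column min) / column max;
    ``column_range`` applies the conventional (v - min) / (max - min).
    Constant columns scale to 0 in both modes.
    """
    if scale not in SCALE_MODES:
        raise ValueError(f"unknown scale mode {scale!r}; expected one of {SCALE_MODES}")
    raw = pd.DataFrame(
        {name: state_enrichment(regions, segmentation, genome)
         for name, regions in region_sets.items()}
    ).T
    raw = raw[segmentation.states]
    scaled = raw.copy()
    for col in scaled.columns:
        v = scaled[col]
        lo, hi = v.min(), v.max()
        if scale == "column_minmax":
            denom = hi
        else:
            denom = hi - lo
        if denom and denom > 0:
            scaled[col] = (v - lo) / denom
        else:
            scaled[col] = 0.0
    return StateEnrichmentMatrix(raw, scaled, scale)
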