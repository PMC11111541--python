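"""Per-gene chromatin-interaction profiles and cumulative interaction scores.

A significant contact is *gene-associated* when either of its two anchor
bins overlaps the gene body by at least 1 bp; the other bin of such a
contact is the gene's *corresponding anchor* (the putative regulatory
partner region).  Genes are ranked by a cumulative interaction score
aggregated over their associated contacts, and the top fraction (default
5%) forms the high-interaction gene set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import Contact, Gene, GeneSet, GenomicInterval, build_trees, intersect_regions

SCORE_MODES = ("sum_oe", "count", "sum_neglog_q")


@dataclass
class GeneInteractionProfile:
    """All significant contacts assigned to one gene and their partner bins.

    ``partners[i]`` holds the partner bin(s) of ``contacts[i]``: one bin
    normally, both bins when both anchors of the contact overlap the gene
    (the contact still counts once toward the score).
    """

    gene_id: str
    contacts: list[Contact] = field(default_factory=list)
    partners: list[list[GenomicInterval]] = field(default_factory=list)

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def anchors(self) -> list[GenomicInterval]:
        """Flat list of partner anchor bins (may contain duplicates)."""
        return [a for group in self.partners for a in group]

    def distances(self) -> list[int]:
        """Intra-chromosomal contact distances (trans contacts excluded)."""
        return [c.distance for c in self.contacts if c.distance is not None]


def associate_contacts(
    genes: GeneSet,
    contacts: Sequence[Contact],
) -> dict[str, GeneInteractionProfile]:
    """Assign each contact to every gene one of its anchors overlaps.

    One contact may be assigned to several genes.  When both anchors
    overlap the same gene the contact is assigned once and both partner
    bins are recorded as anchors.  Genes with no contact get an empty
    profile.
    """
    profiles = {g.gene_id: GeneInteractionProfile(g.gene_id) for g in genes}
    trees = build_trees(genes.intervals())
    ids = genes.ids()
    for contact in contacts:
        hits: dict[int, list[GenomicInterval]] = {}
        for anchor, partner in ((contact.anchor1, contact.anchor2),
                                (contact.anchor2, contact.anchor1)):
            tree = trees.get(anchor.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(anchor.start, anchor.end):
                hits.setdefault(hit.data, []).append(partner)
        for gi, partners in hits.items():
            prof = profiles[ids[gi]]
            prof.contacts.append(contact)
            prof.partners.append(partners)
    return profiles


def cumulative_interaction_score(profile: GeneInteractionProfile, mode: str = "sum_oe") -> float:
    """Aggregate a gene's contact intensities into one score.

    sum_oe (default) sums the O/E intensity over assigned contacts; count
    returns the number of contacts; sum_neglog_q sums -log10(q).
    """
    if mode == "sum_oe":
        return float(sum(c.oe for c in profile.contacts))
    if mode == "count":
        return float(profile.n_contacts)
    if mode == "sum_neglog_q":
        return float(sum(-math.log10(max(c.qvalue, 1e-300)) for c in profile.contacts))
    raise ValueError(f"unknown score mode {mode!r}; expected one of {SCORE_MODES}")


def score_table(
    profiles: Mapping[str, GeneInteractionProfile],
    mode: str = "sum_oe",
) -> pd.DataFrame:
    """Per-gene score table (gene_id, n_contacts, score), all genes included."""
    rows = [(gid, p.n_contacts, cumulative_interaction_score(p, mode))
            for gid, p in profiles.items()]
    return pd.DataFrame(rows, columns=["gene_id", "n_contacts", "score"])


@dataclass
class RankedGeneTable:
    """Genes ranked by cumulative score with a top-fraction flag."""

    table: pd.DataFrame  # columns gene_id, score, rank, in_top
    fraction: float

    @property
    def top_set(self) -> frozenset[str]:
        return frozenset(self.table.loc[self.table["in_top"], "gene_id"])


def top_fraction_genes(scores: Mapping[str, float] | pd.DataFrame, fraction: float = 0.05) -> RankedGeneTable:
    """Rank genes by score (descending) and flag the top ``fraction``.

    Ties are broken lexicographically by gene_id so the ranking is
    deterministic; the top set has ceil(fraction * N) members.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    if isinstance(scores, pd.DataFrame):
        items = list(zip(scores["gene_id"], scores["score"]))
    else:
        items = list(scores.items())
    if not items:
        raise ValueError("empty score table")
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    n_top = math.ceil(fraction * len(items))
    df = pd.DataFrame(items, columns=["gene_id", "score"])
    df["rank"] = np.arange(1, len(items) + 1)
    df["in_top"] = df["rank"] <= n_top
    return RankedGeneTable(df, fraction)


def corresponding_anchors(
    gene_ids: Iterable[str],
    profiles: Mapping[str, GeneInteractionProfile],
) -> list[GenomicInterval]:
    """Union of partner anchor bins across a gene set, deduplicated and sorted."""
    seen: set[tuple[str, int, int]] = set()
    for gid in gene_ids:
        if gid not in profiles:
            raise KeyError(f"gene {gid!r} has no interaction profile")
        for a in profiles[gid].anchors:
            seen.add((a.chrom, a.start, a.end))
    return [GenomicInterval(c, s, e) for c, s, e in sorted(seen)]


def promoter_association_proportion(
    gene_ids: Iterable[str],
    profiles: Mapping[str, GeneInteractionProfile],
    promoters: Sequence[GenomicInterval],
) -> float:
    """Fraction of the set's assigned contacts whose partner anchor lies on a promoter.

    The unit is one (gene, contact) assignment; the assignment counts as
    promoter-associated when any of its recorded partner bins overlaps a
    promoter window by >= 1 bp.
    """
    trees = build_trees(promoters)

    def on_promoter(iv: GenomicInterval) -> bool:
        tree = trees.get(iv.chrom)
        return tree is not None and bool(tree.overlap(iv.start, iv.end))

    total = 0
    hit = 0
    for gid in gene_ids:
        prof = profiles[gid]
        for partners in prof.partners:
            total += 1
            if any(on_promoter(p) for p in partners):
                hit += 1
    if total == 0:
        return 0.0
    return hit / total


def distance_ecdf(values: Sequence[float]) -> pd.DataFrame:
    """Right-continuous ECDF as a sorted (x, F) table with F(max) = 1."""
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        raise ValueError("distance_ecdf needs at least one finite value")
    xs = np.unique(vals)
    counts = np.searchsorted(np.sort(vals), xs, side="right")
    return pd.DataFrame({"x": xs, "F": counts / vals.size})


def ecdf_at(ecdf: pd.DataFrame, x: float) -> float:
    """Evaluate a distance_ecdf table at x (right-continuous)."""
    idx = np.searchsorted(ecdf["x"].to_numpy(), x, side="right") - 1
    return 0.0 if idx < 0 else float(ecdf["F"].iloc[idx])
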