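"""Synthetic-study generator with planted regulatory structure.

Emits a complete fake study — genome layout, gene models, differential
expression labels, significant 20-kb contacts with q-value and O/E,
differential methylation sites, differential H3K27me3/H3K9me3 sites, a
6-state segmentation, and a bedGraph signal track — together with a
ground-truth record for recovery tests.

The planted structure mirrors the regulatory model under test:

* upregulated genes receive more and stronger contacts with a heavy-tail
  distance law whose distal partner bins avoid promoters (enhancer-like,
  labeled Enh in the segmentation, and targeted by H3K9me3-loss loci);
* downregulated genes contact mostly promoter bins of nearby genes
  (promoter-promoter interactions, rate ~0.8 vs ~0.2 for upregulated),
  and attract hypermethylated DMSs on their partner anchors and
  H3K27me3-gain peaks at their TSSs;
* unchanged genes sit in between with background rates.

Every artifact type draws from its own RNG stream derived from the master
seed, so changing mark parameters never perturbs contact placement.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .genome import (
    Contact,
    Gene,
    GeneSet,
    GenomeLayout,
    GenomicInterval,
    build_trees,
    make_promoters,
    write_bed,
    write_bedgraph,
    write_bedpe_contacts,
    write_gene_table,
)
from .marks import MarkSite, write_mark_table
from .stats import child_seed

STATE_LABELS = ("Tss", "Enh", "EnhLo", "Tx", "ReprPC", "Quies")


@dataclass
class StudyParams:
    """Knobs of the synthetic study; defaults are the study conditions."""

    # genome
    n_chrom: int = 4
    chrom_length: int = 50_000_000
    bin_size: int = 20_000
    # genes
    n_genes: int = 2_000
    frac_up: float = 0.05
    frac_down: float = 0.05
    gene_length_meanlog: float = float(np.log(20_000))
    gene_length_sdlog: float = 0.5
    # promoter window used for planting
    promoter_upstream: int = 2_000
    promoter_downstream: int = 500
    # contacts: mean per-gene counts, O/E lognormal, distance laws
    lambda_up: float = 10.0
    lambda_down: float = 3.0
    lambda_non: float = 4.0
    oe_meanlog_up: float = float(np.log(3.0))
    oe_meanlog_down: float = float(np.log(1.5))
    oe_meanlog_non: float = float(np.log(2.0))
    oe_sdlog: float = 0.4
    dist_meanlog_up: float = float(np.log(2_000_000))
    dist_sdlog_up: float = 1.0
    dist_max_down: int = 400_000
    dist_meanlog_non: float = float(np.log(500_000))
    dist_sdlog_non: float = 0.8
    promoter_contact_rate_up: float = 0.2
    promoter_contact_rate_down: float = 0.8
    promoter_contact_rate_non: float = 0.5
    # planted promoter-promoter hub structure: down genes contact nearby
    # promoters; up genes stay out of the hubs (enhancer-driven)
    down_local_window: int = 2_000_000
    exclude_up_from_hubs: bool = True
    # marks
    n_hyper_dms: int = 400
    n_hypo_dms: int = 400
    p_plant_hyper_dms: float = 0.7
    n_k27_up: int = 60
    n_k27_down: int = 40
    p_plant_k27_up: float = 0.8
    n_k9_down: int = 150
    n_k9_up: int = 100
    p_plant_k9_down: float = 0.7
    mark_width_k27: int = 2_000
    mark_width_k9: int = 2_000
    # segmentation extras
    frac_enhlo_bins: float = 0.05
    frac_reprpc_bins: float = 0.03

    def __post_init__(self):
        if not (0 < self.frac_up < 1 and 0 < self.frac_down < 1):
            raise ValueError("frac_up and frac_down must lie in (0, 1)")
        if self.frac_up + self.frac_down >= 1:
            raise ValueError("frac_up + frac_down must be < 1")
        for name in ("lambda_up", "lambda_down", "lambda_non"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def null(cls, **overrides) -> "StudyParams":
        """A no-effect parameterization: equal contact rates, no planting."""
        base = dict(
            lambda_up=4.0, lambda_down=4.0, lambda_non=4.0,
            oe_meanlog_up=float(np.log(2.0)), oe_meanlog_down=float(np.log(2.0)),
            dist_meanlog_up=float(np.log(500_000)), dist_sdlog_up=0.8,
            dist_max_down=0,  # sentinel: use the non-gene distance law
            promoter_contact_rate_up=0.5, promoter_contact_rate_down=0.5,
            down_local_window=0, exclude_up_from_hubs=False,
            p_plant_hyper_dms=0.0, p_plant_k27_up=0.0, p_plant_k9_down=0.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "StudyParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown study parameters: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """What was planted where, for recovery tests."""

    gene_class: dict[str, str]                    # gene_id -> up/down/non
    contact_provenance: list[dict]                # per contact: gene, class, partner type
    mark_flags: dict[str, list[bool]]             # mark file key -> planted flags
    params: dict

    def to_json(self, path) -> None:
        with open(path, "wt") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class StudyBundle:
    """In-memory view of one generated study."""

    layout: GenomeLayout
    genes: GeneSet
    labels: dict[str, str]
    contacts: list[Contact]
    hyper_dms: list[MarkSite]
    hypo_dms: list[MarkSite]
    k27_up: list[MarkSite]
    k27_down: list[MarkSite]
    k9_down: list[MarkSite]
    k9_up: list[MarkSite]
    segmentation_intervals: list[GenomicInterval]
    signal: dict
    truth: GroundTruth
    deg_table: "object" = None


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, name))


def place_genes(params: StudyParams, seed: int) -> tuple[GenomeLayout, GeneSet]:
    """Place non-overlapping genes uniformly on the synthetic genome."""
    layout = GenomeLayout(
        {f"chr{i + 1}": params.chrom_length for i in range(params.n_chrom)},
        bin_size=params.bin_size,
    )
    rng = _rng(seed, "genes")
    chroms = list(layout.chrom_lengths)
    lengths_bp = np.array([layout.chrom_lengths[c] for c in chroms], dtype=float)
    # allocate gene counts proportional to chromosome length
    alloc = np.floor(params.n_genes * lengths_bp / lengths_bp.sum()).astype(int)
    for i in range(params.n_genes - alloc.sum()):
        alloc[i % len(chroms)] += 1
    genes: list[Gene] = []
    gid = 0
    for c, n_c in zip(chroms, alloc):
        L = layout.chrom_lengths[c]
        glens = np.exp(rng.normal(params.gene_length_meanlog, params.gene_length_sdlog, n_c))
        glens = np.clip(glens, 2_000, 500_000).astype(int)
        free = L - int(glens.sum())
        if free < 0:
            raise ValueError(
                f"genome too small: {n_c} genes of total {glens.sum()} bp do not fit on {c} ({L} bp)"
            )
        # stick-breaking: n_c + 1 random gaps summing to the free space
        cuts = np.sort(rng.integers(0, free + 1, size=n_c))
        pos = 0
        prev_cut = 0
        for j in range(n_c):
            gap = int(cuts[j]) - prev_cut
            prev_cut = int(cuts[j])
            start = pos + gap
            end = start + int(glens[j])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"g{gid:05d}", GenomicInterval(c, start, end), strand))
            gid += 1
            pos = end
    return layout, GeneSet(genes)


def assign_labels(genes: GeneSet, params: StudyParams, seed: int) -> dict[str, str]:
    rng = _rng(seed, "labels")
    ids = np.array(genes.ids())
    perm = rng.permutation(len(ids))
    n_up = int(round(params.frac_up * len(ids)))
    n_down = int(round(params.frac_down * len(ids)))
    labels = {gid: "non" for gid in ids}
    for i in perm[:n_up]:
        labels[ids[i]] = "up"
    for i in perm[n_up:n_up + n_down]:
        labels[ids[i]] = "down"
    return labels


def _promoter_bins(genes: GeneSet, layout: GenomeLayout, params: StudyParams) -> tuple[dict, set]:
    """TSS bin per gene and the set of genic bins (overlapping a promoter
    or gene body), which distal enhancer partners must avoid."""
    promoters = make_promoters(genes, params.promoter_upstream, params.promoter_downstream, layout)
    bs = layout.bin_size
    forbidden: set[tuple[str, int]] = set()
    for iv in list(promoters) + [g.interval for g in genes]:
        for b in range(iv.start // bs, (iv.end - 1) // bs + 1):
            forbidden.add((iv.chrom, b * bs))
    tss_bin = {g.gene_id: (g.chrom, (g.tss // bs) * bs) for g in genes}
    return tss_bin, forbidden


def plant_contacts(
    genes: GeneSet,
    labels: dict[str, str],
    params: StudyParams,
    layout: GenomeLayout,
    seed: int,
) -> tuple[list[Contact], list[dict]]:
    """Plant per-gene significant contacts with class-specific structure.

    Contact counts are Poisson(lambda_class); the gene-side anchor is the
    gene's TSS bin.  Partner bins are promoter bins of other genes with
    the class promoter-contact rate, otherwise non-promoter bins drawn
    from the class distance law; O/E is LogNormal(class).  Emitted
    q-values are U(0, 0.01) (all pass the significance screen).
    """
    rng = _rng(seed, "contacts")
    bs = layout.bin_size
    tss_bin, promoter_bins = _promoter_bins(genes, layout, params)
    genes_by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    lam = {"up": params.lambda_up, "down": params.lambda_down, "non": params.lambda_non}
    oe_mu = {"up": params.oe_meanlog_up, "down": params.oe_meanlog_down, "non": params.oe_meanlog_non}
    prom_rate = {
        "up": params.promoter_contact_rate_up,
        "down": params.promoter_contact_rate_down,
        "non": params.promoter_contact_rate_non,
    }

    def sample_distance(cls: str) -> int:
        if cls == "up":
            d = np.exp(rng.normal(params.dist_meanlog_up, params.dist_sdlog_up))
        elif cls == "down" and params.dist_max_down > 0:
            d = rng.uniform(2 * bs, params.dist_max_down)
        else:
            d = np.exp(rng.normal(params.dist_meanlog_non, params.dist_sdlog_non))
        return max(int(round(d / bs)) * bs, bs)

    contacts: list[Contact] = []
    provenance: list[dict] = []
    for g in genes:
        cls = labels[g.gene_id]
        n = int(rng.poisson(lam[cls]))
        chrom, gbin = tss_bin[g.gene_id]
        neighbors = genes_by_chrom[chrom]
        max_start = ((layout.chrom_lengths[chrom] - bs) // bs) * bs
        # promoter-promoter hubs form among adjacent down/non genes;
        # upregulated genes are enhancer-driven and stay out of the hubs
        hub = [h for h in neighbors
               if h.gene_id != g.gene_id
               and not (params.exclude_up_from_hubs and labels[h.gene_id] == "up")]
        for _ in range(n):
            if rng.random() < prom_rate[cls]:
                if cls == "down" and params.down_local_window > 0:
                    local = [h for h in hub if abs(h.tss - g.tss) <= params.down_local_window]
                    pool = local or hub
                else:
                    pool = hub
                partner_gene = pool[int(rng.integers(len(pool)))]
                pbin = tss_bin[partner_gene.gene_id][1]
                partner_type = "promoter"
            else:
                # distal non-promoter partner from the class distance law
                pbin = None
                for _try in range(64):
                    d = sample_distance(cls)
                    cand = gbin + d if rng.random() < 0.5 else gbin - d
                    cand = min(max(cand, 0), max_start)
                    if cand != gbin and (chrom, cand) not in promoter_bins:
                        pbin = cand
                        break
                if pbin is None:
                    continue  # genome saturated with promoters; skip
                partner_type = "distal"
            if pbin == gbin:
                continue
            a1 = GenomicInterval(chrom, gbin, min(gbin + bs, layout.chrom_lengths[chrom]))
            a2 = GenomicInterval(chrom, pbin, min(pbin + bs, layout.chrom_lengths[chrom]))
            q = float(rng.uniform(0.0, 0.01))
            oe = float(np.exp(rng.normal(oe_mu[cls], params.oe_sdlog)))
            contacts.append(Contact(a1, a2, q, oe))
            provenance.append({
                "gene_id": g.gene_id, "gene_class": cls, "partner_type": partner_type,
                "partner_bin": [chrom, int(pbin)],
            })
    return contacts, provenance


def _partner_bins(provenance: Sequence[dict], gene_class: str, partner_type: str | None = None) -> list[tuple[str, int]]:
    out = []
    for rec in provenance:
        if rec["gene_class"] != gene_class:
            continue
        if partner_type is not None and rec["partner_type"] != partner_type:
            continue
        out.append((rec["partner_bin"][0], rec["partner_bin"][1]))
    return sorted(set(out))


def plant_marks(
    genes: GeneSet,
    labels: dict[str, str],
    provenance: Sequence[dict],
    params: StudyParams,
    layout: GenomeLayout,
    seed: int,
) -> tuple[dict[str, list[MarkSite]], dict[str, list[bool]]]:
    """Plant differential marks on the contact structure.

    Hypermethylated DMSs land inside partner anchors of downregulated
    genes with probability ``p_plant_hyper_dms`` (uniform background
    otherwise); H3K27me3-gain peaks centre on downregulated TSSs;
    H3K9me3-loss loci overlap distal (enhancer) anchors of upregulated
    genes.  Hypomethylated DMSs, K27-loss and K9-gain sites are uniform
    background.
    """
    rng = _rng(seed, "marks")
    bs = layout.bin_size
    chroms = list(layout.chrom_lengths)
    lengths = np.array([layout.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    down_anchor_bins = _partner_bins(provenance, "down")
    up_distal_bins = _partner_bins(provenance, "up", "distal")
    down_tss = [g.tss for g in genes if labels[g.gene_id] == "down"]
    down_tss_chrom = [g.chrom for g in genes if labels[g.gene_id] == "down"]

    def uniform_site(width: int) -> GenomicInterval:
        ci = int(rng.choice(len(chroms), p=probs))
        chrom = chroms[ci]
        s = int(rng.integers(0, layout.chrom_lengths[chrom] - width))
        return GenomicInterval(chrom, s, s + width)

    def in_bin_site(bin_key: tuple[str, int], width: int) -> GenomicInterval:
        chrom, bstart = bin_key
        hi = min(bstart + bs, layout.chrom_lengths[chrom]) - width
        s = int(rng.integers(bstart, max(hi, bstart) + 1))
        return GenomicInterval(chrom, s, s + width)

    marks: dict[str, list[MarkSite]] = {}
    flags: dict[str, list[bool]] = {}

    # hypermethylated DMSs (single-bp sites)
    sites, planted = [], []
    for _ in range(params.n_hyper_dms):
        if down_anchor_bins and rng.random() < params.p_plant_hyper_dms:
            iv = in_bin_site(down_anchor_bins[int(rng.integers(len(down_anchor_bins)))], 1)
            planted.append(True)
        else:
            iv = uniform_site(1)
            planted.append(False)
        sites.append(MarkSite(iv, "DMS", "up",
                              effect=float(rng.uniform(10, 40)),
                              significance=float(rng.uniform(0, 0.05))))
    marks["hyper_dms"], flags["hyper_dms"] = sites, planted

    # hypomethylated DMSs: background only
    sites = [MarkSite(uniform_site(1), "DMS", "down",
                      effect=float(-rng.uniform(10, 40)),
                      significance=float(rng.uniform(0, 0.05)))
             for _ in range(params.n_hypo_dms)]
    marks["hypo_dms"], flags["hypo_dms"] = sites, [False] * len(sites)

    # H3K27me3 gain at down TSSs
    sites, planted = [], []
    w = params.mark_width_k27
    for _ in range(params.n_k27_up):
        if down_tss and rng.random() < params.p_plant_k27_up:
            j = int(rng.integers(len(down_tss)))
            centre = down_tss[j]
            s = max(0, centre - w // 2)
            iv = GenomicInterval(down_tss_chrom[j], s, s + w)
            planted.append(True)
        else:
            iv = uniform_site(w)
            planted.append(False)
        sites.append(MarkSite(iv, "H3K27me3_peak", "up",
                              effect=float(rng.uniform(0.5, 2.0)),
                              significance=float(rng.uniform(0, 0.05))))
    marks["k27_up"], flags["k27_up"] = sites, planted

    sites = [MarkSite(uniform_site(w), "H3K27me3_peak", "down",
                      effect=float(-rng.uniform(0.5, 2.0)),
                      significance=float(rng.uniform(0, 0.05)))
             for _ in range(params.n_k27_down)]
    marks["k27_down"], flags["k27_down"] = sites, [False] * len(sites)

    # H3K9me3 loss over up-gene distal anchors
    sites, planted = [], []
    w = params.mark_width_k9
    for _ in range(params.n_k9_down):
        if up_distal_bins and rng.random() < params.p_plant_k9_down:
            iv = in_bin_site(up_distal_bins[int(rng.integers(len(up_distal_bins)))], w)
            planted.append(True)
        else:
            iv = uniform_site(w)
            planted.append(False)
        sites.append(MarkSite(iv, "H3K9me3_locus", "down",
                              effect=float(-rng.uniform(0.5, 2.0)),
                              significance=float(rng.uniform(0, 0.05))))
    marks["k9_down"], flags["k9_down"] = sites, planted

    sites = [MarkSite(uniform_site(w), "H3K9me3_locus", "up",
                      effect=float(rng.uniform(0.5, 2.0)),
                      significance=float(rng.uniform(0, 0.05)))
             for _ in range(params.n_k9_up)]
    marks["k9_up"], flags["k9_up"] = sites, [False] * len(sites)

    return marks, flags


def build_segmentation(
    genes: GeneSet,
    labels: dict[str, str],
    provenance: Sequence[dict],
    params: StudyParams,
    layout: GenomeLayout,
    seed: int,
) -> list[GenomicInterval]:
    """Six-state segmentation: Tss on promoters, Enh on up-gene distal
    anchors, Tx on gene bodies, random EnhLo/ReprPC bins, Quies elsewhere.

    Overlaps resolve by priority Tss > Enh > Tx > EnhLo > ReprPC > Quies;
    the output is a non-overlapping cover of the genome.
    """
    rng = _rng(seed, "segmentation")
    bs = layout.bin_size
    priority = {label: i for i, label in enumerate(STATE_LABELS)}
    candidates: list[tuple[GenomicInterval, str]] = []
    for p in make_promoters(genes, params.promoter_upstream, params.promoter_downstream, layout):
        candidates.append((p, "Tss"))
    for chrom, bstart in _partner_bins(provenance, "up", "distal"):
        candidates.append((GenomicInterval(chrom, bstart, min(bstart + bs, layout.chrom_lengths[chrom])), "Enh"))
    for g in genes:
        candidates.append((g.interval, "Tx"))
    for chrom in layout.chrom_lengths:
        n_bins = layout.chrom_lengths[chrom] // bs
        n_lo = int(params.frac_enhlo_bins * n_bins)
        n_re = int(params.frac_reprpc_bins * n_bins)
        picks = rng.choice(n_bins, size=min(n_lo + n_re, n_bins), replace=False)
        for j, b in enumerate(picks):
            label = "EnhLo" if j < n_lo else "ReprPC"
            s = int(b) * bs
            candidates.append((GenomicInterval(chrom, s, min(s + bs, layout.chrom_lengths[chrom])), label))

    segments: list[GenomicInterval] = []
    for chrom, L in layout.chrom_lengths.items():
        cand = [(iv, lab) for iv, lab in candidates if iv.chrom == chrom]
        bounds = np.array(sorted({0, L}
                                 | {min(iv.start, L) for iv, _ in cand}
                                 | {min(iv.end, L) for iv, _ in cand}), dtype=np.int64)
        n_seg = len(bounds) - 1
        # difference-array coverage per label over elementary segments
        covered = {}
        for label in STATE_LABELS[:-1]:
            ivs = [iv for iv, lab in cand if lab == label]
            diff = np.zeros(n_seg + 1, dtype=np.int32)
            if ivs:
                i0 = np.searchsorted(bounds, [iv.start for iv in ivs])
                i1 = np.searchsorted(bounds, [min(iv.end, L) for iv in ivs])
                np.add.at(diff, i0, 1)
                np.add.at(diff, i1, -1)
            covered[label] = np.cumsum(diff)[:n_seg] > 0
        choice = np.full(n_seg, len(STATE_LABELS) - 1, dtype=np.int8)  # Quies
        for label in reversed(STATE_LABELS[:-1]):
            choice[covered[label]] = priority[label]
        # emit runs of equal labels
        run_start = 0
        for i in range(1, n_seg + 1):
            if i == n_seg or choice[i] != choice[run_start]:
                segments.append(GenomicInterval(
                    chrom, int(bounds[run_start]), int(bounds[i]),
                    name=STATE_LABELS[choice[run_start]],
                ))
                run_start = i
    return segments


def build_signal(
    genes: GeneSet,
    labels: dict[str, str],
    params: StudyParams,
    layout: GenomeLayout,
    seed: int,
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Sparse repressive-mark-like bedGraph: bumps around TSSs, stronger on
    downregulated genes; uncovered positions are implicit zeros."""
    rng = _rng(seed, "signal")
    acc: dict[str, list[tuple[int, int, float]]] = {c: [] for c in layout.chrom_lengths}
    for g in genes:
        amp = 3.0 if labels[g.gene_id] == "down" else 1.0
        centre = g.tss
        for k in range(-5, 5):
            s = centre + k * 500
            e = s + 500
            if s < 0 or e > layout.chrom_lengths[g.chrom]:
                continue
            weight = np.exp(-abs(k + 0.5) / 2.5)
            v = float(amp * weight * rng.uniform(0.7, 1.3))
            acc[g.chrom].append((s, e, round(v, 4)))
    out = {}
    for chrom, rows in acc.items():
        if not rows:
            continue
        rows.sort()
        merged: list[tuple[int, int, float]] = []
        for s, e, v in rows:  # clip overlaps from adjacent genes
            if merged and s < merged[-1][1]:
                s = merged[-1][1]
                if s >= e:
                    continue
            merged.append((s, e, v))
        out[chrom] = (
            np.array([r[0] for r in merged], dtype=np.int64),
            np.array([r[1] for r in merged], dtype=np.int64),
            np.array([r[2] for r in merged], dtype=float),
        )
    return out


def make_deg_table(genes: GeneSet, labels: dict[str, str], seed: int):
    """Per-gene log2 fold change and p-value consistent with the labels."""
    import pandas as pd

    rng = _rng(seed, "deg")
    rows = []
    for g in genes:
        cls = labels[g.gene_id]
        if cls == "up":
            lfc = float(rng.normal(1.5, 0.4))
            lfc = max(lfc, 0.3)
            p = float(rng.uniform(1e-6, 0.04))
        elif cls == "down":
            lfc = float(-max(rng.normal(1.5, 0.4), 0.3))
            p = float(rng.uniform(1e-6, 0.04))
        else:
            lfc = float(rng.normal(0.0, 0.2))
            p = float(rng.uniform(0.05, 1.0))
        rows.append((g.gene_id, lfc, p, cls))
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "p", "class"])


def generate_study(params: StudyParams, seed: int, outdir=None) -> StudyBundle:
    """Generate the full synthetic study; write the file bundle if ``outdir`` given.

    Deterministic for a fixed (params, seed): the same call twice yields
    byte-identical files.
    """
    layout, genes = place_genes(params, seed)
    labels = assign_labels(genes, params, seed)
    contacts, provenance = plant_contacts(genes, labels, params, layout, seed)
    marks, flags = plant_marks(genes, labels, provenance, params, layout, seed)
    segmentation = build_segmentation(genes, labels, provenance, params, layout, seed)
    signal = build_signal(genes, labels, params, layout, seed)
    deg = make_deg_table(genes, labels, seed)
    truth = GroundTruth(
        gene_class=dict(labels),
        contact_provenance=provenance,
        mark_flags=flags,
        params=params.to_dict(),
    )
    bundle = StudyBundle(
        layout=layout, genes=genes, labels=labels, contacts=contacts,
        hyper_dms=marks["hyper_dms"], hypo_dms=marks["hypo_dms"],
        k27_up=marks["k27_up"], k27_down=marks["k27_down"],
        k9_down=marks["k9_down"], k9_up=marks["k9_up"],
        segmentation_intervals=segmentation, signal=signal, truth=truth,
        deg_table=deg,
    )
    if outdir is not None:
        write_study(bundle, outdir, seed)
    return bundle


def write_study(bundle: StudyBundle, outdir, seed: int) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hdr = [f"synthetic study seed={seed}"]
    write_gene_table(outdir / "genes.tsv", bundle.genes, hdr)
    bundle.deg_table.to_csv(outdir / "deg.tsv", sep="\t", index=False)
    write_bedpe_contacts(outdir / "contacts.bedpe", bundle.contacts, hdr)
    write_mark_table(outdir / "dms_hyper.bed", bundle.hyper_dms, hdr)
    write_mark_table(outdir / "dms_hypo.bed", bundle.hypo_dms, hdr)
    write_mark_table(outdir / "k27_up.bed", bundle.k27_up, hdr)
    write_mark_table(outdir / "k27_down.bed", bundle.k27_down, hdr)
    write_mark_table(outdir / "k9_down.bed", bundle.k9_down, hdr)
    write_mark_table(outdir / "k9_up.bed", bundle.k9_up, hdr)
    write_bed(outdir / "states.bed", bundle.segmentation_intervals, hdr)
    write_bedgraph(outdir / "signal.bedgraph", bundle.signal, hdr)
    with open(outdir / "layout.json", "wt") as fh:
        json.dump({"chrom_lengths": bundle.layout.chrom_lengths,
                   "bin_size": bundle.layout.bin_size}, fh, indent=1)
    bundle.truth.to_json(outdir / "truth.json")
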