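#!/usr/bin/env python
"""Annotate differential mark sites and test their association with
promoter-interacting anchors.

Genome-annotates each differential mark table (promoter / exon / intron /
intergenic / gene desert), then runs regioneR-style permutation tests
(600 resamplings from the all-gene promoter-anchor universe, meanDistance
and numOverlaps) for H3K9me3-loss loci against upregulated genes'
anchors and hypermethylated DMSs against downregulated genes' anchors.
Also computes the repressive-signal profile over downregulated gene
bodies (scale-regions, body 5 kb, flanks 3 kb).  Outputs to results/marks/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from chromlink.genome import make_promoters, read_bedgraph, read_bedpe_contacts, read_gene_table
from chromlink.interactions import associate_contacts
from chromlink.marks import (
    classify_annotation,
    mark_target_association,
    profile_matrix_frame,
    promoter_anchors,
    read_mark_table,
    signal_profile_matrix,
)
from chromlink.pipeline import load_layout
from chromlink.stats import child_seed

ap = argparse.ArgumentParser()
ap.add_argument("--study", type=Path, default=Path("results/study_default"))
ap.add_argument("--outdir", type=Path, default=Path("results/marks"))
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

layout = load_layout(args.study / "layout.json")
genes = read_gene_table(args.study / "genes.tsv")
deg = pd.read_csv(args.study / "deg.tsv", sep="\t", comment="#")
contacts = read_bedpe_contacts(args.study / "contacts.bedpe", q_threshold=0.01,
                               bin_size=layout.bin_size, on_bad_width="keep")
profiles = associate_contacts(genes, contacts)
promoters = make_promoters(genes, layout=layout)
up = sorted(deg.loc[deg["class"] == "up", "gene_id"])
down = sorted(deg.loc[deg["class"] == "down", "gene_id"])

kinds = {"dms_hyper": "DMS", "dms_hypo": "DMS", "k27_up": "H3K27me3_peak",
         "k27_down": "H3K27me3_peak", "k9_down": "H3K9me3_locus", "k9_up": "H3K9me3_locus"}
marks = {k: read_mark_table(args.study / f"{k}.bed", kind) for k, kind in kinds.items()}
rows = []
for key, sites in marks.items():
    br = classify_annotation(sites, genes, promoters)
    for cat, n in br.counts.items():
        rows.append((key, cat, n, br.fractions[cat]))
annot = pd.DataFrame(rows, columns=["mark_set", "category", "count", "fraction"])
annot.to_csv(args.outdir / "mark_annotation.tsv", sep="\t", index=False)
pivot = annot.pivot(index="mark_set", columns="category", values="fraction").round(2)
print("genome annotation fractions per mark set:")
print(pivot.to_string())

by_gene = {p.name: p for p in promoters}
universe = promoter_anchors(genes.ids(), profiles, by_gene)
assoc = {}
for key, mark_key, focal in (("k9loss_vs_up_anchors", "k9_down", up),
                             ("hyperdms_vs_down_anchors", "dms_hyper", down)):
    targets = promoter_anchors(focal, profiles, by_gene)
    res = mark_target_association(marks[mark_key], targets, universe, n_perm=600,
                                  seed=child_seed(args.seed, key), label=key)
    assoc[key] = {s: r.to_dict() for s, r in res.items()}
    print(f"{key}: mean distance z={res['mean_distance'].z:.2f} "
          f"(p_less={res['mean_distance'].p_less:.4g}); overlaps "
          f"z={res['num_overlaps'].z:.2f} (p_greater={res['num_overlaps'].p_greater:.4g})")
with open(args.outdir / "mark_association.json", "wt") as fh:
    json.dump(assoc, fh, indent=1)

signal = read_bedgraph(args.study / "signal.bedgraph")
focal = [genes.by_id[g] for g in down]
pm = signal_profile_matrix(signal, [g.interval for g in focal],
                           strands=[g.strand for g in focal])
profile_matrix_frame(pm, [g.gene_id for g in focal]).to_csv(
    args.outdir / "signal_profile_down_genes.tsv", sep="\t")
print(f"signal profile: {pm.matrix.shape[0]} down-gene rows, "
      f"peak mean signal {pm.mean_profile.max():.2f} near the TSS-proximal bins")
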