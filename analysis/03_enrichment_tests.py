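#!/usr/bin/env python
"""Test DEG over/under-representation among top-scored genes and measure
chromatin-state enrichment of genes and their interaction anchors.

The gene-set test resamples |candidate| genes from the background
(all genes) 10,000 times and compares the overlap with the top-5%
cumulative-score set against the observed overlap.  State enrichment
uses the 6-state segmentation with the column-min/max colour scaling.
Outputs to results/enrichment/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from chromlink.genome import read_bedpe_contacts, read_gene_table
from chromlink.interactions import associate_contacts, corresponding_anchors, score_table, top_fraction_genes
from chromlink.pipeline import load_layout
from chromlink.states import StateSegmentation, enrichment_matrix
from chromlink.stats import child_seed, geneset_top_overlap_test

ap = argparse.ArgumentParser()
ap.add_argument("--study", type=Path, default=Path("results/study_default"))
ap.add_argument("--outdir", type=Path, default=Path("results/enrichment"))
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

layout = load_layout(args.study / "layout.json")
genes = read_gene_table(args.study / "genes.tsv")
deg = pd.read_csv(args.study / "deg.tsv", sep="\t", comment="#")
contacts = read_bedpe_contacts(args.study / "contacts.bedpe", q_threshold=0.01,
                               bin_size=layout.bin_size, on_bad_width="keep")
profiles = associate_contacts(genes, contacts)
ranking = top_fraction_genes(score_table(profiles), 0.05)
top = sorted(ranking.top_set)
background = sorted(genes.ids())
up = sorted(deg.loc[deg["class"] == "up", "gene_id"])
down = sorted(deg.loc[deg["class"] == "down", "gene_id"])

out = {}
for name, cand in (("up", up), ("down", down)):
    r = geneset_top_overlap_test(cand, background, top, n_perm=10_000,
                                 seed=child_seed(args.seed, f"geneset:{name}"))
    out[name] = r.to_dict()
    tail = "p_greater" if name == "up" else "p_less"
    print(f"{name}-genes vs top 5%: observed overlap {r.observed:.0f} "
          f"(null mean {out[name]['null_mean']:.1f}), z={r.z:.2f}, "
          f"{tail}={getattr(r, tail):.4g}")
with open(args.outdir / "geneset_permutation.json", "wt") as fh:
    json.dump(out, fh, indent=1)

seg = StateSegmentation.from_bed(args.study / "states.bed")
sets = {
    "Up_genes": [genes.by_id[g].interval for g in up],
    "Up_anchors": corresponding_anchors(up, profiles),
    "Down_genes": [genes.by_id[g].interval for g in down],
    "Down_anchors": corresponding_anchors(down, profiles),
}
mat = enrichment_matrix(sets, seg, layout)
mat.raw.to_csv(args.outdir / "state_enrichment_raw.tsv", sep="\t")
mat.scaled.to_csv(args.outdir / "state_enrichment_scaled.tsv", sep="\t")
print("\nstate fold enrichment (raw):")
print(mat.raw.round(2).to_string())
print(f"\nEnh column peaks on {mat.scaled['Enh'].idxmax()}, "
      f"Tss column peaks on {mat.scaled['Tss'].idxmax()}")
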