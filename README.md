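# chromlink

Integrative analysis linking differential gene expression in brain
tissue to 3D chromatin interactions, DNA methylation, and repressive
histone marks.

## The problem

Environmental exposures during development can leave lasting
transcriptional signatures in the adult brain.  A recurring observation
in such studies is that up- and downregulated genes sit in different
regulatory regimes: upregulated genes receive many strong, long-range
chromatin contacts from distal enhancer-like regions, while
downregulated genes engage mostly in short-range promoter–promoter
contacts and accumulate repressive marks (DNA hypermethylation,
H3K27me3) at their promoters, with H3K9me3 loss appearing instead on the
distal anchors of upregulated genes.  `chromlink` implements the
statistical machinery needed to make those statements quantitative,
starting from standard tabular inputs (a gene table, significant Hi-C
contacts, DEG calls, differential mark sites, a chromatin-state
segmentation, a signal track).

## The statistics at its core

* **Cumulative interaction score.**  A significant contact (two 20-kb
  bins with contact q < 0.01) is *gene-associated* when either anchor
  overlaps the gene body; the other bin is the gene's *corresponding
  anchor*.  Each gene g gets a score
  S(g) = Σ<sub>c ∈ contacts(g)</sub> O/E(c)
  (alternatives: contact count, Σ −log₁₀ q).  Genes are ranked by S and
  the top 5% form the high-interaction set.
* **Gene-set resampling enrichment.**  For a DEG set of size k, draw k
  genes from the background (all detected genes) without replacement
  10,000 times, record the overlap with the top-5% set, and report both
  empirical tails with a +1 pseudo-count:
  p = (1 + #{null ≥ obs}) / (1 + n_perm).
* **Region permutation tests** (regioneR-style, 600 resamplings):
  observed meanDistance or numOverlaps between a query region set (e.g.
  anchors interacting with upregulated genes' promoters) and a reference
  set (e.g. H3K9me3-loss loci), against a null built by resampling
  |query| regions from a background universe (anchors of all gene
  promoters); z = (obs − mean)/sd plus both empirical tails.
* **Supporting tests.**  Dunn's post-hoc rank test (midranks, tie
  correction, Bonferroni) for score distributions across DEG classes;
  two-sample KS for contact-distance ECDFs; one-sided Fisher's exact
  test for gene-set overlaps.
* **Chromatin-state enrichment.**  Fold enrichment of a region set in
  state s is (region bp in s / region bp) ÷ (genome bp in s / genome
  bp); the heatmap scaling subtracts each column's minimum and divides
  by the column maximum.
* **Signal profiles.**  deeptools-style scale-regions matrices (body
  rescaled to 5 kb, 3-kb flanks, 50-bp bins, skip-zeros) computed as
  exact coverage-weighted integrals of a bedGraph step function.

Because the original sequencing-scale inputs are not reproducible at
desk scale, the package ships a first-class synthetic-study generator
(`chromlink.simulate`) that emits every input format with the regulatory
structure above planted at configurable strength, plus a ground-truth
record, so the whole pipeline is validated end to end by recovery tests.

## Worked example

```sh
python analysis/01_simulate.py --seed 1     # default + null synthetic studies
python analysis/02_interaction_scores.py    # scores, Dunn, ECDF/KS, promoter %
python analysis/03_enrichment_tests.py      # top-5% resampling, state matrix
python analysis/04_mark_integration.py      # annotation, mark-anchor tests
python analysis/05_null_control.py          # negative control
```

On the seed-1 default study this prints (abridged):

```
class mean scores: {'up_genes': 33.38, 'down_genes': 10.86, 'non_genes': 15.41}
contact distance KS (up vs down): D=0.161, p=9.37e-09
promoter-associated contact proportion: down 86.7%, up 23.4%
up-genes vs top 5%: observed overlap 45 (null mean 5.0), z=18.81, p_greater=9.999e-05
down-genes vs top 5%: observed overlap 1 (null mean 5.0), z=-1.87, p_less=0.0366
Enh column peaks on Up_anchors, Tss column peaks on Down_anchors
k9loss_vs_up_anchors: mean distance z=-6.08 (p_less=0.001664); overlaps z=18.89 (p_greater=0.001664)
hyperdms_vs_down_anchors: mean distance z=-6.06 (p_less=0.001664); overlaps z=34.91 (p_greater=0.001664)
```

Reading this: upregulated genes are 9× over-represented in the top-5%
interaction-score set while downregulated genes are depleted; ~87% of
downregulated genes' contacts target promoters versus ~23% for
upregulated genes; up-gene anchors sit in the enhancer state while
down-gene anchors sit in the Tss state; H3K9me3-loss loci cluster on
up-gene anchors and hypermethylated sites on down-gene promoter anchors
(both far closer and more overlapping than resampled anchor sets).  The
null-parameterized study (`05_null_control.py`) shows none of these
effects (all p > 0.05, no promoter-association contrast).

The same flow is scriptable via the CLI (`chromlink simulate / score /
perm-test / anchors / state-enrich / annotate / associate / profile /
run`), with `chromlink run --config study.yaml` executing the full
pipeline from a YAML config.

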