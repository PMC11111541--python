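# Methods

## Coordinate conventions

All coordinates are 0-based, half-open (BED convention), everywhere in
the package.  Readers convert 1-based closed input only under an
explicit `one_based=True` flag, and a configurable prefix rule
normalizes chromosome-name dialects ("chr1" vs "1") at the boundary.
Abutting intervals do not overlap; overlap requires at least 1 bp by
default.  The strand-aware TSS is `start` on the plus strand and
`end − 1` on the minus strand.  Promoters default to TSS −2,000/+500 bp
(strand-aware, clipped at chromosome bounds); the window is a parameter
because no single definition is canonical.

## Gene interaction profiles

A contact is a pair of equal-width bins (default 20 kb) with a q-value
and an observed/expected (O/E) intensity; only contacts with q below
the load-time threshold (default 0.01) enter the analysis.  A contact is
assigned to every gene that either anchor overlaps by ≥ 1 bp; the other
bin of each gene-overlapping anchor is recorded as the gene's
corresponding anchor.  When both anchors overlap the same gene the
contact counts once toward the score and both bins enter the anchor set
— counting it twice would double its intensity for no extra evidence.
One contact may legitimately serve several genes.

The cumulative interaction score defaults to the sum of O/E over a
gene's contacts (`sum_oe`).  Because "cumulative score of contact
intensity" admits other readings, `count` and `sum_neglog_q` are
implemented and selectable; all results in this repository use
`sum_oe`.  Genes without contacts score 0 and participate in the
ranking.  Ranking is descending by score with lexicographic gene-id
tie-breaks (deterministic), and the top fraction (default 5%) contains
ceil(fraction · N) genes.

The promoter-association proportion of a gene set is the fraction of
its (gene, contact) assignments whose partner anchor overlaps any
promoter window; only the partner (regulatory-target) side is tested,
not the gene-side anchor.  Contact distances are |start₁ − start₂| of
the bin starts; inter-chromosomal contacts are retained for overlap and
anchor logic but excluded from distance ECDFs and means.

## Resampling statistics

Empirical p-values always use the +1 pseudo-count,
p = (1 + #{null as-or-more extreme}) / (1 + n_perm), so p ∈ (0, 1]; both
tails are always reported and the caller chooses the interpretation.
Every test derives its own child seed from (study seed, test label) via
a `SeedSequence`, so results are bit-for-bit reproducible and changing
one test never perturbs another.

* **Gene-set resampling (n_perm = 10,000 by default).**  Draws are
  without replacement from the background universe, matching the
  finite-universe overlap question; the null mean therefore equals the
  hypergeometric mean, which the test suite checks.
* **Region permutation (n_perm = 600 by default).**  The default
  randomization resamples |query| regions without replacement from a
  declared universe (e.g. anchors of all gene promoters), inheriting
  the universe's coordinates; a width-preserving uniform random
  placement scheme is available as an alternative.  Both statistics
  (meanDistance to the nearest reference region, with overlapping
  regions at distance 0 and off-chromosome queries excluded from the
  mean; numOverlaps as the count of query regions touching any
  reference region) decompose per region, so the implementation
  precomputes each universe region's contribution once and permutes
  indices — identical to the naive loop (verified against exhaustive
  subset enumeration on a small case) but orders of magnitude faster.
* **Dunn's test.**  Joint midranks over all groups; pairwise
  z = (R̄ᵢ − R̄ⱼ) / √((N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/nᵢ + 1/nⱼ));
  two-sided normal p-values, Bonferroni-adjusted by default.  The
  Kruskal–Wallis omnibus gate is not enforced.
* **Fisher overlap and KS** delegate to scipy (`fisher_exact`,
  one-sided enrichment; `ks_2samp`, asymptotic p).

"Anchors interacting with the promoters of gene set X" means: partner
bins of contacts whose gene-side anchor overlaps the promoter window of
an X gene, deduplicated by coordinate.  The association tests use these
as the query, the differential mark intervals as the reference, and the
promoter anchors of *all* genes as the resampling universe.

## Chromatin-state enrichment

The segmentation is a non-overlapping labeled cover of the assayed
genome (ChromHMM dense-BED dialect; state training itself is out of
scope).  Fold enrichment of a region set in state s is
(region bp in s / total region bp) ÷ (genome bp in s / genome bp);
region sets may overlap internally and each row is computed
independently, so enrichment is invariant to splitting a region into
adjacent pieces.  The default heatmap scaling is
v′ = (v − column min) / column max.  Note this is *not* the
conventional min-max: the scaled column maximum is 1 − min/max rather
than exactly 1.  The conventional (v − min)/(max − min) is available via
`scale="column_range"`; neither is asserted to be the "right" one, and
the raw matrix is always written alongside.

## Genome annotation of mark sites

Sites are assigned exactly one category by priority
promoter > exon > intron > intergenic, with intergenic sites at least
`desert_min_gap` (default 100 kb, configurable — "gene desert" has no
standard numeric definition) from the nearest gene labeled gene_desert.
When no exon model is supplied the whole gene body counts as exonic
(the synthetic studies do not model exon structure, so their intron
fraction is 0 by construction).  Overlap uses the full site interval;
distance-to-TSS summaries use the site midpoint.

## Signal profile matrices

The scale-regions matrix follows the deeptools computeMatrix
conventions used for repressive-mark heatmaps: region bodies rescaled
to 5,000 bp, 3,000-bp unscaled flanks, 50-bp bins, all-zero rows
dropped (`skipZeros`).  Bin values are exact coverage-weighted means of
the bedGraph step function, computed from its cumulative integral, so a
row's total mass reproduces the analytic integral of the signal over
the region ± flanks; positions outside any bedGraph interval (including
beyond the chromosome start) contribute 0.  Regions shorter than one
bin are integrated with fractional bin edges and produce a warning.
Minus-strand rows are reversed.

## The synthetic-study generator

The generator emulates the *statistical* structure of an integrative
brain-epigenomics study, not its sequence content.  Default scale:
4 chromosomes × 50 Mb, 20-kb bins, 2,000 non-overlapping genes (length
log-normal, median 20 kb), 5% up- and 5% downregulated — large enough
for stable permutation nulls, small enough that generation plus the
full analysis takes seconds.

Planted structure (all strengths configurable):

* Per-gene contact counts are Poisson with class means λ_up = 10,
  λ_down = 3, λ_non = 4; O/E is log-normal with class medians 3.0 /
  1.5 / 2.0 (σ_log = 0.4).  The gene-side anchor is the TSS bin.
* With class probability 0.8 (down) / 0.2 (up) / 0.5 (non) the partner
  is the TSS bin of another gene (downregulated genes prefer partners
  within 2 Mb — promoter–promoter hubs among neighbors); otherwise the
  partner is a non-genic bin (overlapping no promoter or gene body)
  at a distance drawn from a class law: heavy-tailed log-normal
  (median 2 Mb, σ_log = 1.0) for up, uniform ≤ 400 kb for down,
  log-normal median 500 kb for non.  Upregulated genes are excluded
  from the promoter hubs — they are enhancer-driven by construction.
* Emitted contact q-values are U(0, 0.01): significance modeling is the
  upstream caller's job, and every emitted contact passes the screen.
* Marks: 400 hypermethylated DMSs (70% planted inside partner anchors
  of downregulated genes, single-bp), 60 H3K27me3-gain peaks (80%
  centred on downregulated TSSs, 2 kb), 150 H3K9me3-loss loci (70%
  inside upregulated genes' distal anchors, 2 kb); hypomethylated,
  K27-loss and K9-gain sites are uniform background.  Effects and
  q-values follow the conventions of the corresponding differential
  callers (q < 0.05, |methylation difference| > 10%).
* Segmentation: promoters → Tss, up-gene distal anchors → Enh, gene
  bodies → Tx, 5%/3% random bins → EnhLo/ReprPC, remainder → Quies,
  flattened by that priority into a non-overlapping cover.
* Signal: a sparse bedGraph of TSS-centred bumps, 3× amplitude on
  downregulated genes.

Each artifact type (genes, labels, contacts, marks, segmentation,
signal, DEG table) draws from its own RNG stream derived from the
master seed, so changing mark parameters never moves contact
placement; the same (params, seed) pair yields byte-identical files.
`StudyParams.null()` keeps all marginal rates but equalizes the class
parameters and zeroes the planting probabilities; it is the negative
control for every detection.

What the generator does **not** emulate: polymer-physics contact decay,
ICE normalization, read-level noise, exon structure, realistic mark
peak shapes, or inter-chromosomal contacts.  Passing recovery tests
therefore demonstrates that the statistics detect the planted relational
structure at realistic effect sizes — not that they would behave
identically on sequencing data with its correlated noise.

## Numerical and design choices

* Permutation z uses the sample SD (ddof = 1); a degenerate null with
  observed equal to the null value gives z = 0 and p = 1.
* The gene-resampling fast path draws k-subsets as the k smallest of
  i.i.d. uniforms per permutation, chunked to bound memory.
* Fisher's test never receives inconsistent tables (validated); −log₁₀ p
  is clamped at 300 for plotting.
* `top_fraction_genes` with all-equal scores returns the
  lexicographically smallest ids — an arbitrary but deterministic rule.
* Pipeline outputs carry a header with package version, seed, and a
  SHA-256 config hash; reruns with the same config and seed are
  identical up to that metadata.

## Problem sizes used in validation

The validation suite uses a 200-gene universe for the
resampling-vs-hypergeometric comparison (10,000 draws), 100 random 2×2
tables for the Fisher oracle, 50 random tied 3-group datasets for the
Dunn oracle, 500 replicates × 600 permutations for type-I control of
the region test, the default 2,000-gene synthetic study (seed 1, with
its null twin) for recovery, and 100 random regions over a 400-segment
step signal for the profile-matrix mass check.  These sizes give stable
Monte-Carlo error margins (3 SE bands) while keeping the whole suite in
the tens of seconds.

## Known limitations

* The depletion test for downregulated genes is intrinsically
  low-powered at 100 genes × 5% top set (expected overlap 5): single
  studies can land near the 0.05 boundary.
* `meanDistance` nulls inherit the universe's spatial distribution;
  if the universe is spatially biased relative to the reference, the z
  score reflects that bias as well as the focal association (same
  caveat as any resampling-from-background design).
* The column-min/max heatmap scaling is implemented as specified for
  compatibility, although the conventional min-max is arguably what a
  reader expects of a 0–1 colour key.
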