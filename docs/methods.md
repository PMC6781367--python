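# Methods

`methylaging` re-implements, as a tested and reusable pipeline, a paired
methylome–transcriptome analysis of brain aging: whole-genome bisulfite
CpG counts and RNA-seq counts from the same young and old animals of both
sexes are combined to (i) call age-related differentially methylated
regions (age-DMRs), (ii) call age-related differentially expressed genes
(age-DEGs) per sex, (iii) test where age-DMRs fall in the genome,
(iv) quantify how methylation — both its age-related change and its
absolute level in early life — relates to expression change, and
(v) predict the *direction* of a gene's expression change from its
early-life epigenetic state.  A seeded synthetic-study generator stands in
for raw sequencing data and provides ground truth for recovery testing.

## DMR calling

Each chromosome is tiled into consecutive, non-overlapping 500-bp windows
anchored at coordinate 0.  Filters are applied in a fixed order:

1. **Site filter** — a cytosine is kept only if its mean per-sample
   coverage is ≥ 5× in *both* age groups (`min_site_cov`).
2. **Window CpG filter** — windows with fewer than 10 surviving CpGs are
   dropped (`min_cpg`).
3. **Window coverage filter** — a window is dropped if any retained CpG
   has pooled (replicate-summed) coverage below 3× in either group
   (`min_cpg_cov`).  Whether this 3×-per-CpG rule should be applied to
   pooled or per-sample coverage is genuinely open; pooled is the default
   because pooling is what the test consumes, and the threshold is a
   parameter.

Counts are then pooled within each age group (summed over replicates and
CpGs) into one 2×2 table per window and tested with a **two-sided Fisher
exact test**, defined as the sum of probabilities of all tables with the
observed margins whose probability does not exceed the observed table's.
The implementation enumerates the conditional distribution with exact
integer binomial weights, so tie comparisons are integer comparisons —
there is no floating-point tie epsilon, and the only rounding is the final
big-integer division.  Benjamini–Hochberg adjustment is applied jointly
over all tested windows of a contrast, and windows with q < 0.05 are
DMRs, labelled hyper-/hypomethylated by the sign of
Δ = m_old − m_young.  Per-sex contrasts are separate invocations on the
sex's samples; because the tiling is fixed, "common DMRs" are windows with
identical coordinates significant in both sexes.

At the emulated sequencing depth (5× mean coverage, n = 3/group) the site
filter removes roughly half of all CpGs, so only CpG-dense windows are
testable and planted-DMR sensitivity is approximately 0.5; at 10×
coverage, where the recovery properties are asserted, sensitivity is
essentially 1.  This coverage-limited behaviour is a property of the
filter cascade itself, not of the implementation.

## Differential expression

Raw counts are normalized with **median-of-ratios** size factors
(reference: per-gene geometric mean across samples, genes containing any
zero excluded) and transformed with `log2(count/s_j + 1)` as a
variance-stabilizing stand-in.  Per gene, ordinary least squares of the
transformed value on age + sex provides the age-main-effect screen
(p < 0.05); screened genes proceed to per-sex young-vs-old pairwise
contrasts.  The default contrast is the **Conover–Iman rank comparison**
(joint ranking, mean-rank difference scaled by the pooled rank variance
with the Kruskal–Wallis correction, t distribution with N − 2 df); a
Welch-t contrast is a config switch.  Pairing a linear-model screen with a
rank post-hoc is unusual but intentional here; both interpretations are
available and agree on strong effects.  BH adjustment is applied within
sex over the contrast p-values.  A gene is an age-DEG iff q < 0.05 **and**
FC > 1.25 or FC < 1/1.25, where FC is the ratio of normalized (not
transformed) group means, with a 0.5 pseudocount only when a group mean is
exactly zero.  Cross-sex overlap is summarized by shared up/down counts
and a 2×2 chi-square test of independence without continuity correction.

All p-values and fold changes are invariant to scaling every sample's
counts by a common constant, and the pipeline is deterministic (no hidden
randomness in this stage).

## Genomic-feature enrichment

Feature classes are derived with the field's standard definitions:
promoters are ±1 kb around the strand-aware TSS (split into
island-containing and island-free by ≥ 1 bp overlap), gene bodies span
TSS→TES, CpG **shores** are the 2-kb flanks of merged islands and
**shelves** the 2-kb flanks beyond the shores, all clipped to chromosome
bounds; islands are merged before flank derivation and flanks are
subtracted so island/shore/shelf are pairwise disjoint.  Representation
of DMR windows in a class is tested with the exact hypergeometric
distribution — `P(X ≥ k)` for over- and `P(X ≤ k)` for
under-representation — conditioning on the universe of windows that
passed filters and were actually tested, not on all genomic tiles.
Overlap is ≥ 1 bp; a window overlapping several classes counts once per
class (classes are tested marginally).  Gene-set over-representation of
DMR-containing genes uses the same hypergeometric machinery over a GMT
file, with BH q across sets.

## Methylation–expression association

Region methylation is the **pooled-count fraction** ΣM/Σ(M+U) over a
region's cytosines (equivalently the coverage-weighted mean of site
fractions) — robust at low coverage, where an unweighted site mean is
noisy.  Regions are the gene body (TSS→TES) and the promoter (±1 kb TSS);
the CpG/CH context of sites entering the pool is selectable.  A binned
profile export (100 equal gene-body bins plus fixed-width 2-kb flanks,
strand-oriented) supports heatmap-style visualization.

Analyses on top of the summaries:

* **DMR Δ vs log2FC** by region class (promoter, gene body, enhancer),
  separately for DEGs and non-DEGs; genes with several DMRs use the mean
  Δ (order-invariant).  Enhancer intervals are assigned to the gene with
  the nearest TSS within 100 kb (configurable) — a standard, explicit
  heuristic.
* **Early-life level vs log2FC**: Pearson r among DEGs and among
  non-DEGs, a degree-2 (configurable) polynomial trend with a pointwise
  95% band, and a Kruskal–Wallis contrast of methylation across
  up/unchanged/down genes with Conover pairwise follow-ups.
* **Resampling null**: the Pearson r of random gene sets (default 500
  genes × 10,000 draws, drawn without replacement within a draw), with
  the empirical percentile of an observed r.  Note the null centres on the
  *pool-level* correlation, not on zero: if planted DEGs make up a
  noticeable fraction of the pool, the null mean is pulled toward the
  pool r — exactly the behaviour that makes the DEG-set r stand out only
  when it exceeds what membership in the pool already implies.
* **Gene-set screen**: per-set r between methylation and log2FC for sets
  with ≥ 50 genes after intersection; sets are flagged at r ≥ 0.4
  (signed positive by default; an absolute-value switch exists because
  "met or exceeded the cutoff" can be read either way).

## Direction-of-change prediction

Per labelled (up/down) gene the feature vector holds mean gene-body and
promoter methylation in young and old, gene size (bp), baseline
normalized young expression, and per-mark **breadth of coverage** —
summed width of the mark's peaks overlapping the gene body divided by
gene length, with peaks merged per mark first so breadth ∈ [0, 1].

A PCA on standardized features reports variance fractions and the
correlation of each component's scores with each original feature;
component signs are fixed deterministically (PC1 correlates positively
with young gene-body methylation when present, other components by their
largest-magnitude loading).  Constant features are dropped with a
warning.

The classifier is a random forest (500 trees, √p features per split,
bootstrap) on a stratified 70/30 split.  Reported are validation accuracy,
ROC AUC of the up-class probability, and two importance measures:
**mean decrease accuracy** as per-tree permutation of a feature within
each tree's out-of-bag samples, averaged over trees, and **mean decrease
Gini** as the forest's impurity-based importance.  The OOB per-tree
estimator was chosen over whole-forest permutation on the held-out set
deliberately: the methylation features are strongly correlated, and
whole-forest permutation zeroes out redundant features (the rest of the
forest covers for the permuted one), which makes importance ranks
unstable; the per-tree OOB form — the classic random-forest definition —
remains informative because individual trees see only feature subsets.

## Synthetic-study generator

The generator emulates the statistical structure the analysis assumes,
not sequencing reads:

* **Genome**: 2 chromosomes × 5 Mb, 2,000 non-overlapping genes
  (1.5–4 kb), 100,000 cytosines: ~150 CpG islands (dense clusters, ≥ 10
  CpGs each by construction, anchored half at TSSs, half intergenic),
  dense 500-bp clusters reserved for planted DMRs, and uniform background.
  All stages complete in seconds to minutes at this scale.
* **Methylation levels**: one latent axis per gene drives promoter
  (centre 0.72, sd 0.16) and gene-body (centre 0.75) levels, giving the
  positive promoter/body correlation seen in real methylomes; islands sit
  at 0.20.  The intergenic background level is then *solved
  algebraically* so the pooled genome-wide CpG mean equals the 74% target
  at any parameter setting.  Because genes cover about half of this
  desk-scale genome, the region centres are higher than a naive reading
  of real brain methylomes would suggest; they are a calibration
  compromise that preserves the genome-wide mean and the between-gene
  variance the association analyses need.
* **Counts**: per-site methylation is Beta-distributed around the
  regional mean (dispersion 0.02) and *shared across animals within a
  group*; replicate variability is binomial read sampling at
  Poisson-distributed coverage (mean 5×).  This matters: the pooled
  Fisher test conditions on totals, and is calibrated exactly when
  replicates are binomial draws from a common site mean.  Per-animal site
  means would make pooling anti-conservative — that regime is a known
  limitation of pooled exact testing and of this generator's null.
  Expression is negative-binomial (dispersion 0.05) around lognormal base
  means with uniform per-sample library factors.
* **Planted effects**: 20 DMR windows shift the old-group mean by ±0.3
  from a mid-range baseline (clipped with a warning if a site leaves
  [0, 1]); 200 DEGs scale the old-group mean by 2^±1 in both sexes.  With
  probability ρ (`association_strength`) a planted DEG is up if its young
  promoter methylation exceeds the planted-set median and down otherwise,
  else its direction is random.  ρ defaults to 0.8, calibrated so the
  emulated study reproduces the association strength the real study
  observed (DEG-set r ≈ 0.45–0.55, classifier accuracy ≈ 0.79–0.90).
  Half of the planted DMRs are placed inside planted-DEG gene bodies with
  Δ opposing the host gene's direction with probability 0.7, so the
  anti-correlation between age-related methylation change and expression
  change in gene bodies is also represented.  Peak tracks draw a gene's
  breadth around a linear function of promoter methylation (negative
  slope for H3K27ac/H3K4me3-like marks, positive for
  H3K27me3/H3K9me3-like marks, noise sd 0.12).
* **Determinism**: every stage derives its generator from the global seed
  plus a stage tag, so stages are order-independent and byte-reproducible;
  a fraction of sites can be labelled CH (default 0) and written through
  the cytosine-report dialect.

What the generator does **not** emulate — and what passing recovery tests
therefore cannot certify on real data: read-level artefacts (bisulfite
conversion error, mapping bias, PCR duplicates), between-animal biological
variance in site methylation, linked methylation along reads, realistic
CpG density profiles and chromatin domain structure, cell-type mixture,
and CH-context biology beyond a context label.

## Numerical and design choices

* Internal coordinates are 0-based half-open everywhere; only the
  coverage-file dialects are 1-based, converted at the I/O boundary.  The
  %methylation column of coverage files is ignored; counts are the source
  of truth.  Symmetric CpG dyads are *not* merged across strands — sites
  on either strand are distinct.
* BH is the plain step-up with NaN passthrough for untested hypotheses
  (screened-out genes), ties resolved by stable sort; q is clipped at 1.
* Fisher p-values for degenerate margins (an empty row or column) are 1;
  windows with zero total coverage in a group are excluded with a reason
  code rather than tested.
* Zero-variance genes are skipped by the OLS screen and reported
  non-significant with a reason.
* Pearson correlations require ≥ 3 pairs and non-constant inputs;
  degenerate cases are flagged, not silently dropped.
* The stratified RF split re-derives from the seed; both labels are
  required in train and validation.
* Pipeline outputs are written with a fixed float format and hashed into
  a manifest; logs echo parameters but never wall-clock times, so two
  runs with one config and seed are byte-identical.
* Sizes used by the test-suite recovery checks are the generator defaults
  (2×5 Mb, 100k CpGs) for calibration/recovery properties, a ~1 Mb /
  15–20k CpG study for pipeline-level and unit tests, and 1,000 draws
  (rather than the 10,000 the analysis functions default to) for the
  resampling-null calibration checks; these are the package's desk-scale
  test conditions.

## Known limitations

* The pooled Fisher window test ignores between-replicate biological
  variance (see above); beta-binomial regression callers are out of scope.
* The log2 shifted transform is a stand-in for a variance-stabilizing
  transformation, adequate for rank-based contrasts and parameter
  recovery, not numerically identical to VST.
* No dispersion shrinkage or empirical-Bayes moderation in the expression
  model; power at n = 6/group comes from the planted effect size.
* Enhancer→gene assignment by nearest TSS is a heuristic; no
  chromatin-contact information is used.
* The gene-set screen and enrichment use marginal tests; gene-gene
  correlation within sets is not modelled.
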