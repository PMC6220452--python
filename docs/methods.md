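# Methods

`epiregseek` re-implements, as a tested pipeline, the computational core of a
two-condition shoot-apex methylome/transcriptome study in cucumber: calling
methylcytosines and differentially methylated cytosines and regions from
whole-genome bisulfite sequencing (WGBS) count data, associating them with
genes and transposable elements, screening for negative promoter-methylation
/ expression couplings ("epiregulation"), and decomposing the variance of a
femaleness phenotype (PNPF) over a multi-year germplasm survey and a
temperature x photoperiod incubator experiment.  Because the original
genome-scale inputs are sequencing archives, every stage is validated on a
synthetic-data generator with planted, recoverable truth.

## Site-level methylome model

A cytosine is observed as a pair (methylated reads, total reads).  Contexts
are CG, CHG and CHH (H = A, T or C), read 5'->3' on the cytosine's own
strand; motifs truncated by a chromosome end or containing an ambiguous base
are unclassified and excluded.  CG sites stay strand-specific: a symmetric
CpG pair is two sites, which keeps intersection keys between condition
comparisons unambiguous.

**mC calling.** Bisulfite conversion is imperfect: an unmethylated cytosine
yields a methylated read with probability `1 - conversion_rate`.  A site is
a methylcytosine when its methylated-read count reaches the smallest `k`
with `P(X >= k | n = coverage, p = 1 - conversion_rate) < alpha` (upper
binomial tail; default alpha 0.05, configurable — the threshold is the
anticipated count under the non-conversion null).  Uncovered sites are "no
call", never 0.

**DmC calling.** For one site in two conditions, a two-sided Fisher exact
test on the 2x2 count table, combined with an absolute methylation-level
difference filter: DmC iff `p < 0.05` and `|ML_B - ML_A| >= 0.20`.  The
delta is read as an absolute difference, not a relative change (relative
change is unstable near 0).  Deliberately, **no multiple-testing correction**
is applied to DmC p-values: the raw-p + delta rule is the procedure being
reproduced.  Sites with coverage below a floor (default 4 reads in either
sample, overridable down to 1) are excluded: Fisher's test is powerless on
tiny counts.  The null calibration check (10^4 paired sites with identical
true MLs) shows a DmC rate of ~2%, below the nominal 5% thanks to the delta
filter.

## DMR calling (seed and extend)

Over the same-context cytosines of a chromosome in coordinate order (both
strands pooled; a strand-separated mode exists):

1. **Seed**: a window of 5 adjacent sites in which at least 4 are DmCs of
   one direction and the two-sided Wilcoxon rank-sum test comparing the 5
   per-site MLs of condition A against those of condition B has `p < 0.05`.
   An opposite-direction DmC in the window vetoes the seed by default
   (flag-controlled, since "at least four of five" leaves the fifth site's
   status open).
2. **Extension**: sites are appended one at a time in increasing coordinate
   order while the next site is a DmC of the seed's direction and the
   rank-sum test over the enlarged region stays below 0.05; extension stops
   at the first failure.  A lenient mode also admits non-significant sites
   whose ML difference has the seed's sign.
3. **Merging and trimming**: overlapping same-direction candidates are
   merged (delta recomputed over the union).  Candidate boundaries are then
   trimmed to the outermost concordant DmC members: a 4-of-5 seed window at
   a block edge can otherwise incorporate a single signal-free site an
   arbitrary distance away (the next same-context cytosine), inflating the
   span without adding evidence.
4. **Filters**: regions shorter than 50 bp or with `|mean ML difference| <
   0.1` are discarded; both thresholds are inclusive on the keep side
   (the discard rule applies to regions strictly smaller).

The rank-sum p-value uses the exact permutation distribution of the pooled
midranks whenever both groups have <= 8 observations (ties handled by
midranks), and the normal approximation with tie correction beyond.  Exact
enumeration at these sizes costs at most C(16,8) = 12,870 relabelings.

## Feature association

A genic region is the gene body +- 2 kb, clipped to the chromosome; a TE
contributes only its body.  A query point (a DmC, or the midpoint of a DMR
or DET) may lie in several features; its category is one of gene-only,
TE-only, TE&gene, none.  A genic query is assigned to the single nearest
gene, with distance measured to the gene body (0 inside; ties broken toward
the smaller gene id; a TSS-distance mode exists).  DMR-TE association uses
full-interval overlap while DMR-gene positioning uses the midpoint — the two
rules are intentionally different.  Shared-DmC analysis intersects keyed
(chrom, pos, strand, context) sets across condition comparisons and reports
per-comparison deltas, the sign-concordance fraction and all Venn-region
counts.  Chromosomal distributions are counted in half-open windows of 2 Mb.

## Differential expression and the epiregulation screen

**DEGs.** The divergence probability of a gene for an ordered condition
pair is an empirical, self-contained statistic: the gene's signal point is
(|log2 ratio|, |difference|) of pseudocount-stabilised condition mean FPKM
(pseudocount 1), the noise cloud collects the same statistic for every
within-condition replicate pair of every gene, and the probability is the
fraction of noise points strictly dominated in both coordinates.  A DEG
requires probability >= 0.8 and fold-change >= 2.  The scheme approximates
the named nonparametric package's statistic; externally computed
probabilities can be injected (`call_degs(..., probabilities=...)`).  Its
known limitation is inherited from the dominance construction: genes far
down the expression range cannot dominate the |difference| axis and are
undetectable regardless of fold change.

**Per-gene ANOVA.** Two-way fixed-effects ANOVA of log2(FPKM+1) on the
balanced 2x2x3 temperature x photoperiod design, classical sums of squares
(all SS types coincide on balanced data), every term tested against the
residual.  Verified cell-by-cell against `statsmodels` `anova_lm`.

**DETs.** TEs overlapping any protein-coding gene body are discarded first.
Counts are pooled across replicates per condition and each TE's condition-B
count is tested against Binomial(total, L_B/(L_A+L_B)) with library-size
offsets, Benjamini-Hochberg adjusted; adjusted p < 0.05 survive.  The
conditional binomial assumes Poisson-level replicate noise; overdispersed
data will inflate the DET list, so the output is exploratory, in keeping
with the screen's role.

**Epiregulation screen.** Only CG/CHG DMRs are eligible.  A DMR associates
with a gene when its midpoint lies inside a CDS interval or within 2 kb
(inclusive) of the TSS or TES.  The association is joined to that gene's
DEG record for the same ordered condition pair; the sign is positive when
the methylation and expression directions agree (hyper & up, hypo & down)
and negative otherwise.  Positive associations are discarded; the distinct
genes of the negative events form the putative epiregulated list.

## Phenotype statistics

PNPF is the proportion of the first 25 main-stem nodes bearing a pistillate
flower.  Sex types: subandroecy (PNPF < 0.25), normal monoecy (0.25 <=
PNPF < 0.75), gynoecy/subgynoecy (>= 0.75); both thresholds lower-inclusive.
All parametric tests run on arcsine-square-root transformed values,
`asin(sqrt(p))`, mapping [0,1] onto [0, pi/2].

Per-accession seasonal change uses Welch's t-test on transformed values (a
pooled-variance flag exists); accessions with fewer than two observations a
season are flagged not testable.  The germplasm summary counts significant
decreases and relative decreases > 40%, and fits autumn means on spring
means.

Both ANOVA layouts are balanced fixed-effects decompositions computed
directly from group means — Season nested in Year for the field survey
(sources Year, Variety, Season(Year), Year x Variety, Season(Year) x
Variety, Residual) and the full three-way Variety x Temperature x
Photoperiod for the incubator experiment.  F uses the residual mean square
for every term; `**` marks p < 0.01.  `finalize_table` reproduces the
printed-table arithmetic (MS = SS/df, TSS% = 100 SS / total SS) at a chosen
printed precision and accepts an explicit total SS, since a printed total
need not equal the component sum when the printed components are rounded.
Mixed-model denominators and REML variance components are out of scope.

## Synthetic data generator

The generator defines the study conditions under which every recovery test
runs.  All randomness flows from one seed (`numpy` `SeedSequence` spawning
per stage); identical configurations are byte-identical.

* **Genome**: random sequence, default 2 chromosomes x 250 kb, GC fraction
  0.37 (cucumber-like AT-rich).
* **Annotation**: 50 non-overlapping gene models (body 1.5-4 kb, 1-3 CDS
  intervals, random strand) and 80 TEs (0.3-2 kb) with class mix LTR 0.40,
  unknown 0.25, LINE 0.15, DNA 0.15, SINE 0.05 (LTR-dominant, as in the
  organism's TE complement); a configurable fraction of TEs (default 0.2)
  is placed overlapping genic regions.
* **Methylome**: baselines ML 0.60 (CG), 0.35 (CHG), 0.08 (CHH); coverage
  per site negative binomial with mean 30 and shape 10 (overdispersion is
  the WGBS norm); conversion rate 0.99, so unmethylated cytosines read
  methylated at rate 0.01.  Planted DMRs (5 CG, 5 CHG, 8 CHH by default)
  occupy runs of >= 8 same-context sites spanning 100-500 bp, placed clear
  of genic regions with a 500 bp margin, delta 0.8 centred in [0,1]
  (ML 0.1 vs 0.9); the generator re-draws on placement conflicts and errors
  out after bounded retries.  Condition B differs from A only inside
  planted regions.
* **Expression**: four incubator conditions x 3 replicates; baseline means
  log-normal around 200 counts; replicate noise negative binomial with
  shape 80 (CV ~ 11% — pooled-tissue triplicates under controlled
  conditions cluster tightly).  Planted DEGs (25 free at |log2FC| 3, plus
  the coupling genes at |log2FC| 2) apply their fold in the treatment
  condition and are floored at a baseline of 600 counts: differential calls
  presume expressed genes.  FPKM is normalised by the design depth rather
  than the realized column sum — with a few dozen genes the column sum is
  dominated by the planted folds themselves and the compositional bias
  would distort every unplanted gene's apparent fold.  Five planted DETs
  (8-fold) sit on TEs free of gene overlap so the screen's discard rule
  does not mask them.
* **Couplings**: 8 negative (promoter CG/CHG DMR hypermethylated in the
  treatment, delta 0.5, gene down 4-fold) and 4 positive controls (same
  promoter DMR, gene up) — the positives must never reach the putative
  epiregulated list.
* **Phenotype**: balanced years x seasons x varieties x replicates design
  generated on the arcsine scale as a sum of independent variance-component
  draws (year, variety, season-within-year, the two printed interactions,
  residual) around a grand mean of 0.70, then back-transformed; default
  variances echo a variety-dominant, season-second hierarchy.  The
  incubator helper generates the balanced 4 x 2 x 2 x 3 layout.

What the generator does **not** emulate: read-level artifacts (M-bias,
mapping bias, duplicate reads), linked methylation along reads, genuine
genomic sequence composition (repeats, isochores), TE families with
internal structure, library-composition effects on FPKM, unbalanced or
missing phenotype cells.  Passing recovery tests therefore demonstrate the
statistical machinery is correct under the declared noise model, not that
the pipeline is robust to alignment-level artifacts.

## Problem sizes and numerical choices

The default simulation (two 250 kb chromosomes, ~185k cytosine sites per
condition, 50 genes, 80 TEs, 30 planted DMRs) runs the full pipeline in
well under a minute; the field-design phenotype used for the df checks is
the survey-scale 5 x 2 x 359 x 3 = 10,770 observations.  Fisher tests are
run only on sites passing the coverage floor and delta filter (the others
cannot be DmCs).  Balanced-ANOVA additivity holds to < 1e-10 relative
error; SS agree with `statsmodels` to 1e-8 relative.  Thresholds follow
the reproduced procedure's stated values throughout (mC alpha 0.05 is the
one value the procedure leaves unstated; it is configurable).  Degenerate
inputs (zero coverage, empty contexts, zero total SS, singleton seasonal
groups) return explicit "undefined" markers or raise configuration errors
rather than silently coercing to zero.
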