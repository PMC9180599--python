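# Methods

This note documents the models, defaults and design choices behind each
component, what the synthetic-data generator does and does not emulate, and
the numerical conventions that matter for reproducing results.

## Robust rank aggregation

Each dataset contributes a full ranked gene list sorted by log2 fold change
(descending for the up-regulated aggregation, ascending for down; ties are
broken by gene id so orderings are reproducible). The normalised rank of
the gene at 1-based position `i` in a universe of `N` genes is `i/N`; a
universe gene absent from a list receives `r = 1.0`, which is the
conservative choice (an unquantified gene contributes no evidence). An
alternative that scores a gene only over the lists containing it is
available via `drop_absent=True`.

The score is the minimum over `k` of the Beta(k, n−k+1) CDF evaluated at
the k-th smallest rank — equivalently a binomial tail — and the per-gene
p-value multiplies by the Bonferroni factor `n` (the number of lists),
clipped at 1. BH adjustment across genes is available as an alternative
(`correction="bh_over_genes"`), but the Bonferroni form is the method's
native correction and the default. The summary effect size per gene is the
median log2FC over the datasets where the gene is present; medians resist
the dataset-specific batch shifts that motivate the method. The robust
call applies both thresholds jointly (corrected p strictly below the
cutoff, |median log2FC| strictly above), with defaults p < 0.01 and
|log2FC| > 1.

Aggregating full lists (not just each dataset's significant genes) is the
default; per-dataset pre-thresholded lists can be passed in unchanged,
since absent genes are handled by the `r = 1` rule.

## Differential expression stand-in

The per-dataset DE step is intentionally minimal and fully documented:
median-of-ratios size factors (geometric-mean reference over genes with all
positive counts, falling back to library-size factors when none exists),
`log2(normalised count + 0.5)`, a per-gene two-sided Welch t-test, and BH
adjustment. Genes with all-zero counts are excluded from testing and from
the BH denominator. Genes constant in both groups give p = 1 (no evidence
against the null). Positive log2FC means higher in the differentiated (MT)
state. Externally produced DEG tables (DESeq2, limma, …) can be substituted
anywhere a table is consumed; no attempt is made to reproduce shrinkage or
voom weights, which is why recovery results on synthetic data are stated
for this test, not for those packages.

## Interval engine

Intervals are 0-based half-open. Merging joins overlapping *and* bookended
(end == start) intervals, matching the common merge semantics, and is
idempotent. Overlap between two peaks requires ≥ 1 shared bp by default;
`min_bp` raises that bar against a single partner peak (not against the
merged union). `overlap_fraction(a, b)` is peak-count based: the share of
a's peaks with a qualifying partner in b. The co-binding partition
classifies a's peaks by b-overlap and adds the b-only class, so
|A+B+| + |A+B−| = |a| always holds. Multi-set union overlap merges the
other sets first; because merging changes peak bookkeeping, per-subset
counts can differ slightly from pairwise counts, which is expected.
Bulk queries run against the merged partner set with binary search;
per-peak minimum-overlap queries use per-chromosome interval trees.

## Motif scanning and dependence calls

PWMs are 4×W count matrices with a pseudocount (default 0.25) and a
background distribution (default uniform); scores are log2 odds. A scan
covers both strands and reports windows scoring at least `threshold_frac`
(default 0.8) of the maximum attainable score; windows containing N score
−∞. The default threshold is a generic stringency choice for sharp
consensus-like motifs, not a calibration against any external scanner.

The dependence classifier consumes the per-class motif fractions of a TF
pair. Margins (all configurable): a flat profile — all fractions within
0.05 — is "undetermined"; TF B is called dependent on A when B's own-motif
fraction in co-bound sites is < 0.25 of A's there and B's own-motif
fraction in B-only sites is low (< 0.25) or within 2× of A's fraction
there; "independent" requires each TF's own-motif fraction to vary by
< 25 % (relative) between its co-bound and solo classes. These margins
separate the two canonical patterns (stable 0.72/0.75 and 0.45/0.44 own-
motif fractions → independent; 0.08 vs 0.67 co-bound depletion →
dependent) with a wide buffer; intermediate patterns return
"undetermined" rather than a forced call.

## Permutation enrichment

The moving set (by default the annotation — super-enhancer-like or
conserved-element-like intervals) is re-placed uniformly at random with
lengths preserved; genome-wide placement picks each interval's chromosome
with probability proportional to its number of valid start positions. The
observed statistic is the number of annotation intervals overlapping ≥ 1
target interval; fold = observed / mean(null) over `n_perm` permutations
(default 1000). The empirical p uses the add-one convention
`(1 + #{null ≥ obs}) / (n_perm + 1)` so it is never 0. Per-permutation
folds `obs/null_i` feed the two-sample Welch comparison between two
enrichment runs; permutations with zero null overlaps use a 0.5
denominator and a warning fires when more than 5 % of permutations are
affected (a sign the problem is too sparse for this statistic). All
permutations are drawn from one seeded generator, so results are
bit-reproducible given (inputs, seed, n_perm). No GC- or
mappability-matched background is attempted.

## Regulatory domains and enrichment

Basal domains are 5 kb upstream / 1 kb downstream of the TSS,
strand-aware; strand is required here because the asymmetry is meaningless
without it. Extension proceeds per side to the nearest of the adjacent
gene's basal boundary, 1 Mb beyond the own basal boundary, or the
chromosome end, and never enters another gene's basal domain (overlapping
basal domains yield zero extension on the facing sides). A literal
"stop at the first binding site" variant is available via
`stop_at_sites`. A site annotates every gene whose extended domain it
overlaps, so neighbouring genes can share a site. Term enrichment is the
hypergeometric upper tail over genes with BH adjustment; terms are
intersected with the universe and zero-overlap terms are skipped. PPI
ranking is plain distinct-neighbour degree, descending, ties broken by
node id.

## Coverage metaprofiles

Tracks are bedGraph; rows must be non-overlapping (unsorted input is
sorted with a notice, overlap is an error). Queries are exact integrals
from cumulative sums, so results are invariant to how a constant region is
split into rows and uncovered positions contribute zero. Anchor windows
are `[anchor − flank, anchor + flank)` binned into `n_bins` equal bins
(bin width `2·flank // n_bins`, remainder bp assigned to the last bin);
minus-strand rows are reversed so bins run 5'→3'. Anchors whose window
leaves the chromosome are dropped and counted, not clipped.

## Synthetic data

The generator's defaults are the study conditions the tests assume:

- **Expression**: 9 datasets, 3 replicates per state (≈ 21 samples per
  state in total), 2000 genes, 100 planted up- and 100 down-regulated
  genes at |log2FC| = 2 (the scale of the |FC| > 2 calling threshold),
  negative-binomial counts with gene-wise log-normal means
  (`lognormal(4, 1)`, mean count ≈ 90) and shared dispersion 0.1
  (`var = μ + 0.1 μ²`). The batch effect is a per-dataset, per-gene
  N(0, 0.5) shift in log2 units — the simplest mechanism that makes
  single-dataset DEG calls inconsistent while leaving the planted ranks
  informative, which is the regime the aggregation method exists for.
  The planted effect is split symmetrically (±effect/2) so the MT/MB mean
  ratio is exactly 2^effect before noise.
- **Genome**: three chromosomes of 10/8/6 Mb; genes placed
  length-proportionally with uniform TSSs and random strands.
- **Peaks**: widths uniform on [200, 600] bp; pairwise overlap designs are
  realised constructively (the designed share of a query set is placed to
  overlap a random reference peak, the rest is placed rejecting reference
  overlap), so realised fractions hit the design up to rounding.
- **Annotations**: SE-like sets default to 800 intervals of 8 kb — large,
  numerous intervals in rough proportion to real super-enhancer sets
  relative to the scaled-down genome, which keeps the expected null
  overlap count high enough (~100+) for the fold estimate to concentrate.
  A planted fold F is achieved by placing a fraction
  `q = p(F−1)/(1−p)` of intervals onto the target (where p is the exact
  uniform-placement hit probability) and the rest uniformly; F is capped
  at `1/p`, the saturation bound.
- **Sequences**: uniform ACGT background; exactly `round(rate · n)` peaks
  carry one consensus insertion at a random offset and strand.
- **Coverage**: Gaussian bumps (SD 600 bp) on a 50 bp genome-aligned bin
  grid with Poisson sampling at depth 50; high-set amplitude is chosen so
  the expected centre signal ratio equals the requested factor.

What the generator does **not** emulate: read-level noise and alignment
artefacts, GC/mappability bias, correlated gene-gene expression,
peak-width/signal correlation, or realistic motif backgrounds. Passing
tests therefore demonstrate that the statistics recover the signals they
are designed for under their own model assumptions — not that any
particular biological dataset would yield a given number.

## Problem sizes and numerical conventions

Validation runs use 2000-gene, 9-dataset expression simulations, 500-peak
target sets, 800-interval annotations with 1000 permutations, and Monte
Carlo oracles of 10⁵ draws — sizes chosen so every check is statistically
informative while the whole suite runs in about a minute. Thresholds are
strict inequalities throughout; sorting is always stable with documented
tie-breaks (gene id, node id, chromosome then start); per-stage pipeline
seeds derive from SHA-256 of (global seed, stage name) so stages are
independently reproducible.

## Known limitations

- The DE stand-in is t-based and loses power at 2–3 replicates relative to
  NB-likelihood methods; it is the documented default, not a DESeq2 clone.
- `overlap_fraction` is peak-count, not base-pair, semantics.
- The fold-enrichment null assumes placement anywhere in the genome is
  equally plausible; no exclusion of unmappable or gapped regions unless
  an exclusion BED is supplied.
- Beta order-statistic p-values are exact under independent uniform ranks;
  correlated datasets (shared samples, re-processed cohorts) violate that
  and make the corrected p anti-conservative.
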