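# Methods

This note documents the models and procedures discbind implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Synthetic tiling-array experiments

The generator emulates a two-tissue × two-factor ChIP-chip study on
tiling arrays.

**Genome and genes.** Chromosomes are i.i.d. sequences with a configurable
GC fraction (default 0.43, fly-euchromatin-like). Genes (2–8 kb, random
strand) are placed on disjoint 10 kb slots so bodies never overlap; each
gene has a single TSS (its strand-oriented start).

**Binding sites.** Each (tissue, factor) condition receives a configured
number of site centers. Distinct loci are drawn on a 2 kb grid, so any
two distinct loci are ≥ 2 kb apart and the 500 bp center-distance overlap
rule is unambiguous: planted-shared pairs coincide exactly, everything
else can never spuriously overlap. Per factor, `round(tissue_shared_fraction · n)`
loci are reused verbatim in both tissues (with unequal per-tissue counts,
n is the smaller count, so the fraction is exact on the smaller tissue's
side). Per tissue, `round(factor_cobound_fraction · min(n_Ubx, n_Hth))`
loci carry both factors. The two constraints interact; the number of loci
co-bound in both tissues is fixed at the independence expectation
`round(shared · cobound · min n)` and the remaining co-bound loci come
from tissue-specific pools. Infeasible combinations raise rather than
silently renormalizing.

**Signal.** A bound site contributes a Gaussian bump of amplitude
`peak_amplitude` (default 2.0 log₂ units, i.e. ~4-fold IP enrichment) and
spatial sd `peak_sd_bp` (default 250 bp). The bump sd approximates
chromatin fragments averaging ~500 bp: a fragment-pileup profile is
roughly triangular at that scale, and a Gaussian with sd at half the
fragment size matches its width while staying smooth and
differentiable-free to parameterize. Probes sit every 36 bp (a dense
commercial tiling-array pitch). IP probe values are the bump sum plus
N(0, `noise_sd`) (default 0.4 log₂ units — a mid-range per-probe array
noise); input tracks are noise only. One IP/input pair per condition by
default; the replicate count is configurable but replicate-aware variance
modeling is deliberately out of scope.

**Motifs.** With probability `hit_probability` per site, a word sampled
from the PWM's column frequencies (random strand) overwrites the genome
at center + N(0, `positional_sd_bp`). Edits that would cross a chromosome
end are skipped and counted.

**Expression.** Genes whose TSS lies within 2 kb of a site bound in the
"haltere" condition receive a ±`effect_log2` shift (sign random per
gene); the second contrast repeats the sign with probability 0.9, giving
the two planted-effect columns a correlation near 0.8. All genes get
independent N(0, noise) per contrast. The responsive-gene list is the
planted-effect list; calling differential expression from raw intensities
is out of scope.

**What the generator does not emulate:** probe GC/affinity bias, dye
effects, spatial array artifacts, copy-number structure, overlapping
genes and isoform diversity, and binding-strength heterogeneity (all
planted sites share one amplitude). Passing recovery tests therefore
demonstrates the *pipeline's* correctness on data obeying its stated
model, not robustness to array-specific systematics.

## Peak calling and the consensus rule

Two simplified caller analogues preserve the interfaces the consensus
rule needs; they are not reimplementations of any published array caller.

**Rank-sum caller.** At each probe, a one-sided Wilcoxon rank-sum test
compares IP vs input probe values within a centered 500 bp bandwidth
window. The p-value is exact: with fixed window size the tie-free null
distribution of the Mann–Whitney U statistic is computed once by the
classical partition-counting recurrence and applied to all windows in one
vectorized lookup (ties get midranks; the p is then conservative to at
most one lattice step). Edge probes whose window holds fewer than
`min_probes` per arm are recorded at p = 1 and flagged. Regions are
maximal runs of probes passing the top-5% p-value threshold, with runs
separated by ≤ 300 bp merged and runs of < 4 probes dropped.

**Trimmed-mean caller.** Log-ratios (IP − input) are standardized over
the whole track; the per-probe score is the 10%-per-tail trimmed mean
over the same 500 bp window. FDR is estimated from a sign-flip null —
the identical computation on the negated log-ratios — as
`#null ≥ s / #observed ≥ s`, clipped to [0, 1]. Scores are converted to
q-values (the minimum FDR over rejection regions containing the score)
and thresholded at 5%.

**Consensus.** A rank-sum region is kept iff the distance from its center
to the nearest trimmed-mean region's interval is ≤ 250 bp (0 inside;
boundary inclusive). Coordinates and center of a kept peak come from the
rank-sum region. Two consequences are load-bearing: consensus output is
always a subset of the rank-sum list, and on null tracks the consensus
count is bounded by both single-caller counts.

**Region centers.** The center is the best-scoring probe of the run. When
the statistic saturates (the exact rank-sum p has a combinatorial floor
of 1/C(2w, w), reached across a plateau of probes on strong peaks), ties
are broken at the plateau midpoint (lower-middle index). A
lowest-coordinate tie-break was considered and rejected: on saturated
peaks it lands ~1 kb left of the summit, which both misplaces centers and
empties the consensus under the 250 bp rule.

## Set algebra and co-occupancy

Overlap is a strict center-distance predicate (< 500 bp, same
chromosome). Because one region can partner several on the other side,
all shared counts and percents are reported from each set's own side; the
overview table makes the asymmetry explicit instead of forcing a
symmetric count. Duplicate centers within a set are collapsed first.
Percentages are rounded half away from zero to one decimal.

For co-occupancy significance, the universe N is the number of distinct
regions after single-linkage merging of *all* input sets' centers under
the 500 bp rule — merging the union rather than summing per-set counts
prevents N inflation when the same event appears in several sets. Per-set
counts and pairwise overlaps are counted on that merged-region universe,
which guarantees a consistent 2×2 table (k ≤ min(nᵢ, nⱼ) ≤ N). The test
is the one-sided hypergeometric upper tail (equivalently one-sided
Fisher); −log10 p is capped at 300 before average-linkage/Euclidean
clustering (the conventional reading where no linkage is prescribed).

Windowed track correlation uses non-overlapping 500 bp window means
(step = window; a sliding step is configurable but the default avoids
autocorrelated windows). Conservation per peak is the coverage-weighted
mean over [center − 500, center + 500); fully uncovered windows are NaN
and excluded from the one-sided rank-sum class comparison.

## Target assignment

Each peak is assigned the gene with minimal |TSS − center| on either
strand; the sign is then oriented by the assigned gene's strand (negative
= upstream). Equidistant TSSs resolve to the lower coordinate, then the
lexically smaller gene id — deterministic and order-independent. One TSS
per gene is used; isoform-level starts are out of scope. Location classes
use precedence promoter (1 kb strand-oriented upstream window) > genic
(inside any gene body) > intergenic. Both peak-level and deduplicated
gene-level target counts are reported, since "number of target genes" is
ambiguous between the two.

## Motif scanning and cutoff selection

PWMs are column-frequency matrices (pseudocount 0.5 per base when built
from counts; uniform background by default, genome-composition background
optional), scored as Σ log₂(fᵢ(base)/bg(base)) in bits, taking the
per-position maximum of forward and reverse-complement scores; ambiguous
bases contribute 0. The operational reading of a "relative entropy
cutoff" is a log-odds threshold in bits on the grid {3.0, 3.5, …,
max attainable}. For each cutoff, positional bias is the one-sided
rank-sum p of hit |offsets| against an equal number of uniformly placed
pseudo-hits (seeded); the winning cutoff minimizes p, lower cutoff on
ties. The grid size is reported alongside the p so users can
Bonferroni-adjust for the multiple cutoffs tested; reported p-values are
otherwise uncorrected. The headline per-motif number is the percent of
peaks with ≥ 1 hit within ±250 bp of the center, which is monotone
non-increasing in the cutoff.

## Expression and term enrichment

Binding × expression linkage is the hypergeometric upper tail of the
bound ∩ responsive overlap in a universe defaulting to all genes in the
expression table. Responsive genes are clustered on the two contrast
columns (average linkage, Euclidean), cut into five flat clusters by
default, with binding indicators carried as annotations only. Term
enrichment is a plain per-term hypergeometric test with Bonferroni
correction over the tested terms; a single "top pick" term is reported
iff its corrected p < 0.001. This reproduces the structure of
functional-annotation summaries without fuzzy clustering of terms.

## Problem sizes and determinism

The validation suites run at desk scale, chosen to keep each suite in the
single-digit-minute range while leaving no estimator starved: planted
shared-fraction recovery uses 300 peaks/condition on 2 × 4 Mb genomes
across 20 seeds per fraction; motif recovery uses 200 peaks with 1 kb
windows and 10 column-shuffled decoys; null calibration uses 50 seeds of
200 kb site-free tracks; the end-to-end demo uses 2 × 1.5 Mb with 235
planted sites. All randomness flows from explicit seeds through
`numpy.random.Generator`; equal (config, seed) reruns produce
byte-identical output bundles (no timestamps enter any artifact).

## Known limitations

* The caller analogues ignore probe affinity, quantile normalization and
  replicate variance; they are fit for validating the consensus rule and
  downstream algebra, not for reanalyzing real arrays.
* The exact rank-sum p saturates at 1/C(2w, w) for the default window;
  peaks stronger than that floor are indistinguishable by p, which is why
  center placement uses the plateau midpoint.
* Percent arithmetic reproduces published-table conventions only to the
  stated rounding (one decimal, half away from zero).
* The sign-flip FDR null assumes symmetric noise; strongly skewed
  log-ratio noise would bias the FDR estimate.
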