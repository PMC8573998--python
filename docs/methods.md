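# Methods

## Quantification model

The unit of analysis is the annotated intron: the gap between consecutive
exons of a transcript. Introns identical in (contig, start, end, strand)
across transcripts are collapsed into one catalog unit that retains all
parent gene/transcript ids; introns sharing only one boundary are distinct
units. Coordinates are 0-based half-open internally and 1-based inclusive
in all text output.

For each intron and sample the package estimates the retained fraction

    IRratio = A_i / (A_i + A_e),  defined as 0 when A_i + A_e = 0.

**Intronic abundance A_i** summarizes per-base aligned depth over the
intron body. Only alignment match/mismatch bases count; deletions and
skips contribute nothing. Bases overlapped by exons of *other* transcripts
or by user-supplied low-mappability intervals are masked out, because
coverage there cannot be attributed to retention of this intron. Short-read
mode takes the median over unmasked positions (robust to local pile-ups);
long-read mode takes the minimum, a deliberately stringent choice that
sends partial-coverage artifacts — e.g. an alternative 3' end whose reads
never traverse the full intron — to exactly 0.

**Exonic abundance A_e** summarizes splice evidence. A read supports a
boundary when one of its alignment gaps (CIGAR `N`) has an endpoint within
`jitter` nucleotides of the annotated position; SpliceLeft/SpliceRight
count donor/acceptor support separately and ExactSplice counts reads with
a single gap matching both. Each read contributes at most once per tally.
Short-read mode uses max(SpliceLeft, SpliceRight) with jitter 0; long-read
mode uses ExactSplice with jitter 3, absorbing the boundary imprecision of
nanopore basecalling. Jitter applies independently at each endpoint and to
all three tallies.

**Warnings** flag unreliable ratios without removing them:

| warning | rule | default |
|---|---|---|
| LowCover | A_i + A_e below a minimum informative depth | 10 |
| MinorIsoform (long mode) | ExactSplice < f × max(SpliceLeft, SpliceRight), max > 0 | f = 0.5 |
| NoEvaluablePositions | every intronic base masked | — |

The LowCover depth of 10 and MinorIsoform fraction 0.5 are package
defaults, both surfaced as flags: 10 separates the depth-4 regime where a
ratio of two tiny numbers is noise from the ≥25 depths required of
training labels, and 0.5 flags loci where under half the boundary-spliced
reads use the annotated boundary pair. Classification of an intron as
retained uses `IRratio >= threshold` (0.05 or 0.10 conventionally) and an
empty warning set.

Reads are counted regardless of MAPQ by default (`--mapq` raises the
floor); directional libraries can restrict counting to reads on the
intron's strand (`--stranded forward|reverse`).

## CNN false-positive filter

Candidates are short-read records with IRratio > 0.05 and no warnings.
Each locus is rendered as a 3 × 160 array: 30 exonic bases per flank at
native resolution around the intron body linearly resampled to 100
columns (masked bases zeroed first), a splice-evidence channel
(SpliceLeft / ExactSplice / SpliceRight over the corresponding segments),
and fixed junction markers. Channels are max-normalized; all-zero
channels stay zero, so scale information enters only through ratios
between segments.

Labels come from long-read quantification of the same introns: true-IR
requires no warnings, depth ≥ 25 and IRratio > 0.1; false-IR requires
depth ≥ 50 and IRratio = 0 — the asymmetric depth demands reflect that
asserting absence needs more evidence than asserting presence. Both depth
rules are minimums. A label is kept only when directional and
non-directional long-read runs agree. Because labeled false positives are
scarce, the negative class is augmented with long-read-negative introns
outside the candidate set whose short-read IRratio still exceeds 0.01;
any residual imbalance is resolved by downsampling the majority class.

The classifier is a 1-D CNN — conv(8 filters, kernel 5) → ReLU → maxpool 2
→ conv(16, 5) → ReLU → maxpool 2 → dense(32) → sigmoid — trained with
Adam (lr 1e-3, batch 32, ≤ 40 epochs, early stopping on a 15% validation
split with patience 8, binary cross-entropy). It is implemented directly
on numpy with hand-written backpropagation: the arrays are tiny, training
sets number in the hundreds, and this keeps training exactly reproducible
from its seed with no deep-learning dependency. Performance is assessed
by stratified 10-fold cross-validation reporting per-fold sensitivity,
specificity and balanced accuracy = (TPR + TNR)/2; the shipped model is
retrained on all data. Candidates scoring below the cutoff (default 0.5)
are removed from the call set.

## Differential intron retention

Introns with LowCover in any sample are removed by default, and at least
one sample must reach IRratio ≥ 0.05. Two tests are offered; both report
BH-adjusted p-values across tested introns.

**glm (default).** Per intron, each sample contributes two counts — the
intronic abundance and max(SpliceLeft, SpliceRight) — modeled with a
negative-binomial GLM `log mu = b0 + b1·cond + b2·ctype + b3·cond:ctype`.
The interaction b3 is the log fold change of the intron:exon count ratio,
i.e. of retention; it is tested with a Wald z statistic, the convention
of count-based differential tools. Dispersion is estimated per intron by
a method-of-moments step on Poisson-fit residuals, clipped to
[1e-8, 10] (a moment estimator cannot fail, where small-sample ML often
does). An intron with an all-zero condition × count-type cell is flagged
untestable and excluded from BH. On 3-vs-3 null simulations with 500
introns this test makes zero BH-0.05 calls; a small-sample t reference
was considered and discarded because it removed all power at depth ~10
without changing null behavior. Default calls: padj < 0.05 and |fold
change| > 1.5.

**ratio.** The effect is the difference of group-mean IRratios. Its
significance comes from an empirical null of between-replicate
|delta IRratio| values within conditions, pooled across introns and
binned by mean exon abundance (decile edges, bins merged below 100 null
values), with the add-one p-value (1 + #{null ≥ |obs|}) / (1 + n).
Because replicate variability is largest exactly where coverage is low,
this test is conservative on shallow data — the count-based glm calls
more low-coverage events, the expected and tested directional contrast
between the two. Default calls: padj < 0.05 and |delta| ≥ 0.1.

With more than two conditions, all unordered pairwise comparisons are
produced.

## Synthetic data

The generator plants known truth and is byte-reproducible from its seed.
Gene models are regularly spaced multi-exon genes (exons 100 nt, introns
200 nt) on one synthetic contig, each intron carrying a planted retention
fraction drawn from {0, 0.1, 0.3, 0.5} unless specified — the levels and
depths (100–200×) used throughout the tests. Read simulation works at
alignment level: each of `depth` molecule copies decides retention per
intron by its planted probability and is tiled with back-to-back reads at
a random phase, so every copy adds exactly one unit of coverage and
spliced junctions appear as `N` gaps (short mode, 75 nt reads) or as one
full-length read per molecule (long mode). Long-read endpoints receive
independent uniform ±`endpoint_noise` displacements; an alternative-3'-end
scenario emits molecules running from the transcript start to 60% of an
intron's length. Group simulation operates at count level: per replicate,
a lognormal(0, 0.1) library factor, Poisson depth, logit-normal
(sigma 0.2) biological noise on the retention fraction and binomial
intronic counts — producing overdispersed data directly as result tables
for the differential tests.

What the generator does **not** emulate: sequence content and mapping
error, non-uniform (fragmentation- or GC-biased) coverage, overlapping
gene architecture beyond the planted antisense exon, transcript-level
expression heterogeneity, or nanopore-specific truncation profiles.
Passing tests therefore demonstrate the estimators' correctness and
calibration under the stated noise models, not performance on real
libraries; the CNN's cross-validated accuracy on synthetic arrays shows
the architecture and training loop work, not that the shipped filter
transfers to a real genome browser's pathologies.

## Numerical choices and degenerate inputs

* IRratio printed at 3 decimals, round-half-even; tables round-trip
  losslessly because readers recompute the ratio from the abundance
  columns.
* Median of an even count of positions is the mean of the middle two.
* A fully masked intron quantifies as A_i = 0 with NoEvaluablePositions;
  an empty alignment file yields all-zero records flagged LowCover.
* Ties at the CNN decision boundary (p = cutoff) are kept.
* Identical groups give delta = 0 and p = 1 in the ratio test, and b3 = 0
  (p ≈ 1) or an untestable flag in the glm.
* BH adjustment delegates to the standard step-up implementation and is
  verified against a direct oracle in the tests.

## Problem sizes

Test and demonstration runs use 3–8 genes × 2–3 introns at depths
100–300 for alignment-level checks, 200-example balanced sets for CNN
cross-validation, and 300–500 introns × 3 replicates per condition for
differential power (50–60 planted events at delta 0.3) and null
calibration — sizes at which every stochastic acceptance check is
comfortably stable across seeds.

## Known limitations

* Strand handling inspects single-read orientation only; paired-end
  dUTP-style protocols are treated read-by-read.
* The glm's per-intron moment dispersion does not share information
  across introns (no shrinkage), which costs power at n = 2–3 per group
  relative to empirical-Bayes methods.
* The empirical-null binning assumes enough introns to fill abundance
  bins; with very few introns all nulls pool into one bin.
* No bedGraph/browser-track output and no database integration.
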