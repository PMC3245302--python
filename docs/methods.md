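# Methods

This note documents the models behind `dermadup`: what the generators
emulate, how each detection stage is defined, the defaults and why, and
what the synthetic setting does and does not show about real data.

## Locus model

The locus is a standalone random DNA sequence spanning
10,218,000–11,935,000 (1,717,001 bp) in the coordinate frame of a toy
chromosome 20 (13.9 Mb), so that published-style coordinates are directly
testable. It tiles into five blocks `L | D1 | S | D2 | R` with
`D1 = 10,717,294–10,846,232` (128,939 bp) and `D2 = 11,262,904–11,435,256`
(172,353 bp), separated by a 416,671 bp single-copy spacer.

The mutant haplotype is assembled from a signed block arrangement; the
default, `L +D1 −D2 +D1 +S +D2 R`, places an inverted copy of D2 between
two direct copies of D1, preserves all four wild-type boundary adjacencies,
and creates two novel junctions (D1 5′ × D2 5′, and D1 3′ × D2 3′). Junction
microhomology is *planted in the reference sequence*: the terminal k bases
of the two joined ends are made reverse-complementary (default k = 1 at the
3′ junction — a single shared C — and k = 0 at the 5′ junction) and the
bases immediately beyond are forced to mismatch, so the planted
microhomology is exact rather than merely a lower bound. The allele drops
the k shared bases once at each junction: no other gain or loss of
sequence.

## SNP-array generator

Markers sit on a regular 6 kb grid (≈ 287 markers over the locus),
emulating the density of a 60K genotyping chip on a small genome. Log R
ratios are additive-shift Gaussians: mean 0 for the diploid state, +0.30
for four copies and +0.15 for three, noise SD 0.15. The shift values model
the compression real arrays show (observed per-segment means around
0.12–0.27 for carriers) rather than the ideal log2(CN/2) = 1; recovering a
planted +0.30 shift at noise 0.15 is therefore the realistic version of the
problem, not an easy caricature. Five markers inside D1 are paralogous
sequence variants: every carrier is called heterozygous there (the
duplicate copies carry fixed differences that the array reads as
constitutive heterozygosity); two of them are fixed-reference in wild-type
birds, three segregate. Homozygous carriers additionally share an identical
genotype vector across the PSV block (identity by descent of the mutant
haplotype), with forced discordance at the flanking markers so the planted
shared interval is unambiguous. Genotype-call-level simulation only — raw
intensities, B-allele frequencies and cluster files are out of scope.

## Circular binary segmentation

CBS treats each segment as a circle and scores every arc (i, j] with
|t| = |mean(arc) − mean(rest)| / (σ·√(1/k + 1/(n−k))), σ the segment SD.
Because σ and the total sum are permutation-invariant, the maximal-|t| arc
coincides with the least-squares two-level changepoint fit — which is what
the exhaustive oracle in the test-suite computes independently. The maximal
arc is accepted when its marker-permutation p-value is ≤ α, then
sub-segments are scanned recursively. Defaults follow the segmentation
software used for array CNV calling: 10,000 permutations, α = 0.01, RNG
seed 12,345,678; results are deterministic for a fixed seed. The
permutation loop stops early only when significance is already impossible,
which cannot change any accepted changepoint. No "undo" pruning is applied,
so noisy profiles may over-segment within a true segment; the group-wise
scan, not CBS, is the boundary-precision instrument.

## Group-wise scan and boundary convention

`delta(m) = mean(LRR carriers) − mean(LRR controls)`, simple unweighted
means. Regions are maximal runs of ≥ 5 consecutive markers with
`delta > 0.1` (ties count as below); qualifying runs separated by fewer
than 5 below-threshold markers merge. Boundaries are reported as the
midpoint between the outermost in-run marker and its nearest out-of-run
neighbour — this halves the worst-case quantization error relative to
reporting the outermost marker, and the convention is recorded in the
output so either can be tested. With 6 kb spacing and correct marker
classification the boundary error is bounded by half the spacing (~3 kb);
at the default noise (delta SD = 0.15·√(2/12) ≈ 0.061) an adjacent outside
marker exceeds the 0.1 threshold with probability ≈ 5%, so occasional
seeds show errors of one extra marker spacing. That is a property of the
stated study conditions, not of the implementation.

## Mate-pair pools

Pairs are drawn uniformly along the template — the toy chromosome with the
locus embedded, or the same chromosome carrying the rearranged allele —
with Normal(2500, 300) fragment lengths and 50 bp reads (a mate-pair-era
read length; configurable). Reads are emitted directly as mapped reference
coordinates through the allele's span map; a read straddling a junction is
treated as unmappable and its pair dropped. Mapping distance is the
absolute difference of the two reads' leftmost coordinates; a
forward/reverse pair that maps to the same strand is strand-discordant
(inversion signature). Depth is 30× of the template per library, and
windowed depth is normalized per million *chromosome-wide* mapped reads —
the analogue of genome-wide library-size normalization. This matters: the
carrier template is 17.6% longer than the wild-type locus, so normalizing
within the locus alone would depress the in-duplication fold change to
about 1.70; against the chromosome-wide total the expected value is
2 × 13.9/14.2 ≈ 1.96, and the single-copy spacer stays at ≈ 0.98. The
candidate-SV rule is applied per 1 kb window (pairs assigned by leftmost
read, counted once, windows with < 10 pairs skipped — a guard for the 20%
fraction against tiny denominators): aberrant pairs exceed
mean + 6 SD of the library's distances; if ≥ 20% of the window's pairs are
aberrant, the subset within ±1500 bp of their median distance supports a
candidate, whose partner window holds the median far-read position.
Sequencing error, base qualities, alignment ambiguity and mappability are
not modelled, so candidate support counts are cleaner than real libraries
would give; positions, spans and strand signatures are the meaningful
outputs.

Junction refinement finds the maximal reference-matching prefix and suffix
of a junction-spanning fragment (exact seed-and-extend from an anchor
k-mer, default 30 bp, on both strands) and reports their overlap on the
fragment as the microhomology (a gap instead is an untemplated insertion).
Exact and deterministic; verified against a character-by-character oracle
on random junctions.

## Rearrangement logic

An architecture is a signed sequence of blocks between fixed flanks; its
orientation-aware adjacency multiset (k internal blocks ⇒ k + 1
adjacencies) is exactly what outward-facing junction PCR observes.
Enumeration is exhaustive over orderings × orientations of the copy
multiset {D1:2, S:1, D2:2} (≤ 960 candidates), keeping arrangements whose
adjacency multiset equals the evidence exactly, de-duplicated under
identical-copy relabeling and whole-arrangement reverse complement. The
copy multiset itself comes from the qPCR/read-depth evidence (duplications
at 2×, spacer single-copy). Six adjacencies — four wild-type boundaries
plus the 5′/5′ and 3′/3′ junctions — admit exactly three architectures.

Crossover between one copy of a block in each parent yields the two
reciprocal concatenations when the paired copies have equal orientation,
or chromosomal loss (dicentric/acentric products) when inverted. The
dominant-allele phenotype rule is: mutant phenotype iff the chromosome
carries either novel junction. An observed recombinant that inherited the
control parent left of a crossover in the spacer and the carrier parent to
its right, with wild-type phenotype and normal copy number, eliminates the
inverted-spacer architecture (loss) and the architecture whose recombinant
retains both duplications — leaving one.

In-silico PCR places primer sites at configured offsets from block ends on
the block-level linearization and emits a product for every convergent
site pair within range; the default diagnostic assays are placed to give
wild-type products of 379 bp (D1 5′ boundary) and 302 bp (D2 3′ boundary)
and junction products of 280 bp and 159 bp. Because carriers retain all
wild-type boundaries, heterozygote and homozygote band patterns are
identical — copy-number qPCR, not PCR, separates them. Sub-base-pair
junction-overlap bookkeeping is ignored at this abstraction level, and
primer thermodynamics are out of scope.

## qPCR model and ΔΔCt

Ct = intercept − log2(template)/log2(1 + E), with E the per-cycle
efficiency (1.0 = perfect doubling, one cycle per template doubling);
replicate noise is additive Gaussian on Ct. Copy number:
CN(s) = CN_cal · 2^−[(Ct_t − Ct_r)_s − (Ct_t − Ct_r)_cal] with a diploid
calibrator; error bars are the replicate-wise minimum and maximum
(replicates paired by index). Expression: per-sample ΔCt against the
reference gene, group fold change 2^−ΔΔCt against the control group, a
normal-theory 95% CI on the mean ΔΔCt back-transformed through 2^−x, an
unpaired t-test for two groups and a one-way ANOVA for more (α = 0.05).
An undetected target in a group is flagged and gets no fold change. In
noiseless mode ΔΔCt recovers any planted ratio exactly and is invariant to
per-sample additive Ct offsets (both are property-tested). The standard
curve is a least-squares fit of Ct on log10(template); QC passes for slope
in [−3.7762, −3.1035], R > 0.995, and |Δ y-intercept| < 1 against a paired
curve. Efficiency is reported as percent of perfect doubling,
100·10^(−1/slope)/2 — the mapping consistent with the published window's
endpoints (92% and 105%) — with the textbook (10^(−1/slope) − 1)·100 as a
secondary field. The planted expression contrasts default to 10-fold for
EDN3 in adult skin (the headline contrast) with smaller in-duplication
gene effects (SLMO2 2.5×, TUBB1 2×) as plausible magnitudes; the
proprietary analysis software's CI internals are not reproduced, and no
equivalence with them is claimed.

## Problem sizes and numerics

Default runs use the full study-scale conditions: 287 markers × 27
individuals for the array; two pools of ≈ 4.2 M pairs (30× over the
13.9 Mb chromosome); 10,000 CBS permutations. Everything completes in
seconds except CBS on a full profile (~15 s). Seeds are explicit arguments
everywhere — there is no global random state — and identical configuration
plus seed reproduces every generator's output byte-for-byte. The log2
fold-change pseudocount is 0.5 normalized units; depth-gain reporting uses
≥ 20 consecutive windows at log2FC ≥ 0.8 (a 2× guide-line rule; the exact
published call rule is not stated, so this one is declared here).
Threshold ties in the group-wise scan count as below; strand-tie inversion
votes count as not inverted; a missing genotype call disqualifies a marker
from fixed-het status unless the strictness flag is relaxed.

## Known limitations

Synthetic sequence is i.i.d. random: no repeats, GC waves, segmental
duplications or mappability structure, so array noise and depth noise are
better behaved than real data. Passing tests demonstrate that each method
recovers what its own model plants under realistic noise magnitudes — not
that the thresholds would be optimal on a real chip or a real mate-pair
library. Multi-chromosome scanning, BAF modelling, alignment, and wet-lab
protocol details are out of scope throughout.
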