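# Methods

This note documents the models, conventions and design choices behind
`loophub`, in the order data flows through the pipeline.

## Coordinates and formats

All coordinates are 0-based half-open (BED convention), internally and in
every file read or written; the convention is fixed rather than detected,
and is guarded by the interval invariant (`end > start`) and round-trip
tests. Chromosomes sort naturally (chr1 < chr2 < chr10). Strand is carried
on intervals for window construction but ignored by every overlap
operation. The mango-style loop reader accepts 8–10 tab-separated columns
(`chrA startA endA chrB startB endB petCount [p] [q]`), since loop callers
differ in whether they emit p- and q-value columns; anchors are
canonicalised on load so that `(chromA, startA) ≤ (chromB, startB)`.

## In-silico digestion and PET classification

A chromosome is cut at the start of every exact GATC occurrence
(overlapping occurrences each cut; an empty leading fragment is dropped),
so fragments tile `[0, length)` exactly. Read trimming truncates at the
earliest occurrence of either ligation-site string and keeps the first
four bases of the site — the fragment-terminal GATC — preserving a
mappable fragment end; the exact retention behaviour of upstream Hi-C
processors is not standardised, so this choice is documented here and
pinned by tests. Pair classification follows standard Hi-C QC: different
non-adjacent fragments → valid (inter-chromosomal pairs are always valid);
same fragment → dangling end (inward strands, i.e. the leftmost end on +)
or self-circle (outward); adjacent fragments (|Δindex| = 1, same
chromosome) → re-ligation, counted invalid. Same-fragment same-strand
pairs are not a ligation product and are left `unassigned`. Classification
is symmetric in the two ends. Duplicate pairs are retained in both library
modes; multi-mapped records are removed only in `plhichip` mode — the
protein-directed (and spike-in) libraries — never in `plhic`. No aligner
is invoked: end positions come from the generator's truth coordinates, so
aligner seed/mismatch settings have no analogue here.

## Spike-in normalisation

For a batch of samples each carrying a primary-genome count and a
spike-genome count (reads for ChIP with reference exogenous chromatin,
valid PETs for spike-in HiChIP), the factor for sample *i* is
`min_j(spike_j) / spike_i`. The minimum is taken over the samples passed
in one call — an experiment batch — not globally, matching per-figure
normalisation practice. Spike-genome PETs are removed from the primary
PET set before PET-count factors are computed. Consequences tested:
normalised values scale with the batch minimum under joint rescaling, and
between-sample ratios equal `(primary_i/spike_i)/(primary_j/spike_j)`
exactly. Whether per-loop PET counts or only total interaction numbers
are rescaled is exposed as two entry points (`splhichip_factors` for
factors, `interaction_fold_change` for totals); totals are the default
reading.

## Annotation

Derived tracks: promoter = TSS ± 500 bp and TES window = TES ± 300 bp,
strand-aware; gene body = the transcribed span (exons plus introns);
enhancer = every intersection of an H3K4me1 and an H3K27ac peak that does
not touch an H3K4me3 peak (candidates overlapping H3K4me3 are excluded
entirely, as promoter-like). Anchor labels use a fixed priority order —
enhancer, promoter, TES, gene body, tRNA, rRNA, miRNA, snRNA, snoRNA,
SINE, LINE, LTR, satellite — with a minimum overlap of 1 bp (the common
intersection default; no slop). Anchors matching nothing are labelled
`intergenic`, a label the upstream bar charts imply but do not name.
Loop-class labels are unordered pairs printed with the higher-priority
class first. Percentages round half away from zero to integers, matching
the printed "28%/19%/14%/10%" style. A `merge_map` lets callers collapse
TES/gene-body anchors into a single genic category where a coarser
tabulation is wanted.

## Loop overlap

`pair_to_pair` reproduces paired-interval overlap semantics: under
"both", each anchor of the A loop must overlap a distinct anchor of the B
loop (either pairing orientation); under "either", at least one anchor
pair overlaps. Self-hits are suppressed by record identity, not by
coordinates, so distinct records at identical coordinates do match.
The published description of this step is internally inconsistent (it
names the both-anchor requirement while citing the either-type option);
this implementation follows the tool semantics the option names. The Venn
summary is loop-level and A-centred: an A loop is counted once however
many B loops it matches, so `shared-one = either − both` — this is the
reading under which the printed counts (1075 one-anchor + 32 both-anchor
= 1107 shared) are consistent. Equivalence with a quadratic brute-force
oracle over all pairs and all four anchor pairings is tested on random
instances.

## Motif scanning

Scores are `Σ log2(p_motif/p_background)` in bits, scanned on both
strands (the minus strand via the reverse-complement matrix, with its own
score distribution so asymmetric backgrounds remain exact). The
background is an order-0 fit of the input sequences with A/T and C/G
symmetrised (the standard zero-order background of motif tools;
symmetrisation can be disabled). The exact p-value of a score is the
probability that a random background word of width w scores at least as
high, computed by discretising per-position scores to 0.001-bit bins and
convolving the distribution position by position. The DP therefore equals
full 4^w enumeration on the same binned scores (tested to 1e-12); against
unbinned enumeration the deviation is bounded by the background mass
within w·0.001 bits of the threshold, which is asserted explicitly.
P-values are monotone non-increasing in score. Per anchor, duplicate hits
of one motif keep the lowest p-value and the anchor label is the
highest-priority motif present — E-box before B-box before A-box — so
priority beats p-value across motifs. Pseudocount is 0.1 per matrix cell.

The shipped PWMs (`data/motifs/synthetic_motifs.meme`) are synthetic,
consensus-derived approximations built for this package: an 8-bp
CACGTG-centred E-box (`CCACGTGG`), the internal RNAPIII promoter B-box
(`GTTCGAANNC`) and A-box (`TGGCNNARYNNG`). The E-box carries the 2-bp
flanking context deliberately: a 6-bp consensus word retains at least
(1/4)^6 ≈ 2.4 × 10⁻⁴ of background mass, so no 6-mer can ever pass the
p ≤ 1 × 10⁻⁴ hit filter; with 8 informative positions the planted
consensus is guaranteed to pass for any non-degenerate background. Real
database matrices can be supplied in MEME minimal format and are treated
as plain inputs.

## Hub networks

Node identity is exact anchor-coordinate equality — shared anchors across
loops arise by construction in peak-anchored loop calling — and parallel
loops merge into one edge with summed PET weight. Clusters are connected
components; whether the original analysis used components or a community
detection is not documented, so components (the weaker assumption) are
used, and the per-cluster statistics (node count, promoter count,
enhancer count, total PET weight, gene list) are computed per component.
Gene assignment to a promoter node takes the gene whose TSS window
contains the anchor midpoint, ties broken by nearest TSS. Cluster-size
comparisons use the two-sided Wilcoxon rank-sum test, exact for ≤ 20
pooled observations, normal approximation with tie correction otherwise.
Gene-set over-representation is the upper-tail hypergeometric test
(`P(X ≥ k)` for k of n hub genes in a K-member set within an N-gene
universe) with Benjamini–Hochberg q-values, flagged at q ≤ 0.05;
duplicate gene symbols are merged beforehand, keeping the median of their
PET counts. Layout is delegated: the module exports SIF-style edge lists
and node tables rather than computing a spring embedding.

## Signal metrics

Windows are strand-aware (`TSS ± w`; `TSS..TSS+w` extending in the
direction of transcription; `TES ± w`) and clipped with a log message at
chromosome edges. Reads count once per window at ≥ 1 bp overlap; no
split-read logic (synthetic reads are contiguous). Metagene profiles
average step-function coverage in equal-width bins, flip minus-strand
genes, and report per-bin mean ± SEM with the n−1 standard deviation;
tracks are expected to be spike-scaled already, and linearity of the
whole stack under a scale factor is tested. Equal-size binning sorts by
x: in genes-per-bin mode the remainder forms a final smaller bin
(14,085 at 150/bin → 94 bins, last 135); in n-bins mode exactly n bins
are produced and the last absorbs the remainder. Reference
normalisation divides by the reference group's median (which maps to 1).
The binding-per-interaction ratio defaults to a global sum-over-windows
ratio, with a per-window mode exposed, since the original computation is
not specified at that granularity. Group comparisons: Welch's t
(unpaired, two-sided, unequal variance) and the unpaired two-sided
Wilcoxon rank-sum; a degenerate-variance Welch call falls back to the
exact rank test with a log message.

## Synthetic data

The generator emulates the statistical structure of the study at one
tenth scale, which keeps the default suite under a few seconds while
leaving all counting statistics comfortably testable: 460 loops with 23
decoys, 1,470 genes (3 kb bodies on four 2.5 Mb chromosomes), 150
enhancers plus 30 decoy K4me1/K27ac sites carrying K4me3, ~850 repeats
across nine classes, expression strata of 1,470/61/92 genes, and a 5%
spike-read fraction standing in for the 1:20 spike cell ratio. Features
are laid out left-to-right with random gaps so annotation tracks never
overlap; this makes planted-truth recovery exact and is the main
idealisation relative to real genomes, where overlapping annotations
force genuinely ambiguous priority decisions — passing tests show the
priority rule is applied correctly, not that real-data compositions are
recoverable. Loop classes are multinomial draws from the planted
fractions (defaults 0.28/0.19/0.14/0.10 for promoter–promoter,
promoter–gene-body, promoter–SINE, enhancer–promoter/gene, remainder
intergenic); PET counts are geometric with mean 4 — a stand-in, as the
emulated study does not characterise its PET-count distribution. True
loops draw q uniform on (0, 0.01], decoys uniform on (0.01, 1], making
the q-filter's behaviour exactly predictable. Planted hubs draw dedicated
promoter/enhancer anchors (reused across their loops, so hub nodes are
shared exactly) connected as a random recursive tree or a path;
`unique_background_anchors` confines background loops to 2-node
components for clean hub-recovery scenarios. Reads are sampled from
fragment ends with planted validity classes; junction reads are chimeras
of a fragment-A suffix, a ligation-site string at a recorded offset and a
fragment-B prefix. Spike reads are drawn from separately labelled spike
chromosomes — exclusive two-genome mapping is represented by this label,
since only exclusivity enters the normalisation formula and alignment is
out of scope. Identical spec and seed give byte-identical outputs; each
generation stage uses an independent seeded stream so stages can be
re-run in any order.

## Known limitations

- No sequencing-error model beyond none, no GC bias, no polymer model of
  contact probability; loop anchors are drawn independently of genomic
  distance.
- Positional truth replaces alignment; MAPQ-dependent behaviour and
  split-read junction rescue are out of scope.
- Background models for motif scanning are order-0 only.
- The overlap module computes no permutation null for overlap
  significance (none is defined for the emulated analysis).
- Community-detection clustering is not implemented; clusters are
  connected components (see above).
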