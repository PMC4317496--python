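# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the simulations do and do not capture, and the
numerical conventions a maintainer would need.

## Simulated genomes

Background sequence is i.i.d. uniform over A/C/G/T (GC 0.5). Each toy
chromosome carries exactly one centromere; dispersed-repeat families
(solo LTRs, full transposon analogues) are derived from one consensus per
family — the first member *is* the consensus and later members carry
seeded substitutions, so a two-member family realizes the requested
pairwise identity exactly up to rounding to a whole number of
substitutions. Both homologues start identical except for explicitly
planted heterozygous variants on homologue 1. Coordinates are 0-based
half-open internally; GFF3 output is 1-based inclusive, BED 0-based
half-open.

Amplification events target homologue 1 by convention, so homologue 0
always serves as the unrearranged mapping reference. In-loco arrays
insert to the right of the original unit by default (configurable to the
left; the left construction is the exact mirror image, built by reverse
complement).

**Junction microhomology** is planted into the reference around the two
donor cut sites (identically on both homologues) and the array is then
formed by plain concatenation at the cuts. The breakpoint-ambiguity
window of the realized junction therefore equals the planted homology
exactly — guard bases immediately outside the window are forced to
mismatch — and each extra copy adds exactly
`unit − internal deletion` nucleotides, which keeps karyotype arithmetic
(`base + E × effective unit`) an identity rather than an approximation.
The single-nucleotide-in-common case is representable as microhomology 1
under the `no_homology` mode.

**Inverted arrays** alternate copy orientation (U, rc(U), U, …); every
interface carries a short unique center whose flanks are reverse
complements of each other. Two center sequences are used, one per
interface parity, reused across the array, so each junction type is
identical in every copy (as in a real array). Copies are *exact* reverse
complements, which makes the junction palindromic to the full unit
depth; the configured arm length is therefore a guaranteed minimum, and
any scorer observes `min(unit depth, its own window)` — e.g. exactly
`200 − center` from a ±200-nt window. (Capping the arm with planted
substitutions was rejected: a 1-nt mismatch at arm distance fragments
the junction contigs in assembly and breaks exact split alignment.) The
center's outer bases are constrained not to complement each other so the
scored center length is exactly the configured one. An odd copy count
leaves one centre-less inverted boundary junction against the flank,
recorded in the truth bundle with unspecified (chance) microhomology.
Array length adds `E × unit + Σ centers`, recorded exactly.

**Episomes** are circular replicons at a fixed per-cell copy count (no
cell-to-cell variance — depth estimation only sees the mean); the
chromosomes are left intact, matching the observation that episome
formation leaves no cognate chromosomal deletion. Reads sampled from a
circle may wrap the origin, so the circular junction produces clipped
reads exactly like a chromosomal one.

**Reads** are single-end, fixed length (default 100 nt), substitution
errors only, constant Phred-40 qualities (the analysis uses no quality
or indel information), starts uniform over all homologues and episome
copies. Read count = `round(depth × total length / read length)`.

Not modelled: paired ends, indel/structural errors, GC bias,
replication-timing coverage waves, cell-to-cell copy-number variance, or
the replication mechanism that creates the arrays. Consequently a
passing suite shows the *inference* is sound on clean uniform-coverage
data; it says nothing about robustness to real library artefacts.

## Mapping and copy number

The mapper is deliberately small: 21-mer seeds from both read ends,
gapless full-length extension on either strand, mismatch budget 3 per
100 nt. Unique/ambiguous/clipped/unmapped semantics: ambiguous reads
(ties at minimal mismatch count) are counted once at their
lowest-coordinate placement for depth and excluded from variant calling;
clipped reads (no full-length placement but an exact prefix or suffix
≥ 25 nt) contribute depth over their mapped span and feed junction
assembly together with unmapped reads. The kernel is JIT-compiled with
numba when available, with an identical pure-Python fallback.

Copy number: `cn(x) = 2·d(x)/m` with `m` the mean depth over the
un-masked genome, so the un-masked mean of cn is exactly 2. Smoothing is
a centered moving average (default window 1,500 nt, odd-ized; 5,000 nt
for coarse views) with edge truncation.

**Segmentation** rounds the smoothed profile to integer levels, keeps
maximal runs, absorbs runs shorter than `min_segment` (default 5,000 nt)
into the closest-level neighbour (which also removes the sub-window
ramps smoothing creates at step edges), refines each boundary to the
raw-profile step position (two-means split within one window) and
recomputes each segment's level as the rounded median of raw cn.

Because the normalizing mean includes the amplified material itself, the
raw normalized level underestimates true copy number whenever the
amplified fraction is non-negligible — on ~600-kb toy genomes a 21 × 50-kb
array is ~40% of the DNA and would round to the wrong integer. The
segmenter therefore re-anchors the diploid baseline before rounding:
first factor from the median of the smoothed profile, then a refinement
pass pinning the median of the *modal* integer level at 2. This is the
standard CNV-caller re-centering step; it assumes the diploid baseline
is the most common level, which holds for every configuration shipped
here (amplified units < 50% of the reference). On genomes much larger
than the amplicon the correction is a no-op (bias < 3%).

Boundary uncertainty is one smoothing window; in practice recovered
boundaries land within a few hundred nucleotides at 30× depth.

## Junction discovery

Breakpoint evidence = unmapped + clipped reads. Assembly builds a de
Bruijn graph on k-mers (default k = 17, odd so no k-mer is its own
reverse complement) over both orientations of every read, drops k-mers
below coverage 2 (error k-mers), and emits contigs as bounded
branch-following simple paths (budgets: ≤ 6 branch events, ≤ 64 paths
per start, ≤ 1,200 nodes) rather than strict unitigs. The relaxation is
load-bearing: a quasi-palindromic junction necessarily branches the
graph at its center (the two strands of the junction window differ there
and nowhere else), and the flank chains of a multi-junction inverted
array are shared between junction types, so strict unitigs truncate
precisely the contigs of interest. Contigs shorter than 2k − 1 are
discarded; reverse-complement and contained duplicates are collapsed;
ordering is deterministic (length desc, then sequence).

Split alignment anchors a contig by its longest exactly-matching prefix
and suffix on either strand (contigs are consensus sequences; junctions
resolve at nucleotide level, so matching is exact). Overlapping anchors
give the microhomology (ambiguity window, leftmost-canonical breakpoint);
anchors short of the contig by ≤ 25 nt give an inserted junction center
(the quasi-palindromic case). A contig fully contained in the reference
yields no call. Calls are strand-canonicalized (the −/− representation
folds onto +/+; mixed-strand anchors are coordinate-ordered) so a contig
and its reverse complement produce the same call.

Scoring: `microhomology_length` returns the longest l with
`left[-l:] == right[:l]`, donors given at the outermost equivalent
breakpoints; `detect_quasi_palindrome` scans every candidate center
(length ≤ 20 by default) and returns the maximal arm, ties toward the
smaller center then leftmost. Both are verified against brute-force
oracles on randomized instances.

## Structure classification

Per amplified region (extra ≥ 1), in order: whole-chromosome segment →
aneuploidy; same-level segments bridged by an internal-deletion junction
merge into one unit whose deletion is the gap. Then the centromere rule
is applied as a hard constraint: a unit whose *retained* part contains
the centromere and has a circularization junction (direct end→start over
a centromeric segment) is an episome; a centromeric unit with a
chromosomal tandem junction is emitted as `conflict`, never resolved
silently. Centromere-free units: direct tandem junction → macrotene
direct (E = 1 with both anchors inside LTR/Ty features → segmental
duplication, otherwise the segmental-duplication rule would be shadowed
by the tandem rule); inverted boundary junction → macrotene inverted;
otherwise `unclassified` with the evidence attached. The episome call
does not require a chromosomal deletion; the intact cn = 2 outside the
unit is part of the evidence. Episome copy number is the segment level
minus 2, i.e. a per-cell mean.

Karyotype prediction: macrotene arrays migrate at
`base + E × effective unit`; an episome leaves the chromosome at base
size and adds a circular species of unit length; an aneuploidy adds a
band at base size. Gel consistency uses relative tolerance 0.10 against
the closest observed band; observation noise is modelled as bounded
multiplicative error (±8%), under which predicted sizes pass the 10%
check in ≥ 95% of draws (Gaussian 8% noise would not satisfy that and is
not what gel reading error looks like — it is bounded by the calibration
ladder).

## Variant screen

Pileups count uniquely mapped reads only. Standard mode requires depth
≥ 5 and variant allele frequency ≥ 0.2 (diploid strains put a real
heterozygote near 0.5); inside designated amplicon intervals both floors
are dropped, because an allele on a subset of array copies sits at
frequency `k/(2+E)`. Zygosity cuts at VAF 0.75, the midpoint of the
heterozygous and homozygous expectations. When depth ≥ 10, a call also
needs supporting reads on both strands (an automated version of manual
strand-consistency inspection). Candidates shared by *all* strains of an
experiment are reference errors when homozygous everywhere and
strain-construction events when heterozygous everywhere — both excluded
from the evolved-mutation report; everything else is strain-specific and
retained. Indels are out of scope (none were ever validated in this
experimental system). Tri-allelic columns emit the most frequent
non-reference base only; the hom/het cut and thresholds are all
configurable arguments.

## Population dynamics

All deterministic arithmetic, matching the experimental design it
describes: `n = log₂(volume·d / Ni)` generations per culture (2-litre
cultures, density `d` in cells/ml, inoculum `Ni` = 10⁹ except the first
two cultures of each experiment at 10⁸ and 5 × 10⁸); prefix sums over
the packaged culture tables give the cumulative counts. A growth-rate
advantage `s` (the mutant divides `1+s` times per wild-type generation —
the only reading under which 12.5% and "doubles per ~8-generation
transfer" are simultaneously exact) multiplies the mutant:wild-type
ratio by `2^(s·n)` per transfer; the invasion threshold is `1/Ni`, the
frequency with one expected mutant cell in the bottleneck. Stability:
conserving a fraction `C` after `G` generations ↔ per-cell
per-generation loss `p = 1 − C^(1/G)`; `conserved_fraction` is the exact
inverse (round trip < 10⁻¹²). Drift between bottlenecks is ignored: at
10⁹-cell bottlenecks it is negligible above the invasion threshold.

## Dosage expression

Observed abundance = `baseline × copy number × exp(N(0, σ²))` per
sample; the control sample carries copy number 2. MA values are
`M = log₂(case/control)`, `A = ½·log₂(case·control)`; the amplicon
summary is the arithmetic mean (and SD) of per-gene folds `2^M` —
mean of folds, not fold of means — with not-tested genes excluded. Under
lognormal noise the mean of folds exceeds the dosage ratio by the
lognormal correction `E[exp(X−Y)]`; the test suite computes that
expectation by Monte Carlo rather than assuming a closed form. Real
microarray fold levels are *not* reproduction targets (real biology,
array normalization); simulations at the published copy numbers are only
required to land in the same 2–20× order of magnitude.

## Problem sizes and determinism

Shipped scenario defaults follow the published amplicon dimensions on
300–700-kb toy chromosomes: 30-kb direct tandem ×12 (600-kb
chromosome), 55-kb centromeric episome ×8, 50-kb inverted array ×21
(midpoint of the printed 20–22 range, 700-kb chromosome), 211-kb
centromeric episome ×3, all at depth 30×, 100-nt reads, error 10⁻³ —
about 0.5–0.7 M reads per run. The scaled-down five-class suite
(120–160-kb chromosomes, 12-kb units) exists for fast classifier
soundness checks. Every random draw flows from a single integer seed
through `numpy.random.SeedSequence`; identical seeds give byte-identical
FASTA/FASTQ/JSON and identical reports.

## Known limitations

* The insertion side of an in-loco array is not inferable from coverage
  plus junction calls (both sides produce identical evidence); it is a
  simulation parameter only.
* Junctions inside long perfect repeats cannot be resolved below the
  microhomology window in principle; calls report the window, and
  nothing asserts a point position there.
* The segmenter assumes the diploid baseline is the modal copy-number
  level; configurations where amplified material exceeds half the
  reference would re-anchor wrongly.
* Inter-chromosomal calls pass through labelled `translocation-like`
  and are not classified further.
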