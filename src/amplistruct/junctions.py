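"""Novel-junction recovery: k-mer assembly of breakpoint reads, split
alignment of the resulting contigs, and junction-geometry scoring.

Reads that fail to map full length (unmapped or clipped) are assembled
into unitigs of a de Bruijn graph (default k = 17, unbranched paths only
— junction neighbourhoods are tiny).  Each contig is then anchored on the
reference by its longest exactly-matching prefix and suffix (either
strand).  If the two anchors overlap on the contig, the overlap is the
breakpoint-ambiguity window (microhomology); if they leave a short gap,
the gap is an inserted junction center (the quasi-palindromic case).
Breakpoints are canonicalized to the leftmost equivalent position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import decode, encode, revcomp
from .genome import Feature, GenomeModel, pairwise_identity
from .mapping import AlignmentSet, ReferenceIndex
from .coverage import SegmentCall
from .reads import ReadSet

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_K = 17


@dataclass(frozen=True)
class JunctionContig:
    contig_id: str
    sequence: str
    support: int
    k: int

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PalindromeDescriptor:
    arm: int
    center: int
    center_start: int  # position of the (possibly empty) center on the contig


@dataclass
class BreakpointCall:
    chrom_l: str
    pos_l: int
    strand_l: str
    chrom_r: str
    pos_r: int
    strand_r: str
    orientation: str  # direct | inverted
    microhomology: int
    inserted: int  # unaligned junction-center length (0 for clean joins)
    ambiguity: tuple[int, int]  # equivalent left-anchor positions [lo, hi]
    contig_id: str
    n_reads: int = 0
    ambiguous: bool = False
    palindrome: PalindromeDescriptor | None = None
    junction_class: str = ""
    anchor_features: tuple = ()
    anchor_identity: float | None = None


# ------------------------------------------------------------- selection
def collect_breakpoint_reads(alignments: AlignmentSet, reads: ReadSet) -> ReadSet:
    """Reads whose status is unmapped or clipped; everything else excluded."""
    return reads.subset(np.flatnonzero(alignments.is_breakpoint_evidence()))


# -------------------------------------------------------------- assembly
def assemble_junction_contigs(
    reads: ReadSet, k: int = DEFAULT_K, min_kmer_cov: int = 2
) -> list[JunctionContig]:
    """Unitigs of the de Bruijn graph over both read orientations.

    k must be odd (a perfect-palindrome k-mer would otherwise equal its own
    reverse complement and self-pair); k-mers seen fewer than
    ``min_kmer_cov`` times are dropped as sequencing errors; contigs
    shorter than 2k - 1 are discarded.  Output is deterministic: reverse-
    complement duplicates are collapsed to the lexicographically smaller
    strand and contigs are ordered by (length desc, sequence).
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    counts: dict[str, int] = {}
    read_seqs = []
    for i in range(len(reads)):
        seq = reads.sequence(i)
        read_seqs.append(seq)
        if len(seq) < k:
            continue
        for s in (seq, revcomp(seq)):
            for j in range(len(s) - k + 1):
                km = s[j : j + k]
                counts[km] = counts.get(km, 0) + 1
    kmers = {km for km, c in counts.items() if c >= min_kmer_cov}

    def succ(km):
        return [km[1:] + b for b in "ACGT" if km[1:] + b in kmers]

    def pred(km):
        return [b + km[:-1] for b in "ACGT" if b + km[:-1] in kmers]

    touched: set[str] = set()
    raw_contigs: list[str] = []
    # junction neighbourhoods are tiny, so paths through the graph can be
    # enumerated with small budgets instead of stopping at every branch
    # (a quasi-palindromic junction necessarily branches at its center:
    # the two strands of the junction differ there and nowhere else)
    MAX_PATH = 1200
    MAX_BRANCHES = 6
    MAX_PATHS_PER_START = 64

    def walk_all(start: str) -> list[str]:
        out: list[str] = []
        stack = [([start], {start}, 0)]
        while stack and len(out) < MAX_PATHS_PER_START:
            path, local, nb = stack.pop()
            cur = path[-1]
            while True:
                touched.add(cur)
                nxt = [n for n in succ(cur) if n not in local]
                if not nxt or len(path) >= MAX_PATH:
                    out.append(path[0] + "".join(p[-1] for p in path[1:]))
                    break
                if len(nxt) == 1:
                    cur = nxt[0]
                    path.append(cur)
                    local.add(cur)
                    continue
                if nb >= MAX_BRANCHES:
                    out.append(path[0] + "".join(p[-1] for p in path[1:]))
                    break
                for n in sorted(nxt)[1:]:
                    stack.append((path + [n], local | {n}, nb + 1))
                cur = sorted(nxt)[0]
                path.append(cur)
                local.add(cur)
                nb += 1
        return out

    starts = [km for km in sorted(kmers) if len(pred(km)) == 0]
    for km in starts:
        raw_contigs.extend(walk_all(km))
    for km in sorted(kmers):  # leftovers (cycles, branch-internal chains)
        if km not in touched:
            raw_contigs.extend(walk_all(km))

    # drop short contigs, collapse reverse-complement duplicates and contigs
    # wholly contained in a longer one (walks may overlap)
    canon: dict[str, None] = {}
    for seq in raw_contigs:
        if len(seq) < 2 * k - 1:
            continue
        canon.setdefault(min(seq, revcomp(seq)), None)
    by_len = sorted(canon, key=lambda s: (-len(s), s))
    ordered: list[str] = []
    for seq in by_len:
        rc = revcomp(seq)
        if any(seq in kept or rc in kept for kept in ordered):
            continue
        ordered.append(seq)

    # supporting reads: any read sharing >= 1 k-mer with the contig
    kmer_to_contig: dict[str, set[int]] = {}
    for ci, seq in enumerate(ordered):
        for s in (seq, revcomp(seq)):
            for j in range(len(s) - k + 1):
                kmer_to_contig.setdefault(s[j : j + k], set()).add(ci)
    support = [0] * len(ordered)
    for seq in read_seqs:
        hit: set[int] = set()
        for j in range(len(seq) - k + 1):
            hit |= kmer_to_contig.get(seq[j : j + k], set())
        for ci in hit:
            support[ci] += 1

    return [
        JunctionContig(contig_id=f"contig{ci + 1:04d}", sequence=seq, support=support[ci], k=k)
        for ci, seq in enumerate(ordered)
    ]


# -------------------------------------------------------- split alignment
def _seed_hits(index: ReferenceIndex, codes: np.ndarray) -> np.ndarray:
    k = index.k
    code = 0
    for t in range(k):
        code = code * 4 + int(codes[t])
    lo = np.searchsorted(index.kmer_keys, code)
    hi = np.searchsorted(index.kmer_keys, code + 1)
    return index.kmer_pos[lo:hi]

def _extend_fwd(index: ReferenceIndex, codes: np.ndarray, p: int) -> int:
    """Length of exact match of ``codes`` starting at global position p."""
    ref = index.codes
    ci = int(np.searchsorted(index.chrom_starts, p, side="right")) - 1
    ce = int(index.chrom_starts[ci + 1])
    t = 0
    n = codes.size
    while t < n and p + t < ce and ref[p + t] == codes[t]:
        t += 1
    return t

def _extend_back(index: ReferenceIndex, codes: np.ndarray, p_end: int) -> int:
    """Length of exact match of ``codes`` ending (exclusive) at global p_end."""
    ref = index.codes
    ci = int(np.searchsorted(index.chrom_starts, p_end - 1, side="right")) - 1
    cs = int(index.chrom_starts[ci])
    n = codes.size
    t = 0
    while t < n and p_end - 1 - t >= cs and ref[p_end - 1 - t] == codes[n - 1 - t]:
        t += 1
    return t


def _longest_prefix(index: ReferenceIndex, codes: np.ndarray, rcc: np.ndarray):
    """Longest exactly-placed contig prefix on either strand.

    Returns (length, [(gstart, strand)]) with gstart the global reference
    start of the placed prefix (forward-strand coordinates).
    """
    k = index.k
    n = codes.size
    best, places = 0, []
    if n >= k:
        for p in _seed_hits(index, codes[:k]):
            p = int(p)
            ext = k + _extend_fwd(index, codes[k:], p + k)
            if ext > best:
                best, places = ext, [(p, "+")]
            elif ext == best:
                places.append((p, "+"))
        # prefix of contig == suffix of rcc on the minus strand
        for p in _seed_hits(index, rcc[n - k :]):
            p = int(p)
            ext = k + _extend_back(index, rcc[: n - k], p)
            if ext > best:
                best, places = ext, [(p + k - ext, "-")]
            elif ext == best:
                places.append((p + k - ext, "-"))
    return best, sorted(set(places))


def _longest_suffix(index: ReferenceIndex, codes: np.ndarray, rcc: np.ndarray):
    k = index.k
    n = codes.size
    best, places = 0, []
    if n >= k:
        for p in _seed_hits(index, codes[n - k :]):
            p = int(p)
            ext = k + _extend_back(index, codes[: n - k], p)
            if ext > best:
                best, places = ext, [(p + k - ext, "+")]
            elif ext == best:
                places.append((p + k - ext, "+"))
        # suffix of contig == prefix of rcc on the minus strand
        for p in _seed_hits(index, rcc[:k]):
            p = int(p)
            ext = k + _extend_fwd(index, rcc[k:], p + k)
            if ext > best:
                best, places = ext, [(p, "-")]
            elif ext == best:
                places.append((p, "-"))
    return best, sorted(set(places))


def split_align_contig(
    contig: JunctionContig,
    reference: ReferenceIndex | GenomeModel,
    max_gap: int = 25,
) -> BreakpointCall | None:
    """Anchor a junction contig by its longest exact prefix and suffix.

    Returns ``None`` for contigs that match the reference over their full
    length (no breakpoint) or that cannot be anchored on both sides within
    ``max_gap`` unaligned center nucleotides.
    """
    if isinstance(reference, GenomeModel):
        index = ReferenceIndex.from_genome(reference)
    elif isinstance(reference, dict):
        index = ReferenceIndex(reference)
    else:
        index = reference
    codes = encode(contig.sequence)
    rcc = encode(revcomp(contig.sequence))
    n = codes.size

    lp, p_places = _longest_prefix(index, codes, rcc)
    if lp == n:
        return None  # wholly reference
    ls, s_places = _longest_suffix(index, codes, rcc)
    if lp == 0 or ls == 0:
        return None
    overlap = lp + ls - n
    gap = max(0, -overlap)
    mh = max(0, overlap)
    if gap > max_gap:
        return None

    ambiguous = len(p_places) > 1 or len(s_places) > 1
    p_start, p_strand = p_places[0]
    s_start, s_strand = s_places[0]

    # canonical leftmost breakpoint: trim the prefix by the overlap, keep the
    # full suffix; the left anchor is the inner (junction-adjacent) base of
    # the trimmed prefix, the right anchor the first base of the suffix.
    if p_strand == "+":
        left_g = p_start + (lp - mh) - 1
    else:
        left_g = p_start + mh  # minus-strand placement: inner end at low coord
    if s_strand == "+":
        right_g = s_start
    else:
        right_g = s_start + ls - 1

    chrom_l, pos_l = index.chrom_of(left_g)
    chrom_r, pos_r = index.chrom_of(right_g)
    orientation = "direct" if p_strand == s_strand else "inverted"

    # canonical strand representation: a contig and its reverse complement
    # describe the same junction; fold the (-,-) form onto (+,+) and order
    # mixed-strand anchors by coordinate
    flip = {"+": "-", "-": "+"}
    if (p_strand, s_strand) == ("-", "-") or (p_strand != s_strand and pos_r < pos_l):
        (chrom_l, pos_l, p_strand), (chrom_r, pos_r, s_strand) = (
            (chrom_r, pos_r, flip[s_strand]),
            (chrom_l, pos_l, flip[p_strand]),
        )
    if p_strand == "+":
        amb = (pos_l, pos_l + mh)
    else:
        amb = (pos_l - mh, pos_l)

    return BreakpointCall(
        chrom_l=chrom_l,
        pos_l=pos_l,
        strand_l=p_strand,
        chrom_r=chrom_r,
        pos_r=pos_r,
        strand_r=s_strand,
        orientation=orientation,
        microhomology=mh,
        inserted=gap,
        ambiguity=amb,
        contig_id=contig.contig_id,
        n_reads=contig.support,
        ambiguous=ambiguous,
    )


# ------------------------------------------------------------- geometry
def microhomology_length(left_flank: str, right_flank: str) -> int:
    """Breakpoint-ambiguity window between two junction donors.

    Donor flanks are given at the outermost equivalent breakpoints (the
    shared segment, if any, ends the left flank and starts the right one);
    the window is the longest l with ``left_flank[-l:] == right_flank[:l]``.
    """
    if not left_flank or not right_flank:
        raise ValueError("flanks must be non-empty")
    for l in range(min(len(left_flank), len(right_flank)), 0, -1):
        if left_flank[-l:] == right_flank[:l]:
            return l
    return 0


def detect_quasi_palindrome(
    contig: JunctionContig | str, min_arm: int = 10, max_center: int = 20
) -> PalindromeDescriptor | None:
    """Maximal-arm quasi-palindrome: arm + unique center + reverse-complement
    of arm.  Scans every candidate center (length 0..max_center); ties break
    toward the smaller center, then the leftmost.  None if best arm < min_arm.
    """
    seq = contig.sequence if isinstance(contig, JunctionContig) else contig
    n = len(seq)
    if n < 2 * min_arm:
        raise ValueError("contig shorter than twice the minimum arm")
    best: tuple[int, int, int] | None = None  # (arm, center, start)
    for i in range(n + 1):
        for c in range(0, max_center + 1):
            if i + c > n:
                break
            arm = 0
            while (
                i - 1 - arm >= 0
                and i + c + arm < n
                and seq[i - 1 - arm] == _COMP[seq[i + c + arm]]
            ):
                arm += 1
            if arm == 0:
                continue
            cand = (arm, -c, -i)
            if best is None or (cand[0], cand[1], cand[2]) > (best[0], -best[1], -best[2]):
                best = (arm, c, i)
    if best is None or best[0] < min_arm:
        return None
    return PalindromeDescriptor(arm=best[0], center=best[1], center_start=best[2])


# ---------------------------------------------------------- classification
def classify_junction(
    call: BreakpointCall,
    features: list[Feature],
    segments: list[SegmentCall],
    genome: GenomeModel | None = None,
    tol: int = 2000,
) -> str:
    """Assign a junction class against amplified segments and annotation.

    direct end->start over an amplified segment = tandem (or circularization
    when the segment spans the centromere); direct skipping an interval
    inside the amplified region = internal deletion; inverted at an
    amplified boundary = inverted-tandem; otherwise orphan.  Inter-
    chromosomal calls pass through as ``translocation-like``.
    """
    if call.chrom_l != call.chrom_r:
        call.junction_class = "translocation-like"
        return call.junction_class
    chrom = call.chrom_l
    amp = sorted(
        (s for s in segments if s.chrom == chrom and s.extra >= 1),
        key=lambda s: s.start,
    )
    cls = "orphan"
    if amp:
        span_lo, span_hi = amp[0].start, amp[-1].end
        cens = [
            f
            for f in features
            if f.chrom == chrom
            and f.kind == "centromere"
            and any(s.start < f.end and f.start < s.end for s in amp)
        ]
        if call.orientation == "direct":
            if (
                abs(call.pos_l - (span_hi - 1)) <= tol
                and abs(call.pos_r - span_lo) <= tol
                and call.pos_l > call.pos_r
            ):
                cls = "circularization" if cens else "tandem"
            elif (
                span_lo - tol <= call.pos_l < call.pos_r <= span_hi + tol
                and call.pos_r - call.pos_l > 2 * call.microhomology + 1
            ):
                cls = "internal_deletion"
        else:
            boundary_dist = min(
                min(abs(p - s.start) for s in amp for p in (call.pos_l, call.pos_r)),
                min(abs(p - (s.end - 1)) for s in amp for p in (call.pos_l, call.pos_r)),
            )
            if boundary_dist <= tol:
                cls = "inverted_tandem"

    # annotate repeat features under the anchors
    hits = []
    for pos in (call.pos_l, call.pos_r):
        hit = None
        for f in features:
            if f.chrom == chrom and f.kind in ("LTR", "Ty") and f.start <= pos < f.end:
                hit = f
                break
        hits.append(hit)
    call.anchor_features = tuple(hits)
    if genome is not None and all(h is not None for h in hits) and hits[0] is not hits[1]:
        a, b = hits
        if a.length == b.length:
            ref = genome.reference()[chrom]
            sa, sb = ref[a.start : a.end], ref[b.start : b.end]
            if a.strand != b.strand:
                sb = revcomp(sb)
            call.anchor_identity = pairwise_identity(sa, sb)
    call.junction_class = cls
    return cls
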