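"""Junction discovery: breakpoint-read selection, assembly, split
alignment, and the microhomology / quasi-palindrome scorers (checked
against brute-force oracles)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amplistruct._util import encode, revcomp
from amplistruct.junctions import (
    JunctionContig,
    assemble_junction_contigs,
    collect_breakpoint_reads,
    detect_quasi_palindrome,
    microhomology_length,
    split_align_contig,
)
from amplistruct.mapping import ReferenceIndex, map_reads
from amplistruct.reads import ReadSet, simulate_reads

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _readset(seqs):
    codes = np.vstack([encode(s) for s in seqs])
    return ReadSet(codes=codes, read_length=codes.shape[1], error_rate=0.0,
                   depth=0.0, seed=0)


# ------------------------------------------------------- breakpoint reads
def test_unrearranged_genome_yields_no_breakpoint_reads(small_genome):
    rs = simulate_reads(small_genome, depth=10, read_length=100, error_rate=0.0, seed=1)
    aln = map_reads(rs, small_genome.reference())
    bp = collect_breakpoint_reads(aln, rs)
    assert len(bp) == 0


def test_breakpoint_reads_all_overlap_the_junction(small_genome):
    ref = small_genome.reference()["chrA"]
    # build a derived chromosome with one novel junction at 30 kb -> 50 kb
    derived = ref[:30_000] + ref[50_000:]
    reads = []
    for start in range(29_900, 30_000, 7):
        reads.append(derived[start : start + 100])
    for start in range(25_000, 25_100, 7):  # control reads away from it
        reads.append(derived[start : start + 100])
    aln = map_reads(_readset(reads), small_genome.reference())
    bp_idx = np.flatnonzero(aln.is_breakpoint_evidence())
    # every retained read truly overlaps the junction by >= 1 nt (reads with
    # chance microhomology across the breakpoint may legitimately still map)
    starts = list(range(29_900, 30_000, 7)) + list(range(25_000, 25_100, 7))
    assert len(bp_idx) > 5
    for i in bp_idx:
        assert starts[i] < 30_000 < starts[i] + 100


# ----------------------------------------------------------------- assembly
def test_single_read_assembles_to_itself():
    rs = _readset(["ACGTTGCAACGGTCCATAGCTTACGGATCCGTTAACGGCTT"])
    contigs = assemble_junction_contigs(rs, k=17, min_kmer_cov=1)
    assert len(contigs) == 1
    seq = contigs[0].sequence
    assert seq in (rs.sequence(0), revcomp(rs.sequence(0)))
    assert contigs[0].support == 1


def test_even_k_rejected():
    rs = _readset(["ACGT" * 20])
    with pytest.raises(ValueError, match="odd"):
        assemble_junction_contigs(rs, k=16)


def test_disjoint_junctions_assemble_without_chimeras(small_genome, rng):
    ref = small_genome.reference()["chrA"]
    jx1 = ref[10_000:10_060] + ref[30_000:30_060]  # junction A
    jx2 = ref[45_000:45_060] + ref[18_000:18_060]  # junction B
    reads = []
    for window in (jx1, jx2):
        for start in range(0, 41, 4):
            reads.append(window[start : start + 80])
    contigs = assemble_junction_contigs(_readset(reads), k=17, min_kmer_cov=2)
    assert len(contigs) == 2
    for c in contigs:
        s = c.sequence
        one = s in jx1 or revcomp(s) in jx1
        two = s in jx2 or revcomp(s) in jx2
        assert one != two  # each contig belongs to exactly one junction


def test_junction_neighbourhood_assembles_into_one_contig(small_genome):
    # tile a 77-nt novel-junction region at high redundancy
    ref = small_genome.reference()["chrA"]
    window = ref[12_000:12_038] + ref[33_000:33_039]
    region = ref[11_950:12_000] + window + ref[33_039:33_089]
    reads = [region[i : i + 80] for i in range(0, len(region) - 80, 2)]
    contigs = assemble_junction_contigs(_readset(reads), k=17, min_kmer_cov=2)
    best = contigs[0].sequence
    assert window in best or revcomp(window) in best


# ------------------------------------------------------------ split align
def test_direct_junction_contig_anchors_at_known_coordinates(small_genome):
    ref = small_genome.reference()["chrA"]
    A, B = 15_000, 35_000
    contig = JunctionContig("c1", ref[A - 60 : A] + ref[B : B + 60], 5, 17)
    call = split_align_contig(contig, small_genome.reference())
    assert call is not None
    assert call.orientation == "direct"
    assert (call.pos_l, call.pos_r) == (A - 1 - call.microhomology, B - call.microhomology) or (
        call.pos_l,
        call.pos_r,
    ) == (A - 1, B)
    assert call.microhomology == call.ambiguity[1] - call.ambiguity[0]


def test_inverted_junction_contig_called_inverted(small_genome):
    ref = small_genome.reference()["chrA"]
    B = 35_000
    contig = JunctionContig("c1", ref[B - 60 : B] + revcomp(ref[B - 130 : B - 70]), 5, 17)
    call = split_align_contig(contig, small_genome.reference())
    assert call is not None
    assert call.orientation == "inverted"
    assert call.strand_l != call.strand_r


def test_reference_contig_gives_no_call(small_genome):
    ref = small_genome.reference()["chrA"]
    contig = JunctionContig("c1", ref[12_000:12_120], 5, 17)
    assert split_align_contig(contig, small_genome.reference()) is None


def test_center_gap_beyond_limit_gives_no_call(small_genome):
    ref = small_genome.reference()["chrA"]
    rng = np.random.default_rng(1)
    insert = "".join("ACGT"[i] for i in rng.integers(0, 4, size=40))
    contig = JunctionContig("c1", ref[15_000 - 60 : 15_000] + insert + ref[35_000 : 35_000 + 60], 5, 17)
    assert split_align_contig(contig, small_genome.reference(), max_gap=25) is None


# -------------------------------------------------- microhomology scoring
def _brute_microhomology(left: str, right: str) -> int:
    best = 0
    for l in range(1, min(len(left), len(right)) + 1):
        if left[-l:] == right[:l]:
            best = l
    return best


def test_shared_block_scores_its_length():
    rng = np.random.default_rng(2)
    bases = "ACGT"
    block = "".join(bases[i] for i in rng.integers(0, 4, size=29))
    left = "".join(bases[i] for i in rng.integers(0, 4, size=50)) + block
    right = block + "".join(bases[i] for i in rng.integers(0, 4, size=50))
    assert microhomology_length(left, right) >= 29


def test_single_shared_nucleotide_and_disjoint_alphabets():
    assert microhomology_length("ACGGA" + "T", "T" + "GGCAC") >= 1
    assert microhomology_length("ACACAAC", "GTGTGGT") == 0


def test_empty_flank_rejected():
    with pytest.raises(ValueError):
        microhomology_length("", "ACGT")


@settings(max_examples=250, deadline=None)
@given(st.text(alphabet="ACGT", min_size=1, max_size=40),
       st.text(alphabet="ACGT", min_size=1, max_size=40))
def test_microhomology_matches_brute_force(left, right):
    assert microhomology_length(left, right) == _brute_microhomology(left, right)


def test_microhomology_brute_force_bulk_equivalence(rng):
    bases = np.array(list("ACGT"))
    for _ in range(1000):
        l = "".join(bases[rng.integers(0, 4, size=rng.integers(1, 30))])
        r = "".join(bases[rng.integers(0, 4, size=rng.integers(1, 30))])
        assert microhomology_length(l, r) == _brute_microhomology(l, r)


# ---------------------------------------------------- palindrome scoring
def _brute_palindrome(seq: str, min_arm: int, max_center: int):
    n = len(seq)
    best = None
    for i in range(n + 1):
        for c in range(max_center + 1):
            if i + c > n:
                break
            arm = 0
            while i - 1 - arm >= 0 and i + c + arm < n and seq[i - 1 - arm] == COMP[seq[i + c + arm]]:
                arm += 1
            if arm and (best is None or (arm, -c, -i) > (best[0], -best[1], -best[2])):
                best = (arm, c, i)
    if best is None or best[0] < min_arm:
        return None
    return best


def test_constructed_quasi_palindrome_scores_arm_and_center(rng):
    bases = np.array(list("ACGT"))
    arm = "".join(bases[rng.integers(0, 4, size=30)])
    center = "AATAA"  # outer bases not mutually complementary
    seq = arm + center + revcomp(arm)
    desc = detect_quasi_palindrome(seq, min_arm=10, max_center=20)
    assert desc is not None and (desc.arm, desc.center) == (30, 5)


def test_perfect_palindrome_has_empty_center(rng):
    bases = np.array(list("ACGT"))
    arm = "".join(bases[rng.integers(0, 4, size=25)])
    desc = detect_quasi_palindrome(arm + revcomp(arm), min_arm=10, max_center=20)
    assert desc is not None and (desc.arm, desc.center) == (25, 0)


def test_random_sequence_has_no_long_palindrome(rng):
    bases = np.array(list("ACGT"))
    for _ in range(20):
        seq = "".join(bases[rng.integers(0, 4, size=100)])
        got = detect_quasi_palindrome(seq, min_arm=10, max_center=20)
        assert got == _brute_palindrome(seq, 10, 20)  # almost always None


def test_palindrome_brute_force_bulk_equivalence(rng):
    bases = np.array(list("ACGT"))
    for _ in range(1000):
        n = int(rng.integers(20, 60))
        seq = "".join(bases[rng.integers(0, 4, size=n)])
        got = detect_quasi_palindrome(seq, min_arm=1, max_center=8)
        expect = _brute_palindrome(seq, 1, 8)
        if expect is None:
            assert got is None
        else:
            assert (got.arm, got.center, got.center_start) == expect


def test_contig_shorter_than_twice_min_arm_rejected():
    with pytest.raises(ValueError):
        detect_quasi_palindrome("ACGTACGTACGT", min_arm=10)
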