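"""Seed-and-extend single-end read mapping against the collapsed reference.

A deliberately small mapper (no external aligner is called): 21-mer seeds
taken from both read ends, full-length gapless extension on either strand,
mismatch counting with an early abort.  A read is

``unique``     exactly one full-length placement attains the minimal
               mismatch count <= the threshold (default 3 per 100 nt);
``ambiguous``  several placements tie (depth later counts the
               lowest-coordinate one);
``clipped``    no full-length placement, but an exact prefix or suffix of
               >= 25 nt maps (reads straddling novel junctions);
``unmapped``   everything else (these feed junction assembly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import encode
from .genome import GenomeModel
from .reads import ReadSet

SEED_K = 21
MIN_CLIP = 25

STATUS_UNIQUE = 0
STATUS_AMBIGUOUS = 1
STATUS_CLIPPED = 2
STATUS_UNMAPPED = 3
STATUS_NAMES = {0: "unique", 1: "ambiguous", 2: "clipped", 3: "unmapped"}


class ReferenceIndex:
    """Concatenated reference with a sorted 21-mer position index."""

    def __init__(self, sequences: dict[str, str], k: int = SEED_K):
        if not sequences or all(len(s) == 0 for s in sequences.values()):
            raise ValueError("empty reference")
        self.k = k
        self.chroms = list(sequences)
        lengths = [len(sequences[c]) for c in self.chroms]
        self.chrom_starts = np.concatenate([[0], np.cumsum(lengths)]).astype(np.int64)
        self.codes = np.concatenate([encode(sequences[c]) for c in self.chroms])
        keys, pos = [], []
        for ci, c in enumerate(self.chroms):
            arr = self.codes[self.chrom_starts[ci] : self.chrom_starts[ci + 1]].astype(
                np.int64
            )
            n = arr.size - k + 1
            if n <= 0:
                continue
            v = np.zeros(n, dtype=np.int64)
            for j in range(k):
                v = v * 4 + arr[j : j + n]
            keys.append(v)
            pos.append(np.arange(n, dtype=np.int64) + self.chrom_starts[ci])
        allk = np.concatenate(keys)
        allp = np.concatenate(pos)
        order = np.argsort(allk, kind="stable")
        self.kmer_keys = allk[order]
        self.kmer_pos = allp[order]

    # ------------------------------------------------------------------
    def chrom_of(self, gpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self.chrom_starts, gpos, side="right")) - 1
        return self.chroms[ci], int(gpos - self.chrom_starts[ci])

    def global_pos(self, chrom: str, pos: int) -> int:
        return int(self.chrom_starts[self.chroms.index(chrom)] + pos)

    def length(self, chrom: str) -> int:
        ci = self.chroms.index(chrom)
        return int(self.chrom_starts[ci + 1] - self.chrom_starts[ci])

    @classmethod
    def from_genome(cls, genome: GenomeModel, k: int = SEED_K) -> "ReferenceIndex":
        return cls(genome.reference(), k=k)


# ----------------------------------------------------------------- kernel
def _map_batch_py(
    ref,
    chrom_starts,
    keys,
    kpos,
    reads,
    k,
    max_mm,
    min_clip,
    status,
    gpos,
    strand,
    mismatches,
    span,
    clip_side,
    nplace,
):
    n_reads, L = reads.shape
    n_chrom = chrom_starts.shape[0] - 1
    seen_pos = np.empty(512, dtype=np.int64)
    seen_strand = np.empty(512, dtype=np.uint8)
    rc = np.empty(L, dtype=np.uint8)
    for i in range(n_reads):
        fwd = reads[i]
        for t in range(L):
            rc[t] = 3 - fwd[L - 1 - t]
        best_mm = max_mm + 1
        n_best = 0
        best_pos = np.int64(-1)
        best_strand = np.uint8(0)
        n_seen = 0
        for s in range(2):
            read = fwd if s == 0 else rc
            for oi in range(2):
                off = 0 if oi == 0 else L - k
                code = np.int64(0)
                for t in range(k):
                    code = code * 4 + read[off + t]
                lo = np.searchsorted(keys, code)
                hi = np.searchsorted(keys, code + 1)
                for q in range(lo, hi):
                    p = kpos[q] - off
                    # bounds: whole read inside one chromosome
                    ci = np.searchsorted(chrom_starts, p, side="right") - 1
                    if ci < 0 or ci >= n_chrom:
                        continue
                    if p < chrom_starts[ci] or p + L > chrom_starts[ci + 1]:
                        continue
                    dup = False
                    for t in range(n_seen):
                        if seen_pos[t] == p and seen_strand[t] == s:
                            dup = True
                            break
                    if dup:
                        continue
                    if n_seen < 512:
                        seen_pos[n_seen] = p
                        seen_strand[n_seen] = s
                        n_seen += 1
                    mm = 0
                    for t in range(L):
                        if ref[p + t] != read[t]:
                            mm += 1
                            if mm > max_mm:
                                break
                    if mm > max_mm:
                        continue
                    if mm < best_mm:
                        best_mm = mm
                        best_pos = p
                        best_strand = np.uint8(s)
                        n_best = 1
                    elif mm == best_mm:
                        n_best += 1
                        if p < best_pos:
                            best_pos = p
                            best_strand = np.uint8(s)
        if best_mm <= max_mm:
            status[i] = 0 if n_best == 1 else 1
            gpos[i] = best_pos
            strand[i] = best_strand
            mismatches[i] = best_mm
            span[i] = L
            clip_side[i] = -1
            nplace[i] = n_best
            continue
        # clipped: longest exact prefix/suffix >= min_clip on either strand
        best_len = 0
        best_cpos = np.int64(-1)
        best_cstrand = np.uint8(0)
        best_cside = np.int8(-1)
        for s in range(2):
            read = fwd if s == 0 else rc
            # prefix
            code = np.int64(0)
            for t in range(k):
                code = code * 4 + read[t]
            lo = np.searchsorted(keys, code)
            hi = np.searchsorted(keys, code + 1)
            for q in range(lo, hi):
                p = kpos[q]
                ci = np.searchsorted(chrom_starts, p, side="right") - 1
                if ci < 0 or ci >= n_chrom:
                    continue
                ce = chrom_starts[ci + 1]
                t = k
                while t < L and p + t < ce and ref[p + t] == read[t]:
                    t += 1
                if t > best_len:
                    best_len = t
                    best_cpos = p
                    best_cstrand = np.uint8(s)
                    best_cside = np.int8(0)
            # suffix
            code = np.int64(0)
            for t in range(k):
                code = code * 4 + read[L - k + t]
            lo = np.searchsorted(keys, code)
            hi = np.searchsorted(keys, code + 1)
            for q in range(lo, hi):
                p = kpos[q]
                ci = np.searchsorted(chrom_starts, p, side="right") - 1
                if ci < 0 or ci >= n_chrom:
                    continue
                cs = chrom_starts[ci]
                m = 0
                while L - k - 1 - m >= 0 and p - 1 - m >= cs and ref[p - 1 - m] == read[L - k - 1 - m]:
                    m += 1
                if k + m > best_len:
                    best_len = k + m
                    best_cpos = p - m
                    best_cstrand = np.uint8(s)
                    best_cside = np.int8(1)
        if best_len >= min_clip:
            status[i] = 2
            gpos[i] = best_cpos
            strand[i] = best_cstrand
            mismatches[i] = 0
            span[i] = best_len
            clip_side[i] = best_cside
            nplace[i] = 1
        else:
            status[i] = 3
            gpos[i] = -1
            strand[i] = 0
            mismatches[i] = -1
            span[i] = 0
            clip_side[i] = -1
            nplace[i] = 0


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _map_batch = njit(cache=True)(_map_batch_py)
except Exception:  # pragma: no cover
    _map_batch = _map_batch_py


# ------------------------------------------------------------------ result
@dataclass
class AlignmentSet:
    """Per-read placement records over the collapsed haploid reference."""

    index: ReferenceIndex
    status: np.ndarray  # uint8 codes, see STATUS_NAMES
    gpos: np.ndarray  # int64 global start of the mapped span (-1 if unmapped)
    strand: np.ndarray  # 0 = forward, 1 = reverse
    mismatches: np.ndarray
    span: np.ndarray  # mapped span length (read length if full)
    clip_side: np.ndarray  # 0 prefix maps, 1 suffix maps, -1 not clipped
    n_placements: np.ndarray
    max_mismatches: int
    read_length: int

    def __len__(self) -> int:
        return self.status.shape[0]

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.status == code)) for code, name in STATUS_NAMES.items()
        }

    def is_breakpoint_evidence(self) -> np.ndarray:
        return (self.status == STATUS_CLIPPED) | (self.status == STATUS_UNMAPPED)

    def to_sam(self, path, reads: ReadSet) -> None:
        from .io import write_sam

        write_sam(path, self, reads)


def map_reads(
    reads: ReadSet,
    reference: ReferenceIndex | GenomeModel | dict,
    max_mismatches: int | None = None,
) -> AlignmentSet:
    """Map every read; the default mismatch budget is 3 per 100 nt of read."""
    if isinstance(reference, GenomeModel):
        index = ReferenceIndex.from_genome(reference)
    elif isinstance(reference, dict):
        index = ReferenceIndex(reference)
    else:
        index = reference
    L = reads.read_length
    if max_mismatches is None:
        max_mismatches = int(round(3 * L / 100))
    n = len(reads)
    status = np.empty(n, dtype=np.uint8)
    gpos = np.empty(n, dtype=np.int64)
    strand = np.empty(n, dtype=np.uint8)
    mismatches = np.empty(n, dtype=np.int16)
    span = np.empty(n, dtype=np.int32)
    clip_side = np.empty(n, dtype=np.int8)
    nplace = np.empty(n, dtype=np.int32)
    if n:
        _map_batch(
            index.codes,
            index.chrom_starts,
            index.kmer_keys,
            index.kmer_pos,
            np.ascontiguousarray(reads.codes),
            index.k,
            max_mismatches,
            MIN_CLIP,
            status,
            gpos,
            strand,
            mismatches,
            span,
            clip_side,
            nplace,
        )
    return AlignmentSet(
        index=index,
        status=status,
        gpos=gpos,
        strand=strand,
        mismatches=mismatches,
        span=span,
        clip_side=clip_side,
        n_placements=nplace,
        max_mismatches=max_mismatches,
        read_length=L,
    )
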