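"""Shotgun single-end read simulation from a (possibly amplified) genome.

Emulates uniform-coverage short-read sequencing: fixed read length,
substitution-only errors, constant base quality (Phred 40).  Start
positions are uniform over all homologues and episome copies, so a
segment present at ``c`` copies receives ``c/2`` times the diploid depth
— the signal the coverage pipeline reads out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import decode, encode
from .genome import GenomeModel

PHRED_CHAR = "I"  # Phred 40, Sanger offset 33


@dataclass
class ReadSet:
    """Simulated reads with their (synthetic-truth) origins."""

    codes: np.ndarray  # (n_reads, read_length) uint8, as-sequenced orientation
    read_length: int
    error_rate: float
    depth: float
    seed: int
    replicon_names: list[str] = field(default_factory=list)
    src_replicon: np.ndarray | None = None  # truth: replicon index per read
    src_pos: np.ndarray | None = None  # truth: start on the source replicon
    src_strand: np.ndarray | None = None  # truth: 0 = forward, 1 = reverse
    names: list[str] | None = None  # defaults to read000001...

    def __len__(self) -> int:
        return self.codes.shape[0]

    def name(self, i: int) -> str:
        if self.names is not None:
            return self.names[i]
        return f"read{i + 1:07d}"

    def sequence(self, i: int) -> str:
        return decode(self.codes[i])

    def subset(self, indices: np.ndarray) -> "ReadSet":
        idx = np.asarray(indices)
        return ReadSet(
            codes=self.codes[idx],
            read_length=self.read_length,
            error_rate=self.error_rate,
            depth=self.depth,
            seed=self.seed,
            replicon_names=self.replicon_names,
            src_replicon=None if self.src_replicon is None else self.src_replicon[idx],
            src_pos=None if self.src_pos is None else self.src_pos[idx],
            src_strand=None if self.src_strand is None else self.src_strand[idx],
            names=[self.name(int(i)) for i in idx],
        )

    def to_fastq(self, path) -> None:
        qual = PHRED_CHAR * self.read_length
        with open(path, "w") as fh:
            for i in range(len(self)):
                fh.write(f"@{self.name(i)}\n{self.sequence(i)}\n+\n{qual}\n")

    @classmethod
    def from_fastq(cls, path) -> "ReadSet":
        names, rows = [], []
        with open(path) as fh:
            while True:
                header = fh.readline().strip()
                if not header:
                    break
                seq = fh.readline().strip()
                fh.readline()
                fh.readline()
                names.append(header[1:].split()[0])
                rows.append(encode(seq))
        codes = np.vstack(rows) if rows else np.empty((0, 0), dtype=np.uint8)
        return cls(
            codes=codes,
            read_length=codes.shape[1] if rows else 0,
            error_rate=float("nan"),
            depth=float("nan"),
            seed=0,
            names=names,
        )


def _replicons(genome: GenomeModel):
    """(name, codes, circular, weight) for every distinct replicon."""
    out = []
    for hom in genome.homologues:
        out.append((f"{hom.chrom}#{hom.index}", encode(hom.seq), False, 1))
    for epi in genome.episomes:
        if epi.copies > 0:
            out.append((epi.name, encode(epi.seq), True, epi.copies))
    return out


def simulate_reads(
    genome: GenomeModel,
    depth: float,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Uniformly sample ``round(depth * total_length / read_length)`` reads.

    Episome copy number weights the sampling, and reads from circular
    replicons may wrap around the origin.  Deterministic for a fixed seed.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if read_length < 50:
        raise ValueError("read_length must be >= 50")
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must lie in [0, 0.05]")

    reps = _replicons(genome)
    shortest = min(len(codes) for _, codes, _, _ in reps)
    if read_length > shortest:
        raise ValueError(
            f"read_length {read_length} exceeds the shortest replicon ({shortest} nt)"
        )

    total = sum(len(codes) * w for _, codes, _, w in reps)
    n_reads = int(round(depth * total / read_length))
    rng = np.random.default_rng(seed)

    weights = np.array([len(codes) * w for _, codes, _, w in reps], dtype=float)
    rep_idx = rng.choice(len(reps), size=n_reads, p=weights / weights.sum())
    u = rng.random(n_reads)
    strands = rng.integers(0, 2, size=n_reads).astype(np.uint8)

    starts = np.zeros(n_reads, dtype=np.int64)
    mat = np.empty((n_reads, read_length), dtype=np.uint8)
    offsets = np.arange(read_length)
    for r, (_, codes, circular, _) in enumerate(reps):
        sel = np.flatnonzero(rep_idx == r)
        if sel.size == 0:
            continue
        span = len(codes) if circular else len(codes) - read_length + 1
        st = np.minimum((u[sel] * span).astype(np.int64), span - 1)
        starts[sel] = st
        pos = st[:, None] + offsets
        if circular:
            pos %= len(codes)
        mat[sel] = codes[pos]

    rev = strands == 1
    mat[rev] = 3 - mat[rev][:, ::-1]

    if error_rate > 0:
        n_err = rng.binomial(n_reads * read_length, error_rate)
        flat = rng.integers(0, n_reads * read_length, size=n_err)
        shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
        mat.reshape(-1)[flat] = (mat.reshape(-1)[flat] + shift) % 4

    return ReadSet(
        codes=mat,
        read_length=read_length,
        error_rate=error_rate,
        depth=depth,
        seed=seed,
        replicon_names=[name for name, _, _, _ in reps],
        src_replicon=rep_idx.astype(np.int32),
        src_pos=starts,
        src_strand=strands,
    )
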