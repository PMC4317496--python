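"""Pileup-based point-variant screen.

Implements the diploid short-read SNV filter used for the evolved-strain
screen: a call requires depth >= 5 and variant allele frequency >= 0.2
(strains are diploid); inside designated amplicon intervals both floors are
dropped, because an allele carried by a subset of array copies can sit at
an arbitrarily low frequency.  Calls in masked repeat regions are removed
(the masked fraction is reported), and candidates shared by every strain
of an experiment are classified as reference errors (homozygous in all)
or strain-construction events (heterozygous in all) and set aside.
Zygosity is cut at VAF 0.75, the midpoint between the heterozygous (0.5)
and homozygous (1.0) expectations; when depth >= 10 a call additionally
needs supporting reads on both strands (PCR-bias guard).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapping import STATUS_UNIQUE, AlignmentSet
from .reads import ReadSet

BASES = "ACGT"


@dataclass(frozen=True)
class PileupColumn:
    chrom: str
    pos: int
    ref_base: str
    counts: tuple[int, int, int, int]  # A, C, G, T
    fwd_counts: tuple[int, int, int, int]

    @property
    def depth(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    depth: int
    vaf: float
    zygosity: str  # het | hom
    region_mode: str  # standard | amplicon
    strain: str = ""

    def __post_init__(self):
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError("VAF must lie in [0, 1]")


def pileup_counts(alignments: AlignmentSet, reads: ReadSet) -> list[PileupColumn]:
    """Per-position base counts from uniquely mapped reads only.

    Zero-coverage positions are omitted (sparse convention).
    """
    index = alignments.index
    total = int(index.chrom_starts[-1])
    counts = np.zeros((4, total), dtype=np.int32)
    fwd = np.zeros((4, total), dtype=np.int32)
    L = alignments.read_length
    offs = np.arange(L)
    sel = np.flatnonzero(alignments.status == STATUS_UNIQUE)
    if sel.size:
        starts = alignments.gpos[sel]
        strands = alignments.strand[sel]
        mat = reads.codes[sel].astype(np.int64)
        rev = strands == 1
        mat[rev] = 3 - mat[rev][:, ::-1]  # orient to the reference strand
        pos = starts[:, None] + offs
        np.add.at(counts, (mat.reshape(-1), pos.reshape(-1)), 1)
        if np.any(~rev):
            np.add.at(
                fwd,
                (mat[~rev].reshape(-1), pos[~rev].reshape(-1)),
                1,
            )
    covered = np.flatnonzero(counts.sum(axis=0) > 0)
    out = []
    for g in covered:
        chrom, p = index.chrom_of(int(g))
        out.append(
            PileupColumn(
                chrom=chrom,
                pos=p,
                ref_base=BASES[int(index.codes[g])],
                counts=tuple(int(x) for x in counts[:, g]),
                fwd_counts=tuple(int(x) for x in fwd[:, g]),
            )
        )
    return out


def call_variants(
    columns: list[PileupColumn],
    min_depth: int = 5,
    min_vaf: float = 0.2,
    mode: str = "standard",
    amplicon_intervals: dict[str, list[tuple[int, int]]] | None = None,
    hom_cutoff: float = 0.75,
    strand_check_depth: int = 10,
    strain: str = "",
) -> list[VariantCall]:
    """Emit the most frequent non-reference base where thresholds hold.

    ``mode='amplicon'`` (or positions inside ``amplicon_intervals``) drops
    both the depth and the frequency floor.
    """
    calls = []
    for col in columns:
        ref_i = BASES.index(col.ref_base)
        alts = [(c, i) for i, c in enumerate(col.counts) if i != ref_i and c > 0]
        if not alts:
            continue
        alt_count, alt_i = max(alts)
        depth = col.depth
        vaf = alt_count / depth
        in_amplicon = mode == "amplicon" or (
            amplicon_intervals is not None
            and any(
                s <= col.pos < e
                for s, e in amplicon_intervals.get(col.chrom, [])
            )
        )
        if not in_amplicon:
            if depth < min_depth or vaf < min_vaf:
                continue
            if depth >= strand_check_depth:
                fwd_alt = col.fwd_counts[alt_i]
                if fwd_alt == 0 or fwd_alt == alt_count:
                    continue  # all support on one strand
        calls.append(
            VariantCall(
                chrom=col.chrom,
                pos=col.pos,
                ref_base=col.ref_base,
                alt_base=BASES[alt_i],
                depth=depth,
                vaf=vaf,
                zygosity="hom" if vaf >= hom_cutoff else "het",
                region_mode="amplicon" if in_amplicon else "standard",
                strain=strain,
            )
        )
    return calls


def apply_repeat_mask(
    calls: list[VariantCall],
    mask: dict[str, list[tuple[int, int]]],
    chrom_lengths: dict[str, int],
) -> tuple[list[VariantCall], dict]:
    """Remove calls in masked intervals; report the masked genome fraction."""
    kept = [
        c
        for c in calls
        if not any(s <= c.pos < e for s, e in mask.get(c.chrom, []))
    ]
    total = sum(chrom_lengths.values())
    masked = sum(e - s for ivs in mask.values() for s, e in ivs)
    report = {
        "masked_bp": masked,
        "genome_bp": total,
        "masked_fraction": masked / total if total else 0.0,
        "removed_calls": len(calls) - len(kept),
    }
    return kept, report


def cross_strain_classify(call_sets: dict[str, list[VariantCall]]) -> pd.DataFrame:
    """Classify candidates shared across strains.

    Present in ALL strains and homozygous in all -> ``reference_error``;
    heterozygous in all -> ``construction_event`` (both excluded from the
    evolved-mutation report); otherwise ``strain_specific`` and retained.
    """
    if len(call_sets) < 2:
        raise ValueError("cross-strain classification needs >= 2 strains")
    strains = sorted(call_sets)
    by_key: dict[tuple, dict[str, VariantCall]] = {}
    for strain in strains:
        for c in call_sets[strain]:
            by_key.setdefault((c.chrom, c.pos, c.alt_base), {})[strain] = c
    rows = []
    for (chrom, pos, alt), hits in sorted(by_key.items()):
        zygs = {hits[s].zygosity for s in hits}
        if len(hits) == len(strains):
            if zygs == {"hom"}:
                label, retained = "reference_error", False
            elif zygs == {"het"}:
                label, retained = "construction_event", False
            else:
                label, retained = "strain_specific", True  # mixed zygosity
        else:
            label, retained = "strain_specific", True
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "alt": alt,
                "n_strains": len(hits),
                "strains": ",".join(sorted(hits)),
                "zygosities": ",".join(sorted(zygs)),
                "label": label,
                "retained": retained,
            }
        )
    return pd.DataFrame(rows)
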