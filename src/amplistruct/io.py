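"""File-format interchange: FASTA/FASTQ/GFF3/BED/bedGraph/SAM/VCF/TSV.

Library conventions: coordinates are 0-based half-open internally; GFF3 is
written 1-based inclusive, BED/bedGraph 0-based half-open.  FASTA goes
through Biopython, SAM through pysam; the remaining formats are simple
line-oriented writers.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage import CoverageProfile, SegmentCall
from .genome import Feature, GenomeModel
from .junctions import BreakpointCall, JunctionContig
from .structures import StructureCall


# ------------------------------------------------------------------ FASTA
def write_fasta(path, sequences: dict[str, str], width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_genome_fasta(path, genome: GenomeModel) -> None:
    seqs = {f"{h.chrom}#{h.index}": h.seq for h in genome.homologues}
    for epi in genome.episomes:
        seqs[epi.name] = epi.seq
    write_fasta(path, seqs)


def write_reference_fasta(path, genome: GenomeModel) -> None:
    write_fasta(path, genome.reference())


# ------------------------------------------------------------- GFF3 / BED
def write_gff3(path, features: list[Feature]) -> None:
    type_map = {
        "gene": "gene",
        "centromere": "centromere",
        "LTR": "long_terminal_repeat",
        "Ty": "mobile_genetic_element",
        "repeat_mask": "repeat_region",
    }
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(sorted(features, key=lambda x: (x.chrom, x.start))):
            attrs = f"ID={f.kind}{i + 1}"
            if f.family:
                attrs += f";family={f.family};identity={f.identity:.3f}"
            fh.write(
                f"{f.chrom}\tamplistruct\t{type_map[f.kind]}\t{f.start + 1}\t{f.end}\t"
                f".\t{f.strand}\t.\t{attrs}\n"
            )


def write_bed(path, intervals: dict[str, list[tuple[int, int]]], name: str = "mask") -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for s, e in sorted(intervals[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            out.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    return out


def write_bedgraph(path, profile: CoverageProfile, which: str = "cn") -> None:
    arrays = profile.cn if which == "cn" else profile.depth
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{which}"\n')
        for chrom, arr in arrays.items():
            start = 0
            for i in range(1, arr.size + 1):
                if i == arr.size or arr[i] != arr[start]:
                    fh.write(f"{chrom}\t{start}\t{i}\t{arr[start]:.4f}\n")
                    start = i


# -------------------------------------------------------------------- SAM
def write_sam(path, alignments, reads) -> None:
    import pysam

    from ._util import revcomp
    from .mapping import (
        STATUS_AMBIGUOUS,
        STATUS_CLIPPED,
        STATUS_UNIQUE,
        STATUS_UNMAPPED,
    )

    index = alignments.index
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [
                {"SN": c, "LN": index.length(c)} for c in index.chroms
            ],
        }
    )
    L = alignments.read_length
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for i in range(len(alignments)):
            a = pysam.AlignedSegment(header)
            a.query_name = reads.name(i)
            seq = reads.sequence(i)
            status = int(alignments.status[i])
            if status == STATUS_UNMAPPED:
                a.flag = 4
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * L)
                out.write(a)
                continue
            strand = int(alignments.strand[i])
            a.flag = 16 if strand else 0
            chrom, pos = index.chrom_of(int(alignments.gpos[i]))
            a.reference_id = index.chroms.index(chrom)
            a.reference_start = pos
            a.mapping_quality = 0 if status == STATUS_AMBIGUOUS else 60
            span = int(alignments.span[i])
            if status == STATUS_CLIPPED:
                side = int(alignments.clip_side[i])
                cigar = (
                    [(0, span), (4, L - span)] if side == 0 else [(4, L - span), (0, span)]
                )
            else:
                cigar = [(0, L)]
            a.cigartuples = cigar
            a.query_sequence = revcomp(seq) if strand else seq
            a.query_qualities = pysam.qualitystring_to_array("I" * L)
            out.write(a)


# -------------------------------------------------------------------- VCF
def write_vcf(path, calls, chrom_lengths: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Variant allele frequency">\n')
        fh.write('##INFO=<ID=ZYG,Number=1,Type=String,Description="het or hom">\n')
        fh.write('##INFO=<ID=MODE,Number=1,Type=String,Description="standard or amplicon">\n')
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda v: (v.chrom, v.pos)):
            info = f"DP={c.depth};AF={c.vaf:.4f};ZYG={c.zygosity};MODE={c.region_mode}"
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref_base}\t{c.alt_base}\t.\tPASS\t{info}\n"
            )


# -------------------------------------------------------------------- TSV
def segments_to_frame(segments: list[SegmentCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "level": s.level,
                "extra": s.extra,
                "mean_cn": round(s.mean_cn, 4),
            }
            for s in segments
        ]
    )


def breakpoints_to_frame(calls: list[BreakpointCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom_l": b.chrom_l,
                "pos_l": b.pos_l,
                "strand_l": b.strand_l,
                "chrom_r": b.chrom_r,
                "pos_r": b.pos_r,
                "strand_r": b.strand_r,
                "orientation": b.orientation,
                "microhomology": b.microhomology,
                "inserted": b.inserted,
                "arm": b.palindrome.arm if b.palindrome else 0,
                "center": b.palindrome.center if b.palindrome else 0,
                "class": b.junction_class,
                "n_reads": b.n_reads,
                "contig": b.contig_id,
            }
            for b in calls
        ]
    )


def structures_to_frame(calls: list[StructureCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class": s.structure_class,
                "chrom": s.chrom,
                "unit_start": s.unit[0],
                "unit_end": s.unit[1],
                "effective_unit_nt": s.effective_unit_length,
                "extra_copies": s.extra_copies,
                "deletion": "" if s.deletion is None else f"{s.deletion[0]}-{s.deletion[1]}",
                "centromere_in_unit": s.centromere_in_unit,
                "predicted_kb": ";".join(f"{x:.1f}" for x in s.predicted_sizes_kb),
                "junctions": ";".join(s.junction_ids),
            }
            for s in calls
        ]
    )


def write_contigs_fasta(path, contigs: list[JunctionContig]) -> None:
    write_fasta(path, {c.contig_id: c.sequence for c in contigs})
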