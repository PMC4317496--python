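"""Toy diploid genome construction with planted annotation features.

The generator emulates the statistical structure of a small budding-yeast
genome: random background sequence, a single centromere per chromosome,
and families of dispersed repeats (solo LTRs and full-length transposon
analogues) whose members are derived from a family consensus by seeded
point mutation so that a requested pairwise sequence identity is achieved.
Both homologues of a diploid pair start identical except for explicitly
planted heterozygous variants.

Coordinates are 0-based half-open throughout the library; GFF3 output is
1-based inclusive and BED output 0-based half-open (see :mod:`amplistruct.io`).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from ._util import encode, mutate_positions, random_seq

FEATURE_KINDS = ("gene", "centromere", "LTR", "Ty", "repeat_mask")


@dataclass(frozen=True)
class Feature:
    """An annotated interval on the (reference coordinate) genome."""

    kind: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    family: str = ""
    identity: float = 1.0

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.start < self.end:
            raise ValueError(f"empty feature interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class Homologue:
    chrom: str
    index: int
    seq: str


@dataclass(frozen=True)
class Episome:
    """A circular extrachromosomal replicon carried at a fixed per-cell copy number."""

    name: str
    seq: str
    copies: int
    source_chrom: str = ""
    source_interval: tuple[int, int] | None = None


@dataclass
class GenomeModel:
    """Homologue sequences plus planted features for a toy diploid genome."""

    homologues: list[Homologue]
    features: list[Feature]
    ploidy: int = 2
    seed: int = 0
    episomes: list[Episome] = field(default_factory=list)

    # ------------------------------------------------------------------ views
    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for h in self.homologues:
            seen.setdefault(h.chrom, None)
        return list(seen)

    def homologue(self, chrom: str, index: int) -> Homologue:
        for h in self.homologues:
            if h.chrom == chrom and h.index == index:
                return h
        raise KeyError(f"no homologue {index} of chromosome {chrom!r}")

    def reference(self) -> dict[str, str]:
        """Collapsed haploid reference: homologue 0 of each chromosome.

        By convention amplifications target homologue indices >= 1, so
        homologue 0 always carries the unrearranged reference sequence.
        """
        return {c: self.homologue(c, 0).seq for c in self.chromosomes}

    def chrom_features(self, chrom: str, kind: str | None = None) -> list[Feature]:
        return [
            f
            for f in self.features
            if f.chrom == chrom and (kind is None or f.kind == kind)
        ]

    def total_length(self) -> int:
        n = sum(len(h.seq) for h in self.homologues)
        n += sum(len(e.seq) * e.copies for e in self.episomes)
        return n

    def checksum(self) -> str:
        h = hashlib.sha256()
        for hom in sorted(self.homologues, key=lambda x: (x.chrom, x.index)):
            h.update(f">{hom.chrom}#{hom.index}\n{hom.seq}\n".encode())
        for epi in self.episomes:
            h.update(f">{epi.name}x{epi.copies}\n{epi.seq}\n".encode())
        return h.hexdigest()

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        lengths = {c: len(self.homologue(c, 0).seq) for c in self.chromosomes}
        for f in self.features:
            if f.chrom not in lengths:
                raise ValueError(f"feature on unknown chromosome {f.chrom!r}")
            if f.end > lengths[f.chrom]:
                raise ValueError(
                    f"{f.kind} [{f.start}, {f.end}) exceeds {f.chrom} length {lengths[f.chrom]}"
                )
        for c in self.chromosomes:
            cens = self.chrom_features(c, "centromere")
            if len(cens) != 1:
                raise ValueError(f"chromosome {c!r} has {len(cens)} centromeres (need 1)")
        _check_same_kind_overlaps(self.features)
        for h in self.homologues:
            encode(h.seq)  # raises on non-ACGT

    def with_homologue(self, chrom: str, index: int, seq: str) -> "GenomeModel":
        homs = [
            replace(h, seq=seq) if (h.chrom == chrom and h.index == index) else h
            for h in self.homologues
        ]
        return replace(self, homologues=homs)


def _check_same_kind_overlaps(features: list[Feature]) -> None:
    by_key: dict[tuple[str, str], list[Feature]] = {}
    for f in features:
        by_key.setdefault((f.chrom, f.kind), []).append(f)
    for feats in by_key.values():
        feats = sorted(feats, key=lambda f: f.start)
        for a, b in zip(feats, feats[1:]):
            if a.overlaps(b.start, b.end):
                raise ValueError(
                    f"overlapping {a.kind} features on {a.chrom}: "
                    f"[{a.start}, {a.end}) and [{b.start}, {b.end})"
                )


# ---------------------------------------------------------------------- plans
@dataclass(frozen=True)
class FeaturePlan:
    """A feature to plant: where it goes and, for repeats, its family identity."""

    kind: str
    start: int
    end: int
    strand: str = "+"
    family: str = ""
    identity: float = 1.0


@dataclass(frozen=True)
class ChromosomePlan:
    name: str
    length: int
    features: tuple[FeaturePlan, ...] = ()


@dataclass(frozen=True)
class ReferenceConfig:
    chromosomes: tuple[ChromosomePlan, ...]
    seed: int
    ploidy: int = 2
    # heterozygous variants planted on homologue 1: (chrom, pos, alt_base)
    het_variants: tuple[tuple[str, int, str], ...] = ()

    MIN_CHROM_LEN = 10_000


def build_reference(config: ReferenceConfig) -> GenomeModel:
    """Build a deterministic toy diploid genome from a chromosome/feature plan.

    Repeat (LTR/Ty) family members on the same chromosome set are derived
    from one consensus per family: the first member is the consensus itself
    and later members carry seeded substitutions, so a two-member family
    realizes the requested pairwise identity exactly (up to rounding to a
    whole number of substitutions).
    """
    rng = np.random.default_rng(config.seed)
    homologues: list[Homologue] = []
    features: list[Feature] = []

    # repeat families are shared across chromosomes
    plans_by_family: dict[str, list[tuple[str, FeaturePlan]]] = {}
    for chrom in config.chromosomes:
        for fp in chrom.features:
            if fp.kind in ("LTR", "Ty") and fp.family:
                plans_by_family.setdefault(fp.family, []).append((chrom.name, fp))

    family_seqs: dict[tuple[str, int], str] = {}
    for fam, members in plans_by_family.items():
        length = members[0][1].end - members[0][1].start
        for _, fp in members:
            if fp.end - fp.start != length:
                raise ValueError(
                    f"family {fam!r} members must share one length "
                    f"(got {fp.end - fp.start} vs {length})"
                )
        consensus = random_seq(rng, length)
        for i, (_, fp) in enumerate(members):
            if i == 0:
                family_seqs[(fam, 0)] = consensus
            else:
                n_mut = round((1.0 - fp.identity) * length)
                pos = rng.choice(length, size=n_mut, replace=False)
                family_seqs[(fam, i)] = mutate_positions(consensus, pos, rng)

    for chrom in config.chromosomes:
        if chrom.length < config.MIN_CHROM_LEN:
            raise ValueError(
                f"chromosome {chrom.name!r} length {chrom.length} < "
                f"{config.MIN_CHROM_LEN} minimum"
            )
        seq = list(random_seq(rng, chrom.length))
        fam_counter: dict[str, int] = {}
        for fp in chrom.features:
            if fp.end > chrom.length:
                raise ValueError(
                    f"{fp.kind} [{fp.start}, {fp.end}) exceeds "
                    f"{chrom.name} length {chrom.length}"
                )
            if fp.kind in ("LTR", "Ty") and fp.family:
                idx = _family_index(plans_by_family[fp.family], chrom.name, fp)
                member = family_seqs[(fp.family, idx)]
                if fp.strand == "-":
                    from ._util import revcomp

                    member = revcomp(member)
                seq[fp.start : fp.end] = member
                fam_counter[fp.family] = fam_counter.get(fp.family, 0) + 1
            features.append(
                Feature(fp.kind, chrom.name, fp.start, fp.end, fp.strand, fp.family, fp.identity)
            )
        base = "".join(seq)
        for idx in range(config.ploidy):
            homologues.append(Homologue(chrom.name, idx, base))

    genome = GenomeModel(
        homologues=homologues, features=features, ploidy=config.ploidy, seed=config.seed
    )
    for chrom_name, pos, alt in config.het_variants:
        hom = genome.homologue(chrom_name, 1)
        if hom.seq[pos] == alt:
            raise ValueError(f"variant at {chrom_name}:{pos} equals the reference base")
        genome = genome.with_homologue(
            chrom_name, 1, hom.seq[:pos] + alt + hom.seq[pos + 1 :]
        )
    genome.validate()
    return genome


def _family_index(members: list[tuple[str, FeaturePlan]], chrom: str, fp: FeaturePlan) -> int:
    for i, (c, m) in enumerate(members):
        if c == chrom and m == fp:
            return i
    raise KeyError("feature plan not registered in its family")


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    ca, cb = encode(a), encode(b)
    return float(np.mean(ca == cb))
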