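"""Apply amplification events to a toy genome, with exact truth bookkeeping.

Five structure classes are modelled, mirroring the amplification classes
seen in serial-transfer yeast evolution experiments:

``direct_tandem``
    E extra copies of a chromosomal unit inserted in loco, head-to-tail,
    adjacent to the original copy; the unit may carry an internal deletion
    (the pericentromeric-deletion case) with its own junction geometry.
``inverted_tandem``
    E extra copies alternating orientation (U, rc(U), U, ...), each interface
    carrying a quasi-palindromic junction: a short unique center flanked by
    reverse-complementary arms.
``episome``
    A circular extrachromosomal replicon of the unit sequence, present at a
    fixed per-cell copy number; chromosomes are left untouched.
``segmental_duplication``
    The E = 1 special case of a direct tandem whose junction anchors fall in
    flanking dispersed-repeat (LTR/Ty) features.
``aneuploidy``
    A whole extra homologue.

Junction microhomology is realized by *planting* the shared segment into the
reference sequence around the junction donor sites (identically on every
homologue, so the mapping reference sees it too) and then joining copies by
plain concatenation at the cut points.  The breakpoint-ambiguity window of
the realized junction therefore equals the planted homology length exactly,
while length bookkeeping stays exact: an intrachromosomal event adds
``extra_copies x effective_unit_length`` nucleotides (plus the inserted
junction centers for inverted arrays).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._util import other_base, random_seq, revcomp
from .genome import Episome, GenomeModel, Homologue

STRUCTURE_CLASSES = (
    "direct_tandem",
    "inverted_tandem",
    "episome",
    "segmental_duplication",
    "aneuploidy",
)

JUNCTION_MODES = ("no_homology", "microhomology", "quasi_palindrome")

@dataclass(frozen=True)
class JunctionGeometry:
    """How the two donor sequences meet at a junction."""

    mode: str = "no_homology"
    microhomology: int = 0
    arm: int = 0
    center: int = 0

    def __post_init__(self):
        if self.mode not in JUNCTION_MODES:
            raise ValueError(f"unknown junction mode {self.mode!r}")
        if self.microhomology < 0:
            raise ValueError("microhomology length must be >= 0")
        if self.mode == "no_homology" and self.microhomology not in (0, 1):
            # the single-shared-nucleotide case is representable as chance identity
            raise ValueError("no_homology junctions allow microhomology 0 or 1 only")
        if self.mode == "quasi_palindrome":
            if self.arm < 1:
                raise ValueError("quasi_palindrome requires arm length >= 1")
            if self.center < 0:
                raise ValueError("palindrome center length must be >= 0")


@dataclass(frozen=True)
class AmpliconSpec:
    """Ground-truth description of one amplification event."""

    structure_class: str
    chrom: str
    unit: tuple[int, int]
    extra_copies: int
    homologue: int = 1
    deletion: tuple[int, int] | None = None
    junction: JunctionGeometry = JunctionGeometry("no_homology", 1)
    deletion_junction: JunctionGeometry | None = None
    second_junction: JunctionGeometry | None = None
    insertion_side: str | None = None
    name: str = ""

    def __post_init__(self):
        if self.structure_class not in STRUCTURE_CLASSES:
            raise ValueError(f"unknown structure class {self.structure_class!r}")
        if self.extra_copies < 0:
            raise ValueError("extra_copies must be >= 0")
        a, b = self.unit
        if not a < b:
            raise ValueError("unit interval must be non-empty")
        if self.deletion is not None:
            c, d = self.deletion
            if not (a < c < d < b):
                raise ValueError(
                    f"internal deletion [{c}, {d}) must lie strictly inside unit [{a}, {b})"
                )
        if self.structure_class == "episome" and self.insertion_side is not None:
            raise ValueError("episome specs do not take an insertion side")
        if self.insertion_side not in (None, "left", "right"):
            raise ValueError("insertion_side must be 'left' or 'right'")
        if self.structure_class == "inverted_tandem":
            geoms = [self.junction] + ([self.second_junction] if self.second_junction else [])
            if not any(g.mode == "quasi_palindrome" for g in geoms):
                raise ValueError(
                    "inverted_tandem requires a quasi_palindrome geometry on at least one boundary"
                )
        if self.structure_class == "segmental_duplication" and self.extra_copies not in (0, 1):
            raise ValueError("segmental_duplication means exactly one extra copy")

    @property
    def unit_length(self) -> int:
        return self.unit[1] - self.unit[0]

    @property
    def deletion_length(self) -> int:
        return 0 if self.deletion is None else self.deletion[1] - self.deletion[0]

    @property
    def effective_unit_length(self) -> int:
        """Length each extra copy adds, junction centers excluded."""
        return self.unit_length - self.deletion_length

    @property
    def side(self) -> str:
        # in loco arrays default to the right of the original unit
        return self.insertion_side or "right"


@dataclass(frozen=True)
class TruthJunction:
    """One realized junction type (identical across array copies)."""

    kind: str  # tandem | deletion | circular | inverted | inverted_alt | inverted_flank
    chrom: str
    left_pos: int
    left_strand: str
    right_pos: int
    right_strand: str
    orientation: str  # direct | inverted
    microhomology: int | None
    arm: int = 0
    center: int = 0
    count: int = 1
    window_seq: str = ""

    @property
    def ambiguity(self) -> tuple[int, int]:
        """Reference window of equivalent left-anchor positions (canonical leftmost)."""
        h = self.microhomology or 0
        return (self.left_pos - h, self.left_pos)


@dataclass(frozen=True)
class AmplificationEvent:
    spec: AmpliconSpec
    junctions: tuple[TruthJunction, ...]
    effective_unit_length: int
    expected_homologue_length: int
    base_homologue_length: int
    episome_name: str = ""
    episome_length: int = 0
    episome_copies: int = 0


# --------------------------------------------------------------- planting
def _plant_microhomology(
    seq: list[str],
    cut_left: int,
    cut_right: int,
    h: int,
    rng: np.random.Generator,
    guard_left_at: int,
    guard_right_at: int,
) -> None:
    """Make the junction joining ``seq[:cut_left] + seq[cut_right:]``-style cuts
    carry an ambiguity window of exactly ``h`` nucleotides.

    Copies ``seq[cut_left-h:cut_left]`` over ``seq[cut_right-h:cut_right]`` and
    forces a mismatch immediately outside the window on both sides (mutating
    the designated guard positions only).
    """
    if h > 0:
        if cut_right - h < 0 or cut_left - h < 0:
            raise ValueError("microhomology window extends past the sequence start")
        seq[cut_right - h : cut_right] = seq[cut_left - h : cut_left]
    # block further left slide
    if seq[cut_left - h - 1] == seq[cut_right - h - 1]:
        keep = seq[cut_left - h - 1] if guard_left_at == cut_right - h - 1 else seq[cut_right - h - 1]
        seq[guard_left_at] = other_base(keep, rng=rng)
    # block right slide
    if seq[cut_left] == seq[cut_right]:
        keep = seq[cut_left] if guard_right_at == cut_right else seq[cut_right]
        seq[guard_right_at] = other_base(keep, rng=rng)


def _edit_all_homologues(genome: GenomeModel, chrom: str, edit) -> GenomeModel:
    """Apply ``edit(list_of_bases) -> None`` identically to every homologue of ``chrom``."""
    homs = []
    for hom in genome.homologues:
        if hom.chrom == chrom:
            chars = list(hom.seq)
            edit(chars)
            homs.append(replace(hom, seq="".join(chars)))
        else:
            homs.append(hom)
    return replace(genome, homologues=homs)


def _window(product: str, pos: int, radius: int = 200) -> str:
    return product[max(0, pos - radius) : pos + radius]


# ------------------------------------------------------------ application
def apply_amplification(
    genome: GenomeModel, spec: AmpliconSpec, seed: int | None = None
) -> tuple[GenomeModel, AmplificationEvent]:
    """Return a new genome carrying the event, plus its exact truth record.

    With ``extra_copies == 0`` the genome is returned unchanged (no junction
    homology is planted either, so the output is byte-identical).
    """
    rng = np.random.default_rng(genome.seed + 7919 if seed is None else seed)
    base_len = len(genome.homologue(spec.chrom, 0).seq)

    if spec.extra_copies == 0:
        event = AmplificationEvent(
            spec=spec,
            junctions=(),
            effective_unit_length=spec.effective_unit_length,
            expected_homologue_length=base_len,
            base_homologue_length=base_len,
        )
        return genome, event

    if spec.structure_class == "aneuploidy":
        return _apply_aneuploidy(genome, spec, base_len)
    if spec.structure_class == "episome":
        return _apply_episome(genome, spec, rng, base_len)
    if spec.structure_class == "inverted_tandem":
        return _apply_inverted(genome, spec, rng, base_len)
    return _apply_direct(genome, spec, rng, base_len)  # direct tandem / segmental dup


def _apply_aneuploidy(genome, spec, base_len):
    src = genome.homologue(spec.chrom, 0)
    new_index = max(h.index for h in genome.homologues if h.chrom == spec.chrom) + 1
    homs = list(genome.homologues)
    for _ in range(spec.extra_copies):
        homs.append(Homologue(spec.chrom, new_index, src.seq))
        new_index += 1
    event = AmplificationEvent(
        spec=spec,
        junctions=(),
        effective_unit_length=base_len,
        expected_homologue_length=base_len,
        base_homologue_length=base_len,
    )
    return replace(genome, homologues=homs), event


def _plant_boundary(genome, spec, rng) -> tuple[GenomeModel, int]:
    """Plant the unit-boundary junction homology; return genome and h."""
    a, b = spec.unit
    geom = spec.junction
    h = geom.microhomology if geom.mode in ("no_homology", "microhomology") else 0

    def edit(chars: list[str]) -> None:
        # junction joins ...seq[b-1] | seq[a]... ; homology planted in the
        # left flank P (outside the unit), guards mutate P/Q flank bases only
        _plant_microhomology(
            chars, cut_left=b, cut_right=a, h=h, rng=rng,
            guard_left_at=a - h - 1, guard_right_at=b,
        )

    return _edit_all_homologues(genome, spec.chrom, edit), h


def _plant_deletion(genome, spec, rng) -> tuple[GenomeModel, int]:
    c, d = spec.deletion
    geom = spec.deletion_junction or JunctionGeometry("no_homology", 0)
    h = geom.microhomology if geom.mode in ("no_homology", "microhomology") else 0
    if h + 1 > d - c:
        raise ValueError("deletion too short to carry its junction homology")

    def edit(chars: list[str]) -> None:
        # junction joins ...seq[c-1] | seq[d]...; homology and guards live in
        # the deleted interval so retained unit content is untouched
        _plant_microhomology(
            chars, cut_left=c, cut_right=d, h=h, rng=rng,
            guard_left_at=d - h - 1, guard_right_at=c,
        )

    return _edit_all_homologues(genome, spec.chrom, edit), h


def _apply_direct(genome, spec, rng, base_len):
    a, b = spec.unit
    E = spec.extra_copies
    genome, h_boundary = _plant_boundary(genome, spec, rng)
    h_del = None
    if spec.deletion is not None:
        genome, h_del = _plant_deletion(genome, spec, rng)

    ref = genome.homologue(spec.chrom, spec.homologue).seq
    c, d = spec.deletion if spec.deletion else (b, b)
    unit_eff = ref[a:c] + ref[d:b]
    if spec.side == "right":
        product = ref[:b] + unit_eff * E + ref[b:]
        first_tandem = b  # product coordinate of the first junction cut
    else:
        product = ref[:a] + unit_eff * E + ref[a:]
        first_tandem = a + len(unit_eff)

    junctions = [
        TruthJunction(
            kind="tandem",
            chrom=spec.chrom,
            left_pos=b - 1,
            left_strand="+",
            right_pos=a,
            right_strand="+",
            orientation="direct",
            microhomology=h_boundary,
            count=E,
            window_seq=_window(product, first_tandem),
        )
    ]
    if spec.deletion is not None:
        del_off = (first_tandem if spec.side == "right" else a) + (c - a)
        junctions.append(
            TruthJunction(
                kind="deletion",
                chrom=spec.chrom,
                left_pos=c - 1,
                left_strand="+",
                right_pos=d,
                right_strand="+",
                orientation="direct",
                microhomology=h_del,
                count=E,
                window_seq=_window(product, del_off),
            )
        )

    genome = genome.with_homologue(spec.chrom, spec.homologue, product)
    event = AmplificationEvent(
        spec=spec,
        junctions=tuple(junctions),
        effective_unit_length=spec.effective_unit_length,
        expected_homologue_length=base_len + E * spec.effective_unit_length,
        base_homologue_length=base_len,
    )
    assert len(product) == event.expected_homologue_length
    return genome, event


def _apply_episome(genome, spec, rng, base_len):
    a, b = spec.unit
    genome, h = _plant_boundary(genome, spec, rng)
    ref = genome.homologue(spec.chrom, spec.homologue).seq
    circle = ref[a:b]
    name = spec.name or f"episome_{spec.chrom}_{a}_{b}"
    epi = Episome(
        name=name,
        seq=circle,
        copies=spec.extra_copies,
        source_chrom=spec.chrom,
        source_interval=(a, b),
    )
    junction = TruthJunction(
        kind="circular",
        chrom=spec.chrom,
        left_pos=b - 1,
        left_strand="+",
        right_pos=a,
        right_strand="+",
        orientation="direct",
        microhomology=h,
        count=spec.extra_copies,
        window_seq=_window(circle + circle, len(circle)),
    )
    event = AmplificationEvent(
        spec=spec,
        junctions=(junction,),
        effective_unit_length=spec.effective_unit_length,
        expected_homologue_length=base_len,
        base_homologue_length=base_len,
        episome_name=name,
        episome_length=b - a,
        episome_copies=spec.extra_copies,
    )
    return replace(genome, episomes=[*genome.episomes, epi]), event


def _apply_inverted(genome, spec, rng, base_len):
    if spec.deletion is not None:
        raise ValueError("inverted_tandem with internal deletion is not modelled")
    if spec.side == "left":
        return _apply_inverted_left(genome, spec, rng, base_len)
    a, b = spec.unit
    E = spec.extra_copies
    geom_odd = spec.junction
    geom_even = spec.second_junction or spec.junction
    for g, label in ((geom_odd, "primary"), (geom_even, "second")):
        if g.mode != "quasi_palindrome":
            raise ValueError(f"{label} inverted-interface geometry must be quasi_palindrome")
        if g.arm + 1 >= b - a:
            raise ValueError("palindrome arm does not fit inside the unit")

    ref = genome.homologue(spec.chrom, spec.homologue).seq
    unit = ref[a:b]
    rc_unit = revcomp(unit)

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def make_center(n: int) -> str:
        # the center's outer bases must not complement each other, or the
        # scorer would find a smaller center with a longer arm
        c = list(random_seq(rng, n))
        if n >= 2 and c[-1] == comp[c[0]]:
            c[-1] = other_base(c[-1], avoid=comp[c[0]], rng=rng)
        return "".join(c)

    center_odd = make_center(geom_odd.center)
    center_even = make_center(geom_even.center)

    # interface j (1-based) joins copy j-1 (copy 0 = the original unit) to
    # inserted copy j; odd interfaces read U | center | rc(U), even ones
    # rc(U) | center | U.  Copies are exact reverse complements, so the
    # junction is palindromic to the full unit depth; the configured arm is
    # the *minimum guaranteed* arm, and a scorer sees the smaller of the
    # unit depth and its own window.
    pieces: list[str] = []
    junction_offsets: dict[str, int] = {}
    pos = b  # product coordinate tracker
    for j in range(1, E + 1):
        odd = j % 2 == 1
        center = center_odd if odd else center_even
        body = rc_unit if odd else unit
        piece = center + body
        pieces.append(piece)
        junction_offsets.setdefault("inverted" if odd else "inverted_alt", pos)
        pos += len(piece)

    product = ref[:b] + "".join(pieces) + ref[b:]
    flank_off = pos

    junctions = [
        TruthJunction(
            kind="inverted",
            chrom=spec.chrom,
            left_pos=b - 1,
            left_strand="+",
            right_pos=b - 1,
            right_strand="-",
            orientation="inverted",
            microhomology=0,
            arm=geom_odd.arm,
            center=geom_odd.center,
            count=(E + 1) // 2,
            window_seq=_window(product, junction_offsets.get("inverted", b)),
        )
    ]
    if E >= 2:
        junctions.append(
            TruthJunction(
                kind="inverted_alt",
                chrom=spec.chrom,
                left_pos=a,
                left_strand="-",
                right_pos=a,
                right_strand="+",
                orientation="inverted",
                microhomology=0,
                arm=geom_even.arm,
                center=geom_even.center,
                count=E // 2,
                window_seq=_window(product, junction_offsets.get("inverted_alt", b)),
            )
        )
    if E % 2 == 1:
        # array ends with an rc copy abutting the flank: a second, centre-less
        # inverted boundary junction (chance microhomology, not asserted)
        junctions.append(
            TruthJunction(
                kind="inverted_flank",
                chrom=spec.chrom,
                left_pos=a,
                left_strand="-",
                right_pos=b,
                right_strand="+",
                orientation="inverted",
                microhomology=None,
                count=1,
                window_seq=_window(product, flank_off),
            )
        )

    genome = genome.with_homologue(spec.chrom, spec.homologue, product)
    n_center = ((E + 1) // 2) * geom_odd.center + (E // 2) * geom_even.center
    event = AmplificationEvent(
        spec=spec,
        junctions=tuple(junctions),
        effective_unit_length=spec.effective_unit_length,
        expected_homologue_length=base_len + E * spec.effective_unit_length + n_center,
        base_homologue_length=base_len,
    )
    assert len(product) == event.expected_homologue_length
    return genome, event


def _apply_inverted_left(genome, spec, rng, base_len):
    """Left-side inverted array: the mirror image of the right-side product.

    Build the right-side array on the reverse-complemented chromosome, flip
    the product back, and transform the truth records (positions mirror,
    strands flip, the junction window reads in reverse complement — which
    is the same junction, seen from the other strand).
    """
    chrom_len = len(genome.homologue(spec.chrom, spec.homologue).seq)
    a, b = spec.unit
    mirror_unit = (chrom_len - b, chrom_len - a)

    mirror = genome
    homs = []
    for hom in mirror.homologues:
        homs.append(replace(hom, seq=revcomp(hom.seq)) if hom.chrom == spec.chrom else hom)
    mirror = replace(mirror, homologues=homs)

    sub = replace(spec, unit=mirror_unit, insertion_side="right")
    mirror, ev = _apply_inverted(mirror, sub, rng, base_len)

    homs = []
    for hom in mirror.homologues:
        homs.append(replace(hom, seq=revcomp(hom.seq)) if hom.chrom == spec.chrom else hom)
    result = replace(mirror, homologues=homs)

    flip = {"+": "-", "-": "+"}
    junctions = tuple(
        replace(
            j,
            left_pos=chrom_len - 1 - j.right_pos,
            left_strand=flip[j.right_strand],
            right_pos=chrom_len - 1 - j.left_pos,
            right_strand=flip[j.left_strand],
            window_seq=revcomp(j.window_seq),
        )
        for j in ev.junctions
    )
    event = replace(ev, spec=spec, junctions=junctions)
    return result, event
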