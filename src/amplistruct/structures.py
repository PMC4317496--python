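"""Integrate copy-number segments, junction calls and annotation into
amplification-structure calls, and check predicted karyotype sizes against
pulsed-field-gel style observations.

The classifier applies, per amplified region, the decision rules:

1. a whole-chromosome segment is an aneuploidy;
2. a unit whose retained (non-deleted) part contains the centromere and
   that carries a circularization junction is an episome — the centromere
   rule is hard: a centromere-containing unit can never be called a
   tandem array (a multicentric chromosome would be mitotically unstable);
3. a centromere-free unit with a direct tandem junction is a macrotene
   direct array (an internal-deletion junction shrinks the effective unit);
4. a centromere-free unit with an inverted boundary junction is a
   macrotene inverted array;
5. one extra copy joined between two dispersed-repeat features is a
   segmental duplication;
6. anything else is unclassified; contradictory evidence (a centromeric
   unit with a chromosomal tandem junction) yields ``conflict``, never a
   silent guess.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import SegmentCall
from .genome import Feature
from .junctions import BreakpointCall


@dataclass
class StructureCall:
    structure_class: str
    chrom: str
    unit: tuple[int, int]
    effective_unit_length: int
    extra_copies: int
    deletion: tuple[int, int] | None
    junction_ids: tuple[str, ...]
    centromere_in_unit: bool
    predicted_sizes_kb: tuple[float, ...]
    evidence: tuple[str, ...] = ()


@dataclass(frozen=True)
class KaryotypeObservation:
    chrom: str
    band_sizes_kb: tuple[float, ...]
    tolerance: float = 0.10

    def __post_init__(self):
        if any(s <= 0 for s in self.band_sizes_kb):
            raise ValueError("band sizes must be > 0")
        if not 0 < self.tolerance < 0.5:
            raise ValueError("tolerance must lie in (0, 0.5)")


def _centromeres(features, chrom):
    return [f for f in features if f.chrom == chrom and f.kind == "centromere"]


def _overlaps(f: Feature, start: int, end: int) -> bool:
    return f.start < end and start < f.end


def infer_structures(
    segments: list[SegmentCall],
    breakpoints: list[BreakpointCall],
    features: list[Feature],
    window: int = 1500,
    whole_chrom_fraction: float = 0.95,
) -> list[StructureCall]:
    """Apply the decision rules to every amplified region."""
    calls: list[StructureCall] = []
    tol = 2 * window
    chroms = sorted({s.chrom for s in segments})
    for chrom in chroms:
        segs = sorted((s for s in segments if s.chrom == chrom), key=lambda s: s.start)
        chrom_len = max(s.end for s in segs)
        amp = [s for s in segs if s.extra >= 1]
        if not amp:
            continue
        bps = [b for b in breakpoints if b.chrom_l == chrom and b.chrom_r == chrom]

        # rule 1: whole-chromosome amplification
        covered = sum(s.length for s in amp)
        if len(amp) >= 1 and covered >= whole_chrom_fraction * chrom_len:
            level = int(round(np.mean([s.level for s in amp])))
            calls.append(
                StructureCall(
                    structure_class="aneuploidy",
                    chrom=chrom,
                    unit=(0, chrom_len),
                    effective_unit_length=chrom_len,
                    extra_copies=level - 2,
                    deletion=None,
                    junction_ids=(),
                    centromere_in_unit=True,
                    predicted_sizes_kb=(chrom_len / 1000.0,) * (level - 1),
                    evidence=(f"whole-chromosome segment at level {level}",),
                )
            )
            continue

        # group same-level amplified segments bridged by internal-deletion calls
        units: list[dict] = []
        for s in amp:
            if units and units[-1]["level"] == s.level:
                gap = (units[-1]["end"], s.start)
                bridge = [
                    b
                    for b in bps
                    if b.junction_class == "internal_deletion"
                    and abs(b.pos_l - (gap[0] - 1)) <= tol + b.microhomology
                    and abs(b.pos_r - gap[1]) <= tol + b.microhomology
                ]
                if bridge:
                    units[-1]["end"] = s.end
                    units[-1]["deletion"] = gap
                    units[-1]["segments"].append(s)
                    units[-1]["junctions"] += [b.contig_id for b in bridge]
                    continue
            units.append(
                {
                    "start": s.start,
                    "end": s.end,
                    "level": s.level,
                    "deletion": None,
                    "segments": [s],
                    "junctions": [],
                }
            )

        for u in units:
            start, end, level = u["start"], u["end"], u["level"]
            E = level - 2
            deletion = u["deletion"]
            eff_len = sum(s.length for s in u["segments"])
            cen_in_eff = any(
                _overlaps(f, s.start, s.end)
                for f in _centromeres(features, chrom)
                for s in u["segments"]
            )
            near = lambda p, q: abs(p - q) <= tol  # noqa: E731
            tandem = [
                b
                for b in bps
                if b.junction_class in ("tandem", "circularization")
                and near(b.pos_l, end - 1)
                and near(b.pos_r, start)
            ]
            inverted = [
                b
                for b in bps
                if b.junction_class == "inverted_tandem"
                and (near(b.pos_l, end - 1) or near(b.pos_l, start) or near(b.pos_r, end - 1) or near(b.pos_r, start))
            ]
            junction_ids = tuple(u["junctions"]) + tuple(
                b.contig_id for b in tandem + inverted
            )
            evidence = tuple(
                f"{b.junction_class} junction {b.contig_id} "
                f"({b.pos_l}{b.strand_l}/{b.pos_r}{b.strand_r}, mh {b.microhomology})"
                for b in tandem + inverted
            ) + tuple(f"segment {s.start}-{s.end} level {s.level}" for s in u["segments"])

            circ = [b for b in tandem if b.junction_class == "circularization"]
            plain_tandem = [b for b in tandem if b.junction_class == "tandem"]
            repeat_anchored = any(
                b.anchor_features and all(f is not None for f in b.anchor_features)
                for b in tandem
            )

            if cen_in_eff and plain_tandem:
                cls = "conflict"
            elif cen_in_eff and circ:
                cls = "episome"
            elif not cen_in_eff and tandem:
                cls = "segmental_duplication" if (E == 1 and repeat_anchored) else "direct_tandem"
            elif not cen_in_eff and inverted:
                cls = "inverted_tandem"
            else:
                cls = "unclassified"

            base_len = chrom_len - (
                0 if cls == "episome" else E * eff_len
            )  # observed chromosome length is the reference length here
            calls.append(
                StructureCall(
                    structure_class=cls,
                    chrom=chrom,
                    unit=(start, end),
                    effective_unit_length=eff_len,
                    extra_copies=E,
                    deletion=deletion,
                    junction_ids=junction_ids,
                    centromere_in_unit=cen_in_eff,
                    predicted_sizes_kb=predict_karyotype_sizes_raw(
                        cls, chrom_len, E, eff_len
                    ),
                    evidence=evidence,
                )
            )
    return calls


def predict_karyotype_sizes_raw(
    structure_class: str, base_length: int, extra: int, eff_unit: int
) -> tuple[float, ...]:
    if structure_class in ("direct_tandem", "inverted_tandem", "segmental_duplication"):
        return (round((base_length + extra * eff_unit) / 1000.0, 1),)
    if structure_class == "episome":
        return (round(base_length / 1000.0, 1), round(eff_unit / 1000.0, 1))
    if structure_class == "aneuploidy":
        return (round(base_length / 1000.0, 1),)
    return (round(base_length / 1000.0, 1),)


def predict_karyotype_sizes(call: StructureCall, base_length: int) -> tuple[float, ...]:
    """Predicted band sizes (kb) given the unamplified homologue length.

    Macrotene arrays migrate at base + E x effective unit; an episome
    leaves the chromosome at its base size and adds a circular species of
    unit length; an aneuploidy adds a band at the base size.
    """
    kb = base_length / 1000.0
    if call.structure_class in ("direct_tandem", "inverted_tandem", "segmental_duplication"):
        return (round(kb + call.extra_copies * call.effective_unit_length / 1000.0, 1),)
    if call.structure_class == "episome":
        return (round(kb, 1), round(call.effective_unit_length / 1000.0, 1))
    return (round(kb, 1),)


def consistency_check(
    predicted_kb: float, observation: KaryotypeObservation
) -> tuple[bool, float]:
    """True iff the predicted size is within tolerance of the closest band."""
    if not observation.band_sizes_kb:
        raise ValueError("empty karyotype observation")
    errs = [abs(predicted_kb - b) / b for b in observation.band_sizes_kb]
    rel = min(errs)
    return rel <= observation.tolerance, rel
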