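"""Machine-readable ground-truth bundle for simulated genomes.

Everything a downstream test needs to score the pipeline without
re-deriving it: the genome checksum, each amplification event (class,
unit, copies, junction geometry and realized junction records), expected
homologue/episome lengths and any planted point variants.  Round-trips
losslessly through JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .amplify import AmplificationEvent, AmpliconSpec, JunctionGeometry, TruthJunction
from .genome import GenomeModel


@dataclass(frozen=True)
class TruthBundle:
    genome_checksum: str
    amplifications: tuple[AmplificationEvent, ...]
    expected_homologue_lengths: tuple[tuple[str, int, int], ...]  # (chrom, index, nt)
    variants: tuple[tuple[str, int, str], ...] = ()  # (chrom, pos, alt)
    episomes: tuple[tuple[str, int, int], ...] = ()  # (name, length, copies)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthBundle":
        raw = json.loads(text)
        amps = tuple(_event_from_dict(d) for d in raw["amplifications"])
        return cls(
            genome_checksum=raw["genome_checksum"],
            amplifications=amps,
            expected_homologue_lengths=tuple(
                (c, int(i), int(n)) for c, i, n in raw["expected_homologue_lengths"]
            ),
            variants=tuple((c, int(p), a) for c, p, a in raw["variants"]),
            episomes=tuple((n, int(l), int(k)) for n, l, k in raw["episomes"]),
        )


def _geom_from_dict(d) -> JunctionGeometry | None:
    return None if d is None else JunctionGeometry(**d)


def _event_from_dict(d) -> AmplificationEvent:
    s = d["spec"]
    spec = AmpliconSpec(
        structure_class=s["structure_class"],
        chrom=s["chrom"],
        unit=tuple(s["unit"]),
        extra_copies=s["extra_copies"],
        homologue=s["homologue"],
        deletion=None if s["deletion"] is None else tuple(s["deletion"]),
        junction=_geom_from_dict(s["junction"]),
        deletion_junction=_geom_from_dict(s["deletion_junction"]),
        second_junction=_geom_from_dict(s["second_junction"]),
        insertion_side=s["insertion_side"],
        name=s["name"],
    )
    junctions = tuple(TruthJunction(**j) for j in d["junctions"])
    return AmplificationEvent(
        spec=spec,
        junctions=junctions,
        effective_unit_length=d["effective_unit_length"],
        expected_homologue_length=d["expected_homologue_length"],
        base_homologue_length=d["base_homologue_length"],
        episome_name=d["episome_name"],
        episome_length=d["episome_length"],
        episome_copies=d["episome_copies"],
    )


def build_truth_bundle(
    genome: GenomeModel,
    events,
    variants=(),
) -> TruthBundle:
    lengths = tuple(
        (h.chrom, h.index, len(h.seq))
        for h in sorted(genome.homologues, key=lambda x: (x.chrom, x.index))
    )
    episomes = tuple((e.name, len(e.seq), e.copies) for e in genome.episomes)
    return TruthBundle(
        genome_checksum=genome.checksum(),
        amplifications=tuple(events),
        expected_homologue_lengths=lengths,
        variants=tuple(variants),
        episomes=episomes,
    )


def write_truth_bundle(genome: GenomeModel, events, variants, path) -> TruthBundle:
    """Serialize the bundle to JSON; verifies the write-then-read round trip."""
    bundle = build_truth_bundle(genome, events, variants)
    with open(path, "w") as fh:
        fh.write(bundle.to_json())
    with open(path) as fh:
        back = TruthBundle.from_json(fh.read())
    if back != bundle:
        raise IOError(f"truth bundle round trip failed for {path}")
    return bundle


def read_truth_bundle(path) -> TruthBundle:
    with open(path) as fh:
        return TruthBundle.from_json(fh.read())
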