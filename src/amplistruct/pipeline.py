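"""End-to-end driver: simulate -> map -> depth -> segment -> junctions ->
classify, with a truth-vs-call report and a structure-class confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amplify import AmpliconSpec, apply_amplification
from .coverage import (
    DEFAULT_WINDOW,
    compute_depth,
    normalize_cn,
    segment_cn,
    smooth_profile,
)
from .genome import ReferenceConfig
from .junctions import (
    assemble_junction_contigs,
    classify_junction,
    collect_breakpoint_reads,
    detect_quasi_palindrome,
    split_align_contig,
)
from .mapping import ReferenceIndex, map_reads
from .reads import simulate_reads
from .structures import infer_structures
from .truth import build_truth_bundle
from .genome import build_reference


@dataclass(frozen=True)
class PipelineConfig:
    reference: ReferenceConfig
    amplicons: tuple[AmpliconSpec, ...]
    depth: float = 30.0
    read_length: int = 100
    error_rate: float = 1e-3
    seed: int = 0
    window: int = DEFAULT_WINDOW
    min_segment: int = 5000
    assembly_k: int = 17
    min_kmer_cov: int = 2


@dataclass
class PipelineResult:
    config: PipelineConfig
    genome: object
    truth: object
    alignments: object
    profile: object
    segments: list
    contigs: list
    breakpoints: list
    structures: list
    report: dict

    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.report["events"])

    def confusion(self) -> pd.DataFrame:
        rows = self.report["confusion"]
        classes = sorted({r["truth"] for r in rows} | {r["called"] for r in rows})
        mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
        for r in rows:
            mat.loc[r["truth"], r["called"]] += 1
        return mat


def config_from_dict(raw: dict, seed: int | None = None) -> PipelineConfig:
    """Build a pipeline configuration from a plain (e.g. YAML-loaded) dict.

    Either a ``scenario: <name>`` shortcut naming a preset, or explicit
    ``reference`` / ``amplicons`` sections.
    """
    from .amplify import AmpliconSpec, JunctionGeometry
    from .genome import ChromosomePlan, FeaturePlan, ReferenceConfig
    from . import scenarios as _sc

    seed = int(raw.get("seed", 0) if seed is None else seed)
    if "scenario" in raw:
        builder = {**_sc.PAPER_SCALE, **_sc.FIVE_CLASS_SUITE}[raw["scenario"]]
        ref, specs = builder(seed)
    else:
        chroms = []
        for c in raw["reference"]["chromosomes"]:
            feats = tuple(
                FeaturePlan(
                    kind=f["kind"],
                    start=int(f["start"]),
                    end=int(f["end"]),
                    strand=f.get("strand", "+"),
                    family=f.get("family", ""),
                    identity=float(f.get("identity", 1.0)),
                )
                for f in c.get("features", [])
            )
            chroms.append(ChromosomePlan(name=c["name"], length=int(c["length"]), features=feats))
        het = tuple(
            (v["chrom"], int(v["pos"]), v["alt"])
            for v in raw["reference"].get("het_variants", [])
        )
        ref = ReferenceConfig(chromosomes=tuple(chroms), seed=seed, het_variants=het)

        def geom(d):
            if d is None:
                return None
            return JunctionGeometry(
                mode=d.get("mode", "no_homology"),
                microhomology=int(d.get("microhomology", 0)),
                arm=int(d.get("arm", 0)),
                center=int(d.get("center", 0)),
            )

        specs = tuple(
            AmpliconSpec(
                structure_class=a["structure_class"],
                chrom=a["chrom"],
                unit=(int(a["unit"][0]), int(a["unit"][1])),
                extra_copies=int(a["extra_copies"]),
                homologue=int(a.get("homologue", 1)),
                deletion=tuple(a["deletion"]) if a.get("deletion") else None,
                junction=geom(a.get("junction")) or JunctionGeometry("no_homology", 1),
                deletion_junction=geom(a.get("deletion_junction")),
                second_junction=geom(a.get("second_junction")),
                insertion_side=a.get("insertion_side"),
                name=a.get("name", ""),
            )
            for a in raw.get("amplicons", [])
        )
    return PipelineConfig(
        reference=ref,
        amplicons=specs,
        depth=float(raw.get("depth", 30.0)),
        read_length=int(raw.get("read_length", 100)),
        error_rate=float(raw.get("error_rate", 1e-3)),
        seed=seed,
        window=int(raw.get("window", DEFAULT_WINDOW)),
        min_segment=int(raw.get("min_segment", 5000)),
        assembly_k=int(raw.get("assembly_k", 17)),
        min_kmer_cov=int(raw.get("min_kmer_cov", 2)),
    )


class StageError(RuntimeError):
    def __init__(self, stage: str, digest: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed on input {digest}: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str, digest: str, fn):
    try:
        return fn()
    except Exception as exc:  # noqa: BLE001 - re-raised with context
        raise StageError(name, digest, exc) from exc


def run_coverage(config: PipelineConfig):
    """The depth arm of the pipeline only: simulate -> map -> depth ->
    normalize -> smooth -> segment.  Returns (segments, truth, n_reads)."""
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    genome = build_reference(
        ReferenceConfig(
            chromosomes=config.reference.chromosomes,
            seed=int(seeds[0]),
            ploidy=config.reference.ploidy,
            het_variants=config.reference.het_variants,
        )
    )
    events = []
    for i, spec in enumerate(config.amplicons):
        genome, ev = apply_amplification(genome, spec, seed=int(seeds[1]) + i)
        events.append(ev)
    truth = build_truth_bundle(genome, events, variants=config.reference.het_variants)
    read_set = simulate_reads(
        genome,
        depth=config.depth,
        read_length=config.read_length,
        error_rate=config.error_rate,
        seed=int(seeds[2]),
    )
    index = ReferenceIndex.from_genome(genome)
    aln = map_reads(read_set, index)
    mask = {}
    for f in genome.features:
        if f.kind == "repeat_mask":
            mask.setdefault(f.chrom, []).append((f.start, f.end))
    profile = smooth_profile(
        normalize_cn(compute_depth(aln, index), mask or None), config.window
    )
    segments = segment_cn(profile, config.min_segment)
    return segments, truth, len(read_set)


def run_end_to_end(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline on one simulated truth configuration."""
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    digest = f"seed={config.seed}"

    genome = _stage("build_reference", digest, lambda: build_reference(
        ReferenceConfig(
            chromosomes=config.reference.chromosomes,
            seed=int(seeds[0]),
            ploidy=config.reference.ploidy,
            het_variants=config.reference.het_variants,
        )
    ))
    events = []
    for i, spec in enumerate(config.amplicons):
        genome, ev = _stage(
            "apply_amplification", f"{digest},{spec.name or i}",
            lambda g=genome, s=spec, i=i: apply_amplification(g, s, seed=int(seeds[1]) + i),
        )
        events.append(ev)
    truth = build_truth_bundle(genome, events, variants=config.reference.het_variants)

    read_set = _stage("simulate_reads", digest, lambda: simulate_reads(
        genome,
        depth=config.depth,
        read_length=config.read_length,
        error_rate=config.error_rate,
        seed=int(seeds[2]),
    ))
    index = ReferenceIndex.from_genome(genome)
    aln = _stage("map_reads", digest, lambda: map_reads(read_set, index))

    mask = {}
    for f in genome.features:
        if f.kind == "repeat_mask":
            mask.setdefault(f.chrom, []).append((f.start, f.end))
    profile = _stage("depth", digest, lambda: compute_depth(aln, index))
    profile = _stage("normalize", digest, lambda: normalize_cn(profile, mask or None))
    profile = _stage("smooth", digest, lambda: smooth_profile(profile, config.window))
    segments = _stage("segment", digest, lambda: segment_cn(profile, config.min_segment))

    bp_reads = collect_breakpoint_reads(aln, read_set)
    contigs = _stage("assemble", digest, lambda: assemble_junction_contigs(
        bp_reads, k=config.assembly_k, min_kmer_cov=config.min_kmer_cov
    ))
    breakpoints = []
    for contig in contigs:
        call = split_align_contig(contig, index)
        if call is None:
            continue
        classify_junction(call, genome.features, segments, genome=genome,
                          tol=2 * config.window)
        if contig.length >= 2 * 10:
            try:
                call.palindrome = detect_quasi_palindrome(contig)
            except ValueError:
                call.palindrome = None
        breakpoints.append(call)
    structures = _stage("classify", digest, lambda: infer_structures(
        segments, breakpoints, genome.features, window=config.window
    ))

    report = _score(truth, events, segments, breakpoints, structures)
    return PipelineResult(
        config=config,
        genome=genome,
        truth=truth,
        alignments=aln,
        profile=profile,
        segments=segments,
        contigs=contigs,
        breakpoints=breakpoints,
        structures=structures,
        report=report,
    )


def _score(truth, events, segments, breakpoints, structures) -> dict:
    """Align each truth event with the best-overlapping structure call."""
    rows = []
    confusion = []
    used = set()
    for ev in events:
        spec = ev.spec
        a, b = spec.unit
        best, best_ov = None, 0
        for i, sc in enumerate(structures):
            if sc.chrom != spec.chrom or i in used:
                continue
            ov = min(b, sc.unit[1]) - max(a, sc.unit[0])
            if ov > best_ov:
                best, best_ov = i, ov
        called_class = structures[best].structure_class if best is not None else "missed"
        if best is not None:
            used.add(best)
            sc = structures[best]
            unit_err = abs(sc.unit[0] - a) + abs(sc.unit[1] - b)
            e_called = sc.extra_copies
        else:
            unit_err, e_called = None, None
        jx_recovered = 0
        for tj in ev.junctions:
            lo, hi = tj.ambiguity
            for bp in breakpoints:
                if bp.chrom_l == tj.chrom and lo - 2 <= bp.pos_l <= hi + bp.inserted + 2:
                    jx_recovered += 1
                    break
        rows.append(
            {
                "name": spec.name or spec.structure_class,
                "truth_class": spec.structure_class,
                "called_class": called_class,
                "truth_extra": spec.extra_copies,
                "called_extra": e_called,
                "unit_boundary_error_nt": unit_err,
                "junction_types_recovered": jx_recovered,
                "junction_types_truth": len(ev.junctions),
            }
        )
        confusion.append({"truth": spec.structure_class, "called": called_class})
    spurious = [
        structures[i].structure_class
        for i in range(len(structures))
        if i not in used
    ]
    return {
        "events": rows,
        "confusion": confusion,
        "n_spurious_calls": len(spurious),
        "spurious_classes": spurious,
        "n_segments": len(segments),
        "n_breakpoints": len(breakpoints),
    }
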