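"""Preset truth configurations.

Two families of presets:

* paper-scale scenarios on 300-700-kb toy chromosomes matching the printed
  amplicon descriptions (30-kb unit at 12 extra copies, 55-kb centromeric
  episome at 8 copies, 50-kb inverted array at 21 extra copies — the
  midpoint of the printed 20-22 range — and a 211-kb centromeric episome
  at 3 copies);
* a scaled-down five-class suite (one scenario per structure class) for
  fast noise-free classifier checks.
"""

from __future__ import annotations

from .amplify import AmpliconSpec, JunctionGeometry
from .genome import ChromosomePlan, FeaturePlan, ReferenceConfig


def _chrom(name: str, length: int, cen_at: int, extra_features=()) -> ChromosomePlan:
    feats = [FeaturePlan("centromere", cen_at, cen_at + 120)] + list(extra_features)
    return ChromosomePlan(name=name, length=length, features=tuple(feats))


def viii_b_macrotene(seed: int):
    """Direct tandem, 30-kb centromere-free unit, 12 extra copies (600-kb chromosome)."""
    ref = ReferenceConfig(
        chromosomes=(_chrom("chrVIII", 600_000, 100_000),),
        seed=seed,
    )
    spec = AmpliconSpec(
        structure_class="direct_tandem",
        chrom="chrVIII",
        unit=(300_000, 330_000),
        extra_copies=12,
        junction=JunctionGeometry("no_homology", 1),
        name="VIII-B-like",
    )
    return ref, (spec,)


def viii_b_nested(seed: int):
    """Direct tandem of a 55-kb unit internally deleted of a 25-kb
    centromere-containing segment (effective unit 30 kb), 12 extra copies."""
    ref = ReferenceConfig(
        chromosomes=(_chrom("chrVIII", 600_000, 315_000),),
        seed=seed,
    )
    spec = AmpliconSpec(
        structure_class="direct_tandem",
        chrom="chrVIII",
        unit=(290_000, 345_000),
        extra_copies=12,
        deletion=(305_000, 330_000),
        junction=JunctionGeometry("no_homology", 1),
        deletion_junction=JunctionGeometry("microhomology", 29),
        name="VIII-B-nested",
    )
    return ref, (spec,)


def viii_a_episome(seed: int):
    """55-kb centromere-containing unit as a circular episome at 8 copies."""
    ref = ReferenceConfig(
        chromosomes=(_chrom("chrVIII", 600_000, 115_000),),
        seed=seed,
    )
    spec = AmpliconSpec(
        structure_class="episome",
        chrom="chrVIII",
        unit=(90_000, 145_000),
        extra_copies=8,
        junction=JunctionGeometry("microhomology", 10),
        name="VIII-A-like",
    )
    return ref, (spec,)


def iv_b_inverted(seed: int, extra_copies: int = 21):
    """Inverted tandem of a 50-kb centromere-free unit with quasi-palindromic
    junctions (arm 36, center 5 — a 77-nt junction region), 21 extra copies."""
    ref = ReferenceConfig(
        chromosomes=(_chrom("chrIV", 700_000, 120_000),),
        seed=seed,
    )
    spec = AmpliconSpec(
        structure_class="inverted_tandem",
        chrom="chrIV",
        unit=(400_000, 450_000),
        extra_copies=extra_copies,
        junction=JunctionGeometry("quasi_palindrome", arm=36, center=5),
        second_junction=JunctionGeometry("quasi_palindrome", arm=42, center=3),
        name="IV-B-like",
    )
    return ref, (spec,)


def iv_c_episome(seed: int):
    """211-kb centromere-containing unit as a circular episome at 3 copies."""
    ref = ReferenceConfig(
        chromosomes=(_chrom("chrIV", 700_000, 300_000),),
        seed=seed,
    )
    spec = AmpliconSpec(
        structure_class="episome",
        chrom="chrIV",
        unit=(200_000, 411_000),
        extra_copies=3,
        junction=JunctionGeometry("microhomology", 10),
        name="IV-C-like",
    )
    return ref, (spec,)


# ------------------------------------------------------- scaled-down suite
def small_direct(seed: int):
    ref = ReferenceConfig(chromosomes=(_chrom("chrA", 150_000, 30_000),), seed=seed)
    spec = AmpliconSpec(
        structure_class="direct_tandem",
        chrom="chrA",
        unit=(80_000, 92_000),
        extra_copies=5,
        junction=JunctionGeometry("no_homology", 1),
        name="small-direct",
    )
    return ref, (spec,)


def small_inverted(seed: int):
    ref = ReferenceConfig(chromosomes=(_chrom("chrA", 150_000, 30_000),), seed=seed)
    spec = AmpliconSpec(
        structure_class="inverted_tandem",
        chrom="chrA",
        unit=(80_000, 92_000),
        extra_copies=5,
        junction=JunctionGeometry("quasi_palindrome", arm=36, center=5),
        name="small-inverted",
    )
    return ref, (spec,)


def small_episome(seed: int):
    ref = ReferenceConfig(chromosomes=(_chrom("chrA", 150_000, 85_000),), seed=seed)
    spec = AmpliconSpec(
        structure_class="episome",
        chrom="chrA",
        unit=(80_000, 92_000),
        extra_copies=6,
        junction=JunctionGeometry("microhomology", 10),
        name="small-episome",
    )
    return ref, (spec,)


def small_segmental_dup(seed: int):
    # unit boundaries inside two diverged LTR-family repeats (Ty analogues)
    feats = (
        FeaturePlan("Ty", 79_700, 80_300, "+", family="TyX", identity=1.0),
        FeaturePlan("Ty", 91_700, 92_300, "+", family="TyX", identity=0.78),
    )
    ref = ReferenceConfig(
        chromosomes=(_chrom("chrA", 150_000, 30_000, feats),), seed=seed
    )
    spec = AmpliconSpec(
        structure_class="segmental_duplication",
        chrom="chrA",
        unit=(80_000, 92_000),
        extra_copies=1,
        junction=JunctionGeometry("microhomology", 10),
        name="small-segdup",
    )
    return ref, (spec,)


def small_aneuploidy(seed: int):
    # the unamplified chromosome is the longer one so the diploid baseline
    # dominates the genome-wide median used for re-centering
    ref = ReferenceConfig(
        chromosomes=(
            _chrom("chrA", 80_000, 20_000),
            _chrom("chrB", 160_000, 40_000),
        ),
        seed=seed,
    )
    spec = AmpliconSpec(
        structure_class="aneuploidy",
        chrom="chrA",
        unit=(0, 80_000),
        extra_copies=1,
        name="small-aneuploidy",
    )
    return ref, (spec,)


FIVE_CLASS_SUITE = {
    "direct_tandem": small_direct,
    "inverted_tandem": small_inverted,
    "episome": small_episome,
    "segmental_duplication": small_segmental_dup,
    "aneuploidy": small_aneuploidy,
}

PAPER_SCALE = {
    "viii_b_macrotene": viii_b_macrotene,
    "viii_a_episome": viii_a_episome,
    "iv_b_inverted": iv_b_inverted,
    "iv_c_episome": iv_c_episome,
}
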