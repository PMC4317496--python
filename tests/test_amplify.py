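"""Amplification construction: exact length bookkeeping, junction
realization, truth-bundle round trips."""

import numpy as np
import pytest

from amplistruct.amplify import AmpliconSpec, JunctionGeometry, apply_amplification
from amplistruct.genome import ChromosomePlan, FeaturePlan, ReferenceConfig, build_reference
from amplistruct.junctions import detect_quasi_palindrome, microhomology_length
from amplistruct.truth import TruthBundle, build_truth_bundle, write_truth_bundle


def _genome(length=583_000, cen=50_000, seed=5, name="chr8"):
    return build_reference(
        ReferenceConfig(
            chromosomes=(
                ChromosomePlan(
                    name, length, (FeaturePlan("centromere", cen, cen + 120),)
                ),
            ),
            seed=seed,
        )
    )


def test_direct_tandem_length_bookkeeping_matches_oracle():
    # 583-kb homologue + 12 extra copies of a 30-kb unit = 943 kb
    g = _genome()
    spec = AmpliconSpec("direct_tandem", "chr8", (200_000, 230_000), 12)
    g2, ev = apply_amplification(g, spec, seed=1)
    assert ev.expected_homologue_length == 583_000 + 12 * 30_000
    assert len(g2.homologue("chr8", 1).seq) == 943_000
    # untouched homologue keeps its base length
    assert len(g2.homologue("chr8", 0).seq) == 583_000


def test_zero_extra_copies_is_byte_identity():
    g = _genome()
    spec = AmpliconSpec("direct_tandem", "chr8", (200_000, 230_000), 0)
    g2, ev = apply_amplification(g, spec, seed=1)
    assert g2.checksum() == g.checksum()
    assert ev.junctions == ()


def test_episome_leaves_chromosomes_unchanged_and_adds_circle():
    g = _genome(cen=210_000)
    spec = AmpliconSpec(
        "episome", "chr8", (200_000, 255_000), 8,
        junction=JunctionGeometry("microhomology", 10),
    )
    g2, ev = apply_amplification(g, spec, seed=1)
    assert len(g2.homologue("chr8", 1).seq) == 583_000  # no cognate deletion
    assert len(g2.episomes) == 1
    assert g2.episomes[0].copies == 8
    assert len(g2.episomes[0].seq) == 55_000
    assert ev.episome_copies == 8


def test_internal_deletion_shrinks_effective_unit():
    # 55-kb unit internally deleted of 25 kb -> effective unit 30 kb
    g = _genome(cen=225_000)
    spec = AmpliconSpec(
        "direct_tandem", "chr8", (200_000, 255_000), 12,
        deletion=(215_000, 240_000),
        junction=JunctionGeometry("no_homology", 1),
        deletion_junction=JunctionGeometry("microhomology", 29),
    )
    g2, ev = apply_amplification(g, spec, seed=1)
    assert ev.effective_unit_length == 30_000
    assert ev.expected_homologue_length == 583_000 + 12 * 30_000
    assert len(g2.homologue("chr8", 1).seq) == ev.expected_homologue_length


@pytest.mark.parametrize("side", ["right", "left"])
def test_direct_junction_microhomology_rescored_from_window(side):
    g = _genome()
    spec = AmpliconSpec(
        "direct_tandem", "chr8", (200_000, 230_000), 3,
        junction=JunctionGeometry("microhomology", 29),
        insertion_side=side,
    )
    _, ev = apply_amplification(g, spec, seed=2)
    tandem = [j for j in ev.junctions if j.kind == "tandem"][0]
    assert tandem.microhomology == 29
    w = tandem.window_seq
    # the junction sits at the window midpoint; donors given at the
    # outermost equivalent breakpoints share exactly the planted segment
    mid = len(w) // 2
    assert microhomology_length(w[:mid], w[mid - 29 :]) == 29


@pytest.mark.parametrize("h", [0, 1, 10, 42])
def test_planted_microhomology_width_is_exact(h):
    g = _genome(seed=9)
    mode = "no_homology" if h <= 1 else "microhomology"
    spec = AmpliconSpec(
        "direct_tandem", "chr8", (200_000, 230_000), 2,
        junction=JunctionGeometry(mode, h),
    )
    g2, ev = apply_amplification(g, spec, seed=3)
    tandem = ev.junctions[0]
    # measure the ambiguity window directly on the reference sequence
    ref = g2.homologue("chr8", 0).seq
    b, a = 230_000, 200_000
    left = 0
    while ref[b - 1 - left] == ref[a - 1 - left]:
        left += 1
    right = 0
    while ref[b + right] == ref[a + right]:
        right += 1
    assert left + right == h == tandem.microhomology


def test_inverted_array_window_scores_configured_center():
    g = _genome(seed=13)
    spec = AmpliconSpec(
        "inverted_tandem", "chr8", (200_000, 250_000), 4,
        junction=JunctionGeometry("quasi_palindrome", arm=36, center=5),
        second_junction=JunctionGeometry("quasi_palindrome", arm=42, center=3),
    )
    _, ev = apply_amplification(g, spec, seed=4)
    for j in ev.junctions:
        if j.kind == "inverted_flank":
            continue
        desc = detect_quasi_palindrome(j.window_seq, min_arm=10, max_center=20)
        assert desc is not None
        assert desc.center == j.center
        # copies are exact reverse complements: the arm fills the window
        assert desc.arm == min(
            desc.center_start, len(j.window_seq) - desc.center_start - desc.center
        )
        assert desc.arm >= j.arm


def test_inverted_length_includes_interface_centers():
    g = _genome(seed=13)
    spec = AmpliconSpec(
        "inverted_tandem", "chr8", (200_000, 250_000), 5,
        junction=JunctionGeometry("quasi_palindrome", arm=36, center=5),
        second_junction=JunctionGeometry("quasi_palindrome", arm=36, center=3),
    )
    g2, ev = apply_amplification(g, spec, seed=4)
    centers = 3 * 5 + 2 * 3  # three odd interfaces, two even
    assert ev.expected_homologue_length == 583_000 + 5 * 50_000 + centers
    assert len(g2.homologue("chr8", 1).seq) == ev.expected_homologue_length


def test_aneuploidy_appends_whole_homologue():
    g = _genome()
    spec = AmpliconSpec("aneuploidy", "chr8", (0, 583_000), 1)
    g2, ev = apply_amplification(g, spec, seed=1)
    assert len([h for h in g2.homologues if h.chrom == "chr8"]) == 3
    assert ev.expected_homologue_length == 583_000


@pytest.mark.parametrize(
    "kwargs, message",
    [
        (dict(deletion=(100, 200)), "inside unit"),
        (dict(extra_copies=-1), ">= 0"),
    ],
)
def test_invalid_specs_rejected(kwargs, message):
    base = dict(
        structure_class="direct_tandem",
        chrom="chr8",
        unit=(200_000, 230_000),
        extra_copies=3,
    )
    base.update(kwargs)
    with pytest.raises(ValueError, match=message):
        AmpliconSpec(**base)


def test_episome_with_insertion_side_rejected():
    with pytest.raises(ValueError, match="insertion side"):
        AmpliconSpec("episome", "chr8", (1000, 2000), 3, insertion_side="right")


def test_inverted_without_palindrome_geometry_rejected():
    with pytest.raises(ValueError, match="quasi_palindrome"):
        AmpliconSpec("inverted_tandem", "chr8", (1000, 9000), 3,
                     junction=JunctionGeometry("no_homology", 0))


def test_length_conservation_over_random_configs():
    """base + E x effective unit, across classes and 1,000 random configs."""
    rng = np.random.default_rng(99)
    g = _genome(length=40_000, cen=2_000, seed=77)
    for _ in range(1000):
        cls = ["direct_tandem", "inverted_tandem", "episome"][int(rng.integers(3))]
        ulen = int(rng.integers(2_000, 8_000))
        a = int(rng.integers(5_000, 30_000 - ulen))
        b = a + ulen
        E = int(rng.integers(1, 9))
        if cls == "inverted_tandem":
            spec = AmpliconSpec(
                cls, "chr8", (a, b), E,
                junction=JunctionGeometry("quasi_palindrome", arm=12,
                                          center=int(rng.integers(0, 12))),
            )
        elif cls == "episome":
            spec = AmpliconSpec(cls, "chr8", (a, b), E,
                                junction=JunctionGeometry("microhomology", 6))
        else:
            dlen = int(rng.integers(0, ulen // 2))
            deletion = (a + ulen // 4, a + ulen // 4 + dlen) if dlen > 60 else None
            spec = AmpliconSpec(cls, "chr8", (a, b), E, deletion=deletion,
                                junction=JunctionGeometry("microhomology", 8),
                                deletion_junction=JunctionGeometry("microhomology", 8))
        g2, ev = apply_amplification(g, spec, seed=int(rng.integers(2**31)))
        got = len(g2.homologue("chr8", 1).seq)
        if cls == "episome":
            assert got == 40_000
            assert len(g2.episomes[-1].seq) == ulen
        elif cls == "inverted_tandem":
            centers = ((E + 1) // 2) * spec.junction.center + (E // 2) * spec.junction.center
            assert got == 40_000 + E * ev.effective_unit_length + centers
        else:
            assert got == 40_000 + E * ev.effective_unit_length


def test_truth_bundle_round_trip(tmp_path):
    g = _genome(seed=21)
    spec = AmpliconSpec(
        "direct_tandem", "chr8", (200_000, 255_000), 12,
        deletion=(215_000, 240_000),
        deletion_junction=JunctionGeometry("microhomology", 29),
    )
    g2, ev = apply_amplification(g, spec, seed=6)
    path = tmp_path / "truth.json"
    bundle = write_truth_bundle(g2, [ev], [("chr8", 123, "A")], path)
    back = TruthBundle.from_json(path.read_text())
    assert back == bundle
    assert back.amplifications[0].effective_unit_length == 30_000
    lengths = dict(((c, i), n) for c, i, n in back.expected_homologue_lengths)
    assert lengths[("chr8", 1)] == 583_000 + 12 * 30_000


def test_empty_truth_bundle_is_valid(tmp_path):
    g = _genome(seed=22)
    path = tmp_path / "truth.json"
    bundle = write_truth_bundle(g, [], [], path)
    assert bundle.amplifications == ()
    assert TruthBundle.from_json(path.read_text()) == bundle
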