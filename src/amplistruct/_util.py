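"""Shared sequence/encoding helpers.

Nucleotides are encoded A=0, C=1, G=2, T=3 throughout; reverse complement
is ``3 - code`` on the reversed array.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

# byte -> code lookup (255 marks non-ACGT)
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(BASES.encode(), dtype=np.uint8)

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 code array."""
    arr = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = int(np.argmax(arr > 3))
        raise ValueError(f"non-ACGT base {seq[bad]!r} at position {bad}")
    return arr


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    """i.i.d. uniform nucleotides (GC content 0.5)."""
    return decode(rng.integers(0, 4, size=length).astype(np.uint8))


def mutate_positions(seq: str, positions, rng: np.random.Generator) -> str:
    """Substitute each listed position with a uniformly chosen *different* base."""
    codes = encode(seq).copy()
    for p in positions:
        codes[p] = (codes[p] + rng.integers(1, 4)) % 4
    return decode(codes)


def other_base(base: str, avoid: str = "", rng: np.random.Generator | None = None) -> str:
    """A base different from ``base`` and from every base in ``avoid``."""
    choices = [b for b in BASES if b != base and b not in avoid]
    if rng is None:
        return choices[0]
    return choices[int(rng.integers(len(choices)))]


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministically derive ``n`` independent generators from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
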