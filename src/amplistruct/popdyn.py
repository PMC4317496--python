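"""Serial-transfer bookkeeping, selection arithmetic and amplification
stability.

The experimental design: an unfit diploid population is propagated through
2-litre cultures, each seeded with an inoculum of Ni = 1e9 cells (1e8 and
5e8 for the first two cultures) and grown to a final density d cells/ml,
so each culture spans n = log2(2000 d / Ni) generations (~7-9).  A
beneficial mutant invades once it reaches frequency 1/Ni, and a growth-rate
advantage s multiplies its frequency ratio by 2^(s n) per transfer — 12.5%
doubles the ratio over an 8-generation culture.

Stability of an amplified structure is summarized by the geometric loss
model: conserving a fraction C of cells after G generations corresponds to
a per-cell per-generation loss probability p = 1 - C^(1/G).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

DEFAULT_VOLUME_ML = 2000.0
DEFAULT_INOCULUM = 1e9


@dataclass(frozen=True)
class SerialTransferRecord:
    culture: int
    duration_days: float
    final_density_per_ml: float
    inoculum: float = DEFAULT_INOCULUM
    volume_ml: float = DEFAULT_VOLUME_ML

    @property
    def final_count(self) -> float:
        return self.volume_ml * self.final_density_per_ml

    @property
    def generations(self) -> float:
        return generations_in_culture(
            self.final_density_per_ml, self.inoculum, self.volume_ml
        )


@dataclass(frozen=True)
class SelectionModel:
    advantage: float  # growth-rate increase s (fraction)
    generations_per_transfer: float
    initial_ratio: float = 1e-9  # mutant : wild-type frequency ratio

    def __post_init__(self):
        if self.advantage <= -1:
            raise ValueError("advantage must be > -1")
        if not 0 < self.initial_ratio:
            raise ValueError("initial ratio must be > 0")


@dataclass(frozen=True)
class StabilityEstimate:
    conserved_fraction: float
    generations: float
    loss_rate: float  # per cell per generation

    def __post_init__(self):
        back = (1.0 - self.loss_rate) ** self.generations
        if abs(back - self.conserved_fraction) > 1e-12:
            raise ValueError("loss rate inconsistent with conserved fraction")


# ----------------------------------------------------------------- arithmetic
def generations_in_culture(
    d: float, Ni: float = DEFAULT_INOCULUM, volume_ml: float = DEFAULT_VOLUME_ML
) -> float:
    """n = log2(volume * d / Ni).  Negative if the culture shrank (warned)."""
    if d <= 0 or Ni <= 0 or volume_ml <= 0:
        raise ValueError("density, inoculum and volume must all be > 0")
    n = math.log2(volume_ml * d / Ni)
    if n < 0:
        import warnings

        warnings.warn(f"final count below inoculum: n = {n:.2f}", stacklevel=2)
    return n


def cumulative_generations(records: list[SerialTransferRecord]) -> list[float]:
    """Prefix sums of unrounded per-culture generation counts."""
    out, total = [], 0.0
    for r in records:
        total += r.generations
        out.append(total)
    return out


def frequency_trajectory(model: SelectionModel, transfers: int) -> pd.DataFrame:
    """Mutant:wild-type ratio r multiplied by 2^(s n) per transfer.

    Also reports the absolute mutant frequency r / (1 + r).
    """
    factor = 2.0 ** (model.advantage * model.generations_per_transfer)
    ratios = model.initial_ratio * factor ** np.arange(transfers + 1)
    return pd.DataFrame(
        {
            "transfer": np.arange(transfers + 1),
            "ratio": ratios,
            "frequency": ratios / (1.0 + ratios),
        }
    )


def advantage_for_doubling(n: float) -> float:
    """The growth advantage s with 2^(s n) = 2: s = 1/n.

    A mutant dividing (1+s) times per wild-type generation gains a factor
    2^(s n) in frequency ratio over an n-generation culture; doubling per
    ~8-generation transfer therefore needs only s = 12.5%.
    """
    if n <= 0:
        raise ValueError("generations per transfer must be > 0")
    return 1.0 / n


def invasion_threshold(Ni: float) -> float:
    """Frequency at which the expected number of mutants in the inoculum is 1."""
    if Ni < 1:
        raise ValueError("inoculum must be >= 1 cell")
    return 1.0 / Ni


def loss_rate_estimate(C: float, G: float) -> StabilityEstimate:
    """p = 1 - C^(1/G): per-cell per-generation loss from conservation C."""
    if not 0 < C <= 1:
        raise ValueError("conserved fraction must lie in (0, 1]")
    if G <= 0:
        raise ValueError("generations must be > 0")
    p = 1.0 - C ** (1.0 / G)
    return StabilityEstimate(conserved_fraction=C, generations=G, loss_rate=p)


def conserved_fraction(p: float, G: float) -> float:
    """Inverse of :func:`loss_rate_estimate`: (1 - p)^G."""
    if not 0 <= p < 1:
        raise ValueError("loss rate must lie in [0, 1)")
    return (1.0 - p) ** G


# ------------------------------------------------------------------- tables
def load_transfer_table(which: str = "table1") -> pd.DataFrame:
    """Packaged serial-transfer culture records for the two experiments.

    Columns: culture, days, density_e8_per_ml, inoculum, and the published
    per-culture and cumulative generation counts (one decimal) kept for
    cross-checking recomputation.
    """
    with resources.files("amplistruct.data").joinpath(f"{which}.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def records_from_table(df: pd.DataFrame) -> list[SerialTransferRecord]:
    return [
        SerialTransferRecord(
            culture=int(r.culture),
            duration_days=float(r.days),
            final_density_per_ml=float(r.density_e8_per_ml) * 1e8,
            inoculum=float(r.inoculum),
        )
        for r in df.itertuples()
    ]
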