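"""Dosage-proportional transcript-level simulation.

Each gene's observed abundance is ``baseline * copy_number * exp(N(0, sigma^2))``
per sample; the control sample carries the diploid copy number 2.  With
``sigma = 0`` the case/control ratio equals the copy-number ratio exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionTable:
    table: pd.DataFrame  # gene, copy_number, baseline, case, control
    sigma: float
    seed: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_tsv(path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t")


def simulate_expression(
    copy_numbers,
    baseline,
    sigma: float = 0.0,
    seed: int = 0,
    gene_ids=None,
    control_copy_number: int = 2,
) -> ExpressionTable:
    """Simulate case/control abundances for genes at given copy numbers."""
    copy_numbers = np.asarray(copy_numbers, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if np.any(copy_numbers < 0):
        raise ValueError("copy numbers must be >= 0")
    if np.any(baseline <= 0):
        raise ValueError("baseline abundances must be > 0")
    if copy_numbers.shape != baseline.shape:
        raise ValueError("copy_numbers and baseline must have the same length")

    n = copy_numbers.size
    rng = np.random.default_rng(seed)
    noise_case = np.exp(rng.normal(0.0, sigma, size=n)) if sigma > 0 else np.ones(n)
    noise_ctrl = np.exp(rng.normal(0.0, sigma, size=n)) if sigma > 0 else np.ones(n)
    case = baseline * copy_numbers * noise_case
    control = baseline * control_copy_number * noise_ctrl

    if gene_ids is None:
        gene_ids = [f"gene{i + 1:05d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "gene": gene_ids,
            "copy_number": copy_numbers,
            "baseline": baseline,
            "case": case,
            "control": control,
        }
    )
    return ExpressionTable(table=df, sigma=sigma, seed=seed)
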