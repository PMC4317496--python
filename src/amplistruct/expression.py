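"""MA-style gene-dosage analysis of amplicon-embedded genes.

For each gene with case abundance x and control abundance y (both > 0):
M = log2(x/y), A = 0.5 log2(x y).  The amplicon summary is the arithmetic
mean and standard deviation of the per-gene folds 2^M over the amplicon
gene set (mean of folds, not fold of means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exprsim import ExpressionTable


@dataclass(frozen=True)
class ExpressionRecord:
    gene: str
    case: float
    control: float
    A: float
    M: float
    in_amplicon: bool = False


def ma_transform(table: ExpressionTable | pd.DataFrame, amplicon_genes=()) -> pd.DataFrame:
    """Per-gene (A, M) values; genes with non-positive abundance are rejected."""
    df = table.table if isinstance(table, ExpressionTable) else table
    bad = df[(df["case"] <= 0) | (df["control"] <= 0)]
    if len(bad):
        raise ValueError(
            f"non-positive abundance for gene(s): {', '.join(bad['gene'].astype(str))}"
        )
    x = df["case"].to_numpy(dtype=float)
    y = df["control"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "gene": df["gene"],
            "case": x,
            "control": y,
            "A": 0.5 * np.log2(x * y),
            "M": np.log2(x / y),
        }
    )
    out["fold"] = 2.0 ** out["M"]
    amplicon = set(amplicon_genes)
    out["in_amplicon"] = out["gene"].isin(amplicon) if amplicon else False
    if "tested" in df.columns:
        out["tested"] = df["tested"].astype(bool).to_numpy()
    return out


def amplicon_fold_summary(records: pd.DataFrame, amplicon_genes) -> dict:
    """Mean fold, standard deviation and n over the amplicon gene set.

    Genes flagged not-tested are excluded; an empty intersection of the set
    with the records is rejected.
    """
    genes = set(amplicon_genes)
    if not genes:
        raise ValueError("amplicon gene set is empty")
    sub = records[records["gene"].isin(genes)]
    if "tested" in sub.columns:
        sub = sub[sub["tested"]]
    if len(sub) == 0:
        raise ValueError("no amplicon genes found among the expression records")
    folds = sub["fold"].to_numpy(dtype=float)
    return {
        "mean_fold": float(np.mean(folds)),
        "sd_fold": float(np.std(folds, ddof=0)),
        "n": int(folds.size),
    }


def ma_plot(records: pd.DataFrame, path=None, ax=None):
    """MA scatter with amplicon-embedded genes highlighted."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    bg = records[~records["in_amplicon"]]
    fg = records[records["in_amplicon"]]
    ax.scatter(bg["A"], bg["M"], s=4, alpha=0.4, color="steelblue", label="other genes")
    if len(fg):
        ax.scatter(fg["A"], fg["M"], s=12, color="black", label="amplicon genes")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("A (mean log2 abundance)")
    ax.set_ylabel("M (log2 case/control)")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
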