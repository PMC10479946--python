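"""Differentially-expressed-gene filtering, ranking, and Venn overlap
summaries.

The DEG gate is |log2FC| >= 1 and p < 0.05 (on the raw p column by default,
with an FDR option).  Venn summaries always recompute percentages from the
set counts — they never store free-floating percentages — with half-up
rounding to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = ["filter_degs", "venn_overlap", "top_n", "VennSummary", "round_half_up"]


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def filter_degs(
    table: pd.DataFrame,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    use_fdr: bool = False,
) -> pd.DataFrame:
    """Rows with |log2FC| >= lfc_threshold and p < p_threshold, plus direction."""
    pcol = "FDR" if use_fdr else "pvalue"
    mask = (table["log2FC"].abs() >= lfc_threshold) & (table[pcol] < p_threshold)
    out = table.loc[mask].copy()
    out["direction"] = out["log2FC"].apply(lambda x: "up" if x > 0 else "down")
    return out.reset_index(drop=True)


@dataclass
class VennSummary:
    n_a: int
    n_b: int
    n_shared: int
    n_only_a: int
    n_only_b: int
    pct_shared_of_a: float | None
    pct_shared_of_b: float | None
    pct_only_a: float | None
    pct_only_b: float | None

    def as_dict(self) -> dict:
        return dict(vars(self))


def venn_overlap(set_a: set[str], set_b: set[str]) -> VennSummary:
    """Exact pairwise set arithmetic with percentages relative to each set.

    Percentages are None (undefined, not zero) when the denominator set is
    empty.
    """
    shared = set_a & set_b
    only_a = set_a - set_b
    only_b = set_b - set_a

    def pct(count: int, denom: int) -> float | None:
        return round_half_up(100.0 * count / denom) if denom else None

    return VennSummary(
        n_a=len(set_a), n_b=len(set_b), n_shared=len(shared),
        n_only_a=len(only_a), n_only_b=len(only_b),
        pct_shared_of_a=pct(len(shared), len(set_a)),
        pct_shared_of_b=pct(len(shared), len(set_b)),
        pct_only_a=pct(len(only_a), len(set_a)),
        pct_only_b=pct(len(only_b), len(set_b)),
    )


def top_n(table: pd.DataFrame, n: int = 50, rank_key: str = "log2FC") -> list[str]:
    """Top-n genes by |rank_key| descending; ties broken by gene id."""
    df = table.copy()
    df["_key"] = df[rank_key].abs()
    df = df.sort_values(["_key", "gene"], ascending=[False, True], kind="stable")
    return df["gene"].head(n).tolist()
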