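"""Three-criterion marker-signature selection with reductive minimization.

Candidate genes (positively enriched) are flagged for membership in the
top-K lists under three criteria: ascending adjusted p-value, descending log
fold change, descending specificity ratio.  Genes in all three lists form
tier 3; genes in exactly two form tier 2, ranked by pair weight
(specificity+lfc > specificity+padj > lfc+padj) and within a pair by
specificity.  The final list is ordered by descending specificity within
each tier.
"""

from __future__ import annotations

import os
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .differential_expression import DifferentialTable

DEFAULT_K_TOP = 200
DEFAULT_SIZE = 100
DEFAULT_REDUCTIVE_SIZES = (100, 50, 25, 10, 5, 1)

_PAIR_WEIGHT = {
    ("in_top_spec", "in_top_lfc"): 0,
    ("in_top_spec", "in_top_padj"): 1,
    ("in_top_lfc", "in_top_padj"): 2,
}

SIGNATURE_COLUMNS = [
    "rank",
    "gene",
    "tier",
    "in_top_padj",
    "in_top_lfc",
    "in_top_spec",
    "specificity",
]


@dataclass
class GeneSignature:
    """Ordered signature with per-criterion membership flags."""

    table: pd.DataFrame  # columns: gene, tier, flags, specificity (ordered)
    shortfall: int = 0
    source: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path: str | os.PathLike) -> None:
        out = self.table.copy()
        out.insert(0, "rank", np.arange(1, len(out) + 1))
        out[SIGNATURE_COLUMNS].to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "GeneSignature":
        df = pd.read_csv(path).drop(columns=["rank"])
        return cls(table=df)


def _top_k(table: pd.DataFrame, key: str, ascending: bool, k: int) -> set[str]:
    ordered = table.sort_values(
        [key, "gene"], ascending=[ascending, True], kind="mergesort"
    )
    return set(ordered["gene"].head(k))


def criterion_membership(
    table: DifferentialTable | pd.DataFrame, k: int
) -> pd.DataFrame:
    """Top-``k`` membership flags for p_adj (asc), lfc (desc), specificity (desc).

    Only positively enriched genes (``lfc > 0``) are candidates.  Ties are
    broken lexicographically by gene id so membership is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = table.table if isinstance(table, DifferentialTable) else table
    df = df[df["lfc"] > 0].copy()
    if k > len(df):
        _warnings.warn(
            f"k={k} exceeds candidate pool of {len(df)} genes; all flags set",
            stacklevel=2,
        )
    top_padj = _top_k(df, "p_adj", ascending=True, k=k)
    top_lfc = _top_k(df, "lfc", ascending=False, k=k)
    top_spec = _top_k(df, "specificity", ascending=False, k=k)
    df["in_top_padj"] = df["gene"].isin(top_padj)
    df["in_top_lfc"] = df["gene"].isin(top_lfc)
    df["in_top_spec"] = df["gene"].isin(top_spec)
    return df.reset_index(drop=True)


def _pair_weight(row) -> int:
    flags = [f for f in ("in_top_spec", "in_top_lfc", "in_top_padj") if row[f]]
    return _PAIR_WEIGHT[tuple(flags)]  # type: ignore[index]


def select_signature(
    table: DifferentialTable | pd.DataFrame,
    k_top: int = DEFAULT_K_TOP,
    size: int = DEFAULT_SIZE,
    exclude: Iterable[str] = (),
    source: str = "",
) -> GeneSignature:
    """Build the tiered signature of ``size`` genes.

    Tier-3 genes (all three top-K lists) are taken first; tier-2 genes follow
    in pair-weight order.  If the tiered pool is still short, remaining
    candidates are force-filled by descending specificity (tier ``forced``).
    Excluded genes never appear.  The output is ordered by descending
    specificity within each tier.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    exclude = set(exclude)
    flags = criterion_membership(table, k_top)
    flags = flags[~flags["gene"].isin(exclude)].copy()
    n_flags = flags[["in_top_padj", "in_top_lfc", "in_top_spec"]].sum(axis=1)

    tier3 = flags[n_flags == 3].copy()
    tier3["tier"] = "3"
    tier3 = tier3.sort_values(
        ["specificity", "gene"], ascending=[False, True], kind="mergesort"
    )

    tier2 = flags[n_flags == 2].copy()
    tier2["tier"] = "2"
    if len(tier2):
        tier2["_pair"] = tier2.apply(_pair_weight, axis=1)
        tier2 = tier2.sort_values(
            ["_pair", "specificity", "gene"],
            ascending=[True, False, True],
            kind="mergesort",
        ).drop(columns="_pair")

    selected = pd.concat([tier3, tier2]).head(size)
    shortfall = 0
    warnings: list[str] = []
    if len(selected) < size:
        rest = flags[n_flags < 2].copy()
        rest["tier"] = "forced"
        rest = rest.sort_values(
            ["specificity", "gene"], ascending=[False, True], kind="mergesort"
        )
        selected = pd.concat([selected, rest]).head(size)
    if len(selected) < size:
        shortfall = size - len(selected)
        warnings.append(f"candidate pool short by {shortfall} genes")

    # final presentation order: tier 3, then 2, then forced; by specificity
    tier_order = {"3": 0, "2": 1, "forced": 2}
    selected = selected.assign(_t=selected["tier"].map(tier_order))
    selected = selected.sort_values(
        ["_t", "specificity", "gene"],
        ascending=[True, False, True],
        kind="mergesort",
    ).drop(columns="_t")
    cols = [
        "gene",
        "tier",
        "in_top_padj",
        "in_top_lfc",
        "in_top_spec",
        "specificity",
    ]
    return GeneSignature(
        table=selected[cols].reset_index(drop=True),
        shortfall=shortfall,
        source=source,
        warnings=warnings,
    )


def reduce_signature(
    signature: GeneSignature, sizes: Sequence[int] = DEFAULT_REDUCTIVE_SIZES
) -> dict[int, list[str]]:
    """Nested leading prefixes of the ordered signature at each size."""
    sizes = list(sizes)
    if any(s < 1 for s in sizes):
        raise ValueError("sizes must be positive")
    if any(b >= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly decreasing")
    if sizes and sizes[0] > len(signature):
        raise ValueError(
            f"size {sizes[0]} exceeds signature length {len(signature)}"
        )
    genes = signature.genes
    return {s: genes[:s] for s in sizes}
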