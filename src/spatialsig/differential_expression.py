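"""Region-vs-rest marker statistics.

For a target region against explicit reference regions, each gene gets a
natural-log fold change of mean de-logged normalized expression, a two-sided
Wilcoxon rank-sum p-value (exact for small contrasts), a Bonferroni-adjusted
p over the genes actually tested, expressing fractions inside and outside the
target, and their specificity ratio.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import ranksum_p_rows
from .core_io import NormalizedMatrix, SpotDataset

DEFAULT_SPECIFICITY_CAP = 1e6

TABLE_COLUMNS = ["gene", "lfc", "p", "p_adj", "pct_in", "pct_out", "specificity"]


@dataclass
class DifferentialTable:
    """Per-gene DE statistics for one region contrast."""

    table: pd.DataFrame
    target_region: str = ""
    reference_regions: tuple[str, ...] = ()
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"DifferentialTable missing columns {missing}")

    def significant(self, alpha: float = 0.05, lfc_min: float = 0.0) -> pd.DataFrame:
        t = self.table
        return t[(t["p_adj"] < alpha) & (t["lfc"] > lfc_min)]

    def to_csv(self, path: str | os.PathLike) -> None:
        self.table[TABLE_COLUMNS].to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "DifferentialTable":
        return cls(table=pd.read_csv(path))


def expressing_fraction(
    dataset: SpotDataset, gene: str, spot_set: Iterable[int]
) -> float:
    """Fraction of ``spot_set`` with raw count > 0 for ``gene``."""
    idx = np.asarray(list(spot_set), dtype=int)
    if idx.size == 0:
        raise ValueError("spot_set must be non-empty")
    row = dataset.counts[dataset.gene_index(gene)]
    expressed = np.zeros(dataset.n_spots, dtype=bool)
    expressed[row.indices] = True
    return float(expressed[idx].mean())


def specificity_ratio(
    pct_in: float, pct_out: float, cap: float = DEFAULT_SPECIFICITY_CAP
) -> float:
    """``pct_in / pct_out`` with 0/0 -> 0 and x/0 -> ``cap`` for x > 0."""
    if not (0 <= pct_in <= 1 and 0 <= pct_out <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if pct_out == 0:
        return 0.0 if pct_in == 0 else float(cap)
    return float(pct_in / pct_out)


def region_de(
    norm: NormalizedMatrix,
    dataset: SpotDataset,
    target_region: str,
    reference_regions: Sequence[str],
    min_pct: float = 0.1,
    lfc_threshold: float = 0.25,
    specificity_cap: float = DEFAULT_SPECIFICITY_CAP,
) -> DifferentialTable:
    """Target-vs-reference DE over all genes passing the detection filters.

    Genes with ``max(pct_in, pct_out) < min_pct`` or ``|lfc| < lfc_threshold``
    are excluded before testing; the Bonferroni denominator is the number of
    genes actually tested.
    """
    target = {target_region}
    reference = set(reference_regions)
    if target & reference:
        raise ValueError("target and reference regions must be disjoint")
    if not (0 <= min_pct < 1):
        raise ValueError("min_pct must lie in [0, 1)")
    t_idx = dataset.spots_in_regions(target)
    r_idx = dataset.spots_in_regions(reference)
    if t_idx.size == 0:
        raise ValueError(f"no spots in target region {target_region!r}")
    if r_idx.size == 0:
        raise ValueError(f"no spots in reference regions {sorted(reference)!r}")
    warnings: list[str] = []
    if t_idx.size < 3 or r_idx.size < 3:
        warnings.append(
            f"small groups: {t_idx.size} target / {r_idx.size} reference spots"
        )

    counts = dataset.counts
    pct_in = np.clip(np.asarray((counts[:, t_idx] > 0).mean(axis=1)).ravel(), 0, 1)
    pct_out = np.clip(np.asarray((counts[:, r_idx] > 0).mean(axis=1)).ravel(), 0, 1)

    vals = norm.values
    # lfc on the de-logged scale: ln(mean(expm1(x)) + 1) per group
    mean_t = _mean_expm1(vals, t_idx)
    mean_r = _mean_expm1(vals, r_idx)
    lfc = np.log(mean_t + 1.0) - np.log(mean_r + 1.0)

    tested = (np.maximum(pct_in, pct_out) >= min_pct) & (
        np.abs(lfc) >= lfc_threshold
    )
    tested_idx = np.flatnonzero(tested)
    n_tested = tested_idx.size

    both = np.concatenate([t_idx, r_idx])
    in_group = np.zeros(both.size, dtype=bool)
    in_group[: t_idx.size] = True
    p = np.ones(n_tested)
    if n_tested:
        block = vals[tested_idx][:, both].toarray()
        p = ranksum_p_rows(block, in_group)
    p_adj = np.minimum(1.0, p * n_tested)

    spec = np.array(
        [
            specificity_ratio(pi, po, cap=specificity_cap)
            for pi, po in zip(pct_in[tested_idx], pct_out[tested_idx])
        ]
    )
    table = pd.DataFrame(
        {
            "gene": dataset.gene_ids[tested_idx],
            "lfc": lfc[tested_idx],
            "p": p,
            "p_adj": p_adj,
            "pct_in": pct_in[tested_idx],
            "pct_out": pct_out[tested_idx],
            "specificity": spec,
        }
    )
    table = table.sort_values(
        ["p_adj", "p", "gene"], kind="mergesort", ignore_index=True
    )
    return DifferentialTable(
        table=table,
        target_region=target_region,
        reference_regions=tuple(sorted(reference)),
        warnings=warnings,
    )


def _mean_expm1(values, idx: np.ndarray) -> np.ndarray:
    sub = values[:, idx].copy()
    sub.data = np.expm1(sub.data)
    return np.asarray(sub.sum(axis=1)).ravel() / idx.size


def deg_set_overlap(
    tables: dict[str, DifferentialTable],
    alpha: float = 0.05,
    lfc_min: float = 0.0,
) -> pd.DataFrame:
    """Set sizes and pairwise intersections of significant enriched genes."""
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    sets = {
        name: set(t.significant(alpha=alpha, lfc_min=lfc_min)["gene"])
        for name, t in tables.items()
    }
    rows = []
    names = sorted(sets)
    for name in names:
        rows.append({"set_a": name, "set_b": name, "n": len(sets[name])})
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rows.append({"set_a": a, "set_b": b, "n": len(sets[a] & sets[b])})
    return pd.DataFrame(rows)
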