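"""Gene-set module scoring with expression-binned random controls.

A module score for a spot is the mean normalized expression of the signature
genes minus the mean over a pooled draw of control genes, where each control
is sampled from the signature gene's expression bin (equal-frequency bins of
dataset-wide mean expression).  Cell-cycle scoring runs two module scores and
assigns a phase per spot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import ranksum_p
from .core_io import NormalizedMatrix, SpotDataset, read_gene_list

DEFAULT_N_BINS = 24
DEFAULT_N_CTRL = 100

PHASES = ("S", "G2M", "G1")


@dataclass
class ModuleScores:
    """Per-spot module score plus the control draw that produced it."""

    score: np.ndarray
    gene_set: list[str]
    n_bins: int
    n_ctrl: int
    seed: int
    controls: dict[str, np.ndarray] = field(default_factory=dict)
    sampled_with_replacement: list[str] = field(default_factory=list)

    def to_frame(self, dataset: SpotDataset) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": dataset.spot_ids,
                "sample_id": dataset.sample_ids,
                "region": dataset.regions,
                "score": self.score,
            }
        )


@dataclass
class CellCycleResult:
    """S / G2M module scores and the per-spot phase call.

    Phase is G1 iff both scores are <= 0; otherwise the argmax, with positive
    ties assigned S.
    """

    s_score: np.ndarray
    g2m_score: np.ndarray
    phase: np.ndarray

    def to_frame(self, dataset: SpotDataset) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": dataset.spot_ids,
                "sample_id": dataset.sample_ids,
                "region": dataset.regions,
                "s_score": self.s_score,
                "g2m_score": self.g2m_score,
                "phase": self.phase,
            }
        )


def expression_bins(
    norm: NormalizedMatrix, gene_ids: np.ndarray, n_bins: int
) -> np.ndarray:
    """Equal-frequency bin index per gene from dataset-wide mean expression.

    Genes are ordered by (mean expression, gene id) — the id breaks ties
    deterministically — then cut into ``n_bins`` near-equal chunks.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    means = np.asarray(norm.values.mean(axis=1)).ravel()
    order = np.lexsort((np.asarray(gene_ids, dtype=object), means))
    bins = np.empty(len(gene_ids), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins


def module_score(
    norm: NormalizedMatrix,
    gene_ids: np.ndarray,
    gene_set: Iterable[str],
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> ModuleScores:
    """Score a gene set against expression-matched random controls.

    Controls for each signature gene are drawn without replacement from the
    gene's bin after removing all signature genes; bins smaller than
    ``n_ctrl`` fall back to sampling with replacement (recorded).
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    requested = list(dict.fromkeys(gene_set))
    id_to_idx = {g: i for i, g in enumerate(gene_ids)}
    present = [g for g in requested if g in id_to_idx]
    missing = [g for g in requested if g not in id_to_idx]
    if not present:
        raise ValueError(f"no gene-set genes present in dataset; missing: {missing}")
    if len(present) >= len(gene_ids):
        raise ValueError("gene_set covers the whole gene universe; no controls possible")
    if n_ctrl < 1:
        raise ValueError("n_ctrl must be >= 1")

    bins = expression_bins(norm, gene_ids, n_bins)
    sig_idx = np.array([id_to_idx[g] for g in present])
    sig_set = set(sig_idx.tolist())

    rng = np.random.default_rng(seed)
    controls: dict[str, np.ndarray] = {}
    with_repl: list[str] = []
    # fixed iteration order (sorted by gene id) keeps draws seed-stable
    for g in sorted(present):
        gi = id_to_idx[g]
        # widen symmetrically when the home bin is exhausted by signature genes
        for width in range(n_bins):
            lo, hi = bins[gi] - width, bins[gi] + width
            pool = np.flatnonzero((bins >= lo) & (bins <= hi))
            pool = np.array([i for i in pool if i not in sig_set], dtype=int)
            if pool.size:
                break
        if pool.size == 0:
            raise ValueError(f"no control candidates available for gene {g!r}")
        if pool.size >= n_ctrl:
            draw = rng.choice(pool, size=n_ctrl, replace=False)
        else:
            draw = rng.choice(pool, size=n_ctrl, replace=True)
            with_repl.append(g)
        controls[g] = np.sort(draw)

    score = _score_from_controls(norm, sig_idx, controls)
    return ModuleScores(
        score=score,
        gene_set=present,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
        controls=controls,
        sampled_with_replacement=with_repl,
    )


def _score_from_controls(
    norm: NormalizedMatrix, sig_idx: np.ndarray, controls: dict[str, np.ndarray]
) -> np.ndarray:
    vals = norm.values
    sig_mean = np.asarray(vals[sig_idx].mean(axis=0)).ravel()
    pooled = np.concatenate(list(controls.values()))
    ctrl_mean = np.asarray(vals[pooled].mean(axis=0)).ravel()
    return sig_mean - ctrl_mean


def rescore(
    norm: NormalizedMatrix, gene_ids: np.ndarray, scores: ModuleScores
) -> np.ndarray:
    """Recompute scores on (possibly different) values with a frozen draw."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    id_to_idx = {g: i for i, g in enumerate(gene_ids)}
    sig_idx = np.array([id_to_idx[g] for g in scores.gene_set])
    return _score_from_controls(norm, sig_idx, scores.controls)


def cell_cycle_score(
    norm: NormalizedMatrix,
    gene_ids: np.ndarray,
    s_genes: Sequence[str],
    g2m_genes: Sequence[str],
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> CellCycleResult:
    """Score S and G2M programs and call a phase per spot."""
    s = module_score(norm, gene_ids, s_genes, n_bins, n_ctrl, seed=seed)
    g2m = module_score(norm, gene_ids, g2m_genes, n_bins, n_ctrl, seed=seed + 1)
    phase = np.where(
        np.maximum(s.score, g2m.score) <= 0,
        "G1",
        np.where(s.score >= g2m.score, "S", "G2M"),
    )
    return CellCycleResult(s_score=s.score, g2m_score=g2m.score, phase=phase.astype(object))


def score_contrast(
    scores: np.ndarray,
    dataset: SpotDataset,
    region_a: str | Sequence[str],
    region_b: str | Sequence[str],
) -> tuple[float, float, list[str]]:
    """Mean score difference (a - b) and two-sided rank-sum p on spot scores.

    Each side may be a single region label or a collection of labels (e.g.
    blastema vs everything else).
    """
    a_regions = [region_a] if isinstance(region_a, str) else list(region_a)
    b_regions = [region_b] if isinstance(region_b, str) else list(region_b)
    a_idx = dataset.spots_in_regions(a_regions)
    b_idx = dataset.spots_in_regions(b_regions)
    if a_idx.size == 0 or b_idx.size == 0:
        raise ValueError("both regions must be non-empty")
    warnings = []
    if a_idx.size < 3 or b_idx.size < 3:
        warnings.append(f"small groups: {a_idx.size} vs {b_idx.size} spots")
    scores = np.asarray(scores, dtype=float)
    a, b = scores[a_idx], scores[b_idx]
    return float(a.mean() - b.mean()), ranksum_p(a, b), warnings


def phase_distribution(
    cc_result: CellCycleResult, dataset: SpotDataset
) -> pd.DataFrame:
    """Per-region S / G2M / G1 fractions (rows sum to 1)."""
    df = pd.DataFrame({"region": dataset.regions, "phase": cc_result.phase})
    rows = []
    for region, grp in df.groupby("region", sort=True):
        frac = grp["phase"].value_counts(normalize=True)
        rows.append(
            {
                "region": region,
                "n": len(grp),
                **{ph: float(frac.get(ph, 0.0)) for ph in PHASES},
            }
        )
    return pd.DataFrame(rows)


def builtin_gene_list_names() -> list[str]:
    root = resources.files("spatialsig.resources.gene_lists")
    return sorted(p.name[:-4] for p in root.iterdir() if p.name.endswith(".txt"))


def load_builtin_gene_list(name: str) -> list[str]:
    """Load one of the packaged (provisional, user-editable) gene lists."""
    ref = resources.files("spatialsig.resources.gene_lists") / f"{name}.txt"
    with resources.as_file(ref) as path:
        return read_gene_list(path)
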