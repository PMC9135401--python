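"""Synthetic Visium-like datasets with known ground truth.

The generator lays a hex-like spot lattice over a stylized digit: a proximal
remaining-digit block, a bone-stump block, a blastema cap distal to the stump
reference line, and a boundary band at the tip.  Counts are negative binomial
with per-gene dispersion and log-normal per-spot depth.  Planted structure —
region-enriched gene sets with controlled fold change and expressing-fraction
specificity, proximal/distal gradient programs anchored to the stump
polyline, and per-spot cell-cycle phases driving S/G2M programs — is recorded
in truth tables so every downstream stage can be checked against
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import ReferencePolyline, SpotDataset
from .spatialtime import polyline_distances


@dataclass
class PlantedSet:
    """A planted gene program.

    Exactly one of ``region`` / ``gradient`` is set.  For region sets the
    in-region NB mean is ``effect`` times the out-of-region mean, the
    out-of-region counts are additionally thinned so the expressing-fraction
    ratio hits ``specificity``.  Gradient sets multiply the base rate by
    ``exp(beta * (1 - st))`` (proximal-high) or ``exp(beta * st)``
    (distal-high) across the gradient regions.
    """

    name: str
    n_genes: int
    region: str | None = None
    gradient: str | None = None  # "proximal" or "distal"
    effect: float = 2.5
    pct_in: float = 0.5
    specificity: float | None = 4.0
    beta: float = 1.2

    def __post_init__(self) -> None:
        if (self.region is None) == (self.gradient is None):
            raise ValueError("set exactly one of region / gradient")
        if self.gradient not in (None, "proximal", "distal"):
            raise ValueError("gradient must be 'proximal' or 'distal'")
        if not (0 < self.pct_in <= 1):
            raise ValueError("pct_in target must lie in (0, 1]")
        if self.specificity is not None and self.pct_in / self.specificity > 1:
            raise ValueError("infeasible expressing-fraction target")


@dataclass
class CycleSpec:
    """Planted cell-cycle programs and per-region phase mixtures."""

    n_s_genes: int = 80
    n_g2m_genes: int = 80
    effect: float = 10.0
    base_pct: float = 0.25  # baseline expressing fraction of cycle genes
    mixture: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "blastema": (0.35, 0.30, 0.35),
            "boundary": (0.35, 0.30, 0.35),
        }
    )
    default_mixture: tuple[float, float, float] = (0.20, 0.20, 0.60)


@dataclass
class SyntheticSpec:
    """Full parameterization of one synthetic spatial sample."""

    n_genes: int = 2000
    n_cols: int = 38
    digit_rows: int = 20
    bone_rows: int = 8
    blastema_rows: int = 8
    boundary_rows: int = 4
    pitch: float = 100.0
    mean_depth: float = 4000.0
    depth_sigma: float = 0.25
    dispersion_range: tuple[float, float] = (2.0, 50.0)
    base_expr_sigma: float = 1.0
    planted_sets: list[PlantedSet] = field(
        default_factory=lambda: [
            PlantedSet(
                "blastema_program",
                n_genes=100,
                region="blastema",
                effect=2.5,
                pct_in=0.5,
                specificity=4.0,
            )
        ]
    )
    cycle: CycleSpec | None = field(default_factory=CycleSpec)
    gradient_regions: tuple[str, ...] = ("blastema", "boundary")
    sample_id: str = "synthetic"
    seed: int = 0

    @property
    def n_rows(self) -> int:
        return self.digit_rows + self.bone_rows + self.blastema_rows + self.boundary_rows

    @property
    def n_spots(self) -> int:
        return self.n_rows * self.n_cols

    def planted_gene_count(self) -> int:
        n = sum(ps.n_genes for ps in self.planted_sets)
        if self.cycle is not None:
            n += self.cycle.n_s_genes + self.cycle.n_g2m_genes
        return n


def _nb_mean_for_fraction(f: float, theta: np.ndarray) -> np.ndarray:
    """NB mean whose probability of a nonzero draw equals ``f``."""
    return theta * ((1.0 - f) ** (-1.0 / theta) - 1.0)


def _layout(spec: SyntheticSpec):
    """Hex lattice coordinates, region labels and the stump polyline."""
    dy = spec.pitch * math.sqrt(3.0) / 2.0
    rows = np.repeat(np.arange(spec.n_rows), spec.n_cols)
    cols = np.tile(np.arange(spec.n_cols), spec.n_rows)
    x = (cols + 0.5 * (rows % 2)) * spec.pitch
    y = rows * dy

    region = np.empty(spec.n_spots, dtype=object)
    d, b, bl = spec.digit_rows, spec.bone_rows, spec.blastema_rows
    region[rows < d] = "digit"
    region[(rows >= d) & (rows < d + b)] = "bone"
    region[(rows >= d + b) & (rows < d + b + bl)] = "blastema"
    region[rows >= d + b + bl] = "boundary"

    y_line = (d + b - 0.5) * dy
    x_max = (spec.n_cols - 0.5) * spec.pitch
    # slight proximal bend keeps the multi-segment path non-trivial while
    # preserving blastema-closer-than-digit ordering
    polyline = ReferencePolyline(
        sample_id=spec.sample_id,
        vertices=np.array(
            [
                [-spec.pitch, y_line],
                [x_max / 2.0, y_line - 0.2 * dy],
                [x_max + spec.pitch, y_line],
            ]
        ),
    )
    coords = np.column_stack([x, y])
    return coords, region, rows, cols, polyline


def _gradient_fraction(
    coords: np.ndarray, region: np.ndarray, spec: SyntheticSpec, polyline
) -> np.ndarray:
    """Min-max scaled stump distance over the gradient regions; NaN elsewhere."""
    st = np.full(len(region), np.nan)
    mask = np.isin(region, list(spec.gradient_regions))
    if mask.any():
        raw = polyline_distances(coords[mask], polyline)
        lo, hi = raw.min(), raw.max()
        st[mask] = 0.0 if hi == lo else (raw - lo) / (hi - lo)
    return st


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[SpotDataset, ReferencePolyline, dict[str, pd.DataFrame]]:
    """Sample one synthetic dataset; byte-identical under a fixed seed."""
    if spec.planted_gene_count() > spec.n_genes:
        raise ValueError("planted gene programs exceed n_genes")
    rng = np.random.default_rng(spec.seed)
    coords, region, rows, cols, polyline = _layout(spec)
    n_genes, n_spots = spec.n_genes, spec.n_spots
    st_frac = _gradient_fraction(coords, region, spec, polyline)

    lo, hi = spec.dispersion_range
    theta = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    base = rng.lognormal(mean=0.0, sigma=spec.base_expr_sigma, size=n_genes)
    depth = spec.mean_depth * np.exp(
        rng.normal(0.0, spec.depth_sigma, size=n_spots)
        - spec.depth_sigma**2 / 2.0
    )

    gene_truth_rows: list[dict] = []
    cursor = 0
    effect = np.ones((n_genes, n_spots))
    thin_keep = np.ones((n_genes, n_spots))

    for ps in spec.planted_sets:
        idx = np.arange(cursor, cursor + ps.n_genes)
        cursor += ps.n_genes
        if ps.region is not None:
            in_mask = region == ps.region
            if not in_mask.any():
                raise ValueError(f"planted region {ps.region!r} has no spots")
            mu_in = _nb_mean_for_fraction(ps.pct_in, theta[idx])
            base[idx] = mu_in / (spec.mean_depth * ps.effect)
            effect[np.ix_(idx, np.flatnonzero(in_mask))] = ps.effect
            if ps.specificity is not None:
                mu_out = mu_in / ps.effect
                f_nb_out = 1.0 - (theta[idx] / (theta[idx] + mu_out)) ** theta[idx]
                keep = np.minimum(1.0, (ps.pct_in / ps.specificity) / f_nb_out)
                thin_keep[np.ix_(idx, np.flatnonzero(~in_mask))] = keep[:, None]
        else:
            grad_mask = ~np.isnan(st_frac)
            base[idx] = _nb_mean_for_fraction(ps.pct_in, theta[idx]) / spec.mean_depth
            pos = st_frac[grad_mask]
            expo = (1.0 - pos) if ps.gradient == "proximal" else pos
            effect[np.ix_(idx, np.flatnonzero(grad_mask))] = np.exp(
                ps.beta * expo
            )[None, :]
        for gi in idx:
            gene_truth_rows.append(
                {
                    "gene_index": int(gi),
                    "set_name": ps.name,
                    "role": "region" if ps.region else f"gradient_{ps.gradient}",
                    "region": ps.region or "",
                    "effect": ps.effect,
                }
            )

    phase = np.full(n_spots, "G1", dtype=object)
    s_idx = g2m_idx = np.array([], dtype=int)
    if spec.cycle is not None:
        cyc = spec.cycle
        s_idx = np.arange(cursor, cursor + cyc.n_s_genes)
        cursor += cyc.n_s_genes
        g2m_idx = np.arange(cursor, cursor + cyc.n_g2m_genes)
        cursor += cyc.n_g2m_genes
        for idx, role in ((s_idx, "cycle_s"), (g2m_idx, "cycle_g2m")):
            base[idx] = _nb_mean_for_fraction(cyc.base_pct, theta[idx]) / spec.mean_depth
            for gi in idx:
                gene_truth_rows.append(
                    {
                        "gene_index": int(gi),
                        "set_name": role,
                        "role": role,
                        "region": "",
                        "effect": cyc.effect,
                    }
                )
        for r in np.unique(region):
            mix = cyc.mixture.get(str(r), cyc.default_mixture)
            mix = np.asarray(mix, dtype=float)
            mix = mix / mix.sum()
            spots_r = np.flatnonzero(region == r)
            phase[spots_r] = rng.choice(["S", "G2M", "G1"], size=spots_r.size, p=mix)
        effect[np.ix_(s_idx, np.flatnonzero(phase == "S"))] *= cyc.effect
        effect[np.ix_(g2m_idx, np.flatnonzero(phase == "G2M"))] *= cyc.effect

    # background genes rescaled so total base rate is ~1 (library ~ depth)
    planted = np.zeros(n_genes, dtype=bool)
    planted[: cursor] = True
    bg = ~planted
    bg_target = max(1e-6, 1.0 - base[planted].sum())
    base[bg] *= bg_target / base[bg].sum()

    mu = (base[:, None] * effect) * depth[None, :]
    p_nb = theta[:, None] / (theta[:, None] + mu)
    counts = rng.negative_binomial(theta[:, None] * np.ones_like(mu), p_nb)
    drop = rng.random(size=counts.shape) >= thin_keep
    counts[drop] = 0

    width = len(str(n_genes - 1))
    gene_ids = np.array([f"g{i:0{width}d}" for i in range(n_genes)], dtype=object)
    spot_ids = np.array(
        [f"spot-{r:03d}-{c:03d}" for r, c in zip(rows, cols)], dtype=object
    )
    dataset = SpotDataset(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        spot_ids=spot_ids,
        coords=coords,
        sample_ids=np.full(n_spots, spec.sample_id, dtype=object),
        regions=region,
        array_rows=rows,
        array_cols=cols,
    )

    gene_truth = pd.DataFrame(gene_truth_rows)
    if len(gene_truth):
        gene_truth["gene"] = gene_ids[gene_truth["gene_index"].to_numpy()]
    spot_truth = pd.DataFrame(
        {
            "barcode": spot_ids,
            "sample_id": spec.sample_id,
            "row": rows,
            "col": cols,
            "region": region,
            "phase": phase,
            "st_frac": st_frac,
        }
    )
    truth = {
        "genes": gene_truth,
        "spots": spot_truth,
        "params": pd.DataFrame(
            {
                "gene": gene_ids,
                "theta": theta,
                "base_rate": base,
            }
        ),
    }
    return dataset, polyline, truth


def planted_genes(truth: dict[str, pd.DataFrame], set_name: str) -> list[str]:
    g = truth["genes"]
    return list(g.loc[g["set_name"] == set_name, "gene"])


@dataclass
class CellClusterSpec:
    """Synthetic scRNAseq-like matrix sharing the spatial gene universe."""

    n_clusters: int = 5
    cells_per_cluster: int = 150
    signature_effect: float = 2.5
    marker_effect: float = 3.0
    n_markers: int = 30
    mean_depth: float = 3000.0
    depth_sigma: float = 0.3


def generate_cell_dataset(
    spec: SyntheticSpec,
    cell_spec: CellClusterSpec | None = None,
    seed: int | None = None,
) -> tuple[SpotDataset, dict[str, pd.DataFrame]]:
    """Per-cell counts with cluster truth labels.

    Cluster 0 is the blastema-fibroblast-like cluster: it up-regulates the
    first planted region set of ``spec``.  Intermediate clusters get their own
    random background markers; the last cluster is pure baseline (a null
    cluster for score calibration).  Cluster labels land in ``regions``.
    """
    cell_spec = cell_spec or CellClusterSpec()
    if seed is None:
        seed = spec.seed + 1
    region_sets = [ps for ps in spec.planted_sets if ps.region is not None]
    if not region_sets:
        raise ValueError("spec must plant at least one region gene set")
    sig = region_sets[0]
    rng = np.random.default_rng(seed)

    n_genes = spec.n_genes
    lo, hi = spec.dispersion_range
    theta = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    base = rng.lognormal(mean=0.0, sigma=spec.base_expr_sigma, size=n_genes)
    sig_idx = np.arange(sig.n_genes)
    base[sig_idx] = _nb_mean_for_fraction(sig.pct_in, theta[sig_idx]) / (
        cell_spec.mean_depth * cell_spec.signature_effect
    )
    rest = np.setdiff1d(np.arange(n_genes), sig_idx)
    base[rest] *= max(1e-6, 1.0 - base[sig_idx].sum()) / base[rest].sum()

    n_cells = cell_spec.n_clusters * cell_spec.cells_per_cluster
    cluster = np.repeat(np.arange(cell_spec.n_clusters), cell_spec.cells_per_cluster)
    depth = cell_spec.mean_depth * np.exp(
        rng.normal(0.0, cell_spec.depth_sigma, size=n_cells)
        - cell_spec.depth_sigma**2 / 2.0
    )

    effect = np.ones((n_genes, n_cells))
    effect[np.ix_(sig_idx, np.flatnonzero(cluster == 0))] = cell_spec.signature_effect
    background = np.arange(spec.planted_gene_count(), n_genes)
    marker_rows = []
    for c in range(1, cell_spec.n_clusters - 1):
        n_markers = min(cell_spec.n_markers, background.size)
        if n_markers == 0:
            break
        markers = rng.choice(background, size=n_markers, replace=False)
        background = np.setdiff1d(background, markers)
        effect[np.ix_(markers, np.flatnonzero(cluster == c))] = cell_spec.marker_effect
        marker_rows += [
            {"gene_index": int(m), "cluster": int(c)} for m in markers
        ]

    mu = (base[:, None] * effect) * depth[None, :]
    p_nb = theta[:, None] / (theta[:, None] + mu)
    counts = rng.negative_binomial(theta[:, None] * np.ones_like(mu), p_nb)

    width = len(str(n_genes - 1))
    gene_ids = np.array([f"g{i:0{width}d}" for i in range(n_genes)], dtype=object)
    cell_ids = np.array([f"cell-{i:05d}" for i in range(n_cells)], dtype=object)
    labels = np.array([f"cluster_{c}" for c in cluster], dtype=object)
    dataset = SpotDataset(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        spot_ids=cell_ids,
        coords=np.zeros((n_cells, 2)),
        sample_ids=np.full(n_cells, "cells", dtype=object),
        regions=labels,
    )
    markers_df = pd.DataFrame(marker_rows)
    if len(markers_df):
        markers_df["gene"] = gene_ids[markers_df["gene_index"].to_numpy()]
    truth = {
        "cells": pd.DataFrame({"cell": cell_ids, "cluster": labels}),
        "signature_genes": pd.DataFrame({"gene": gene_ids[sig_idx]}),
        "markers": markers_df,
    }
    return dataset, truth


def default_spec(**overrides) -> SyntheticSpec:
    """The default ~1500-spot / 2000-gene regime used across the test suite."""
    return replace(SyntheticSpec(), **overrides)
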