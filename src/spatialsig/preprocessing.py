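"""Depth normalization and log transform."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .core_io import NormalizedMatrix, SpotDataset


def normalize_log(dataset: SpotDataset, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Per-spot depth normalization followed by ``ln(1 + x)``.

    For spot ``j`` with library size ``T_j > 0``::

        value(g, j) = ln(1 + counts(g, j) * scale_factor / T_j)

    A spot with zero total count yields an all-zero column.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    counts = dataset.counts.tocsc().astype(float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    inv = np.zeros_like(totals)
    nz = totals > 0
    inv[nz] = scale_factor / totals[nz]
    scaled = counts @ sp.diags(inv)
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(values=scaled.tocsr(), scale_factor=float(scale_factor))


def filter_spots_min_counts(dataset: SpotDataset, min_counts: int) -> SpotDataset:
    """Optional QC filter: keep spots with library size >= ``min_counts``.

    Off by default in the pipeline; no QC is applied unless configured.
    """
    totals = np.asarray(dataset.counts.sum(axis=0)).ravel()
    return dataset.subset_spots(np.flatnonzero(totals >= min_counts))
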