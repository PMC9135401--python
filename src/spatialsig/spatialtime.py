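"""Proximal-distal gradient coordinate from distance to a reference polyline.

Each included spot gets its minimum Euclidean distance to the reference
polyline; distances are min-max scaled to [0, 1] per sample (0 = closest to
the reference, 1 = farthest) and per-sample results are concatenated without
re-scaling.  Binned profiles summarize any per-spot value along the axis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import ranksum_p
from .core_io import ReferencePolyline, SpotDataset


@dataclass
class SpatialTimeResult:
    """Per-spot raw distance and [0, 1]-scaled axis position."""

    table: pd.DataFrame  # columns: barcode, sample_id, region, raw_dist, st
    degenerate: bool = False

    def to_csv(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def point_segment_distance(p, a, b) -> float:
    """Euclidean distance from point ``p`` to the closed segment [a, b]."""
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:  # degenerate segment: point distance
        return float(np.hypot(*(p - a)))
    t = np.clip(float((p - a) @ ab) / denom, 0.0, 1.0)
    return float(np.hypot(*(p - (a + t * ab))))


def polyline_distances(points: np.ndarray, polyline: ReferencePolyline) -> np.ndarray:
    """Minimum distance from each point to any segment of the polyline."""
    points = np.asarray(points, dtype=float)
    verts = polyline.vertices
    a = verts[:-1][None, :, :]  # (1, S, 2)
    ab = (verts[1:] - verts[:-1])[None, :, :]
    ap = points[:, None, :] - a  # (P, S, 2)
    denom = (ab * ab).sum(axis=2)
    t = np.clip((ap * ab).sum(axis=2) / denom, 0.0, 1.0)
    closest = a + t[:, :, None] * ab
    d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    return d.min(axis=1)


def spatial_time(
    dataset: SpotDataset,
    polyline: ReferencePolyline,
    include_regions: Iterable[str],
) -> SpatialTimeResult:
    """Distance-to-reference axis for one sample's included regions.

    Scaling is strictly per sample: st = (raw - min) / (max - min) over the
    included spots.  If all distances coincide, st is set to 0 everywhere and
    the result is flagged degenerate.
    """
    include = set(include_regions)
    if not include:
        raise ValueError("include_regions must be non-empty")
    mask = np.isin(dataset.regions, list(include)) & (
        dataset.sample_ids == polyline.sample_id
    )
    idx = np.flatnonzero(mask)
    if idx.size < 2:
        raise ValueError(
            f"need >= 2 included spots for sample {polyline.sample_id!r}, "
            f"found {idx.size}"
        )
    raw = polyline_distances(dataset.coords[idx], polyline)
    lo, hi = raw.min(), raw.max()
    degenerate = hi == lo
    st = np.zeros_like(raw) if degenerate else (raw - lo) / (hi - lo)
    table = pd.DataFrame(
        {
            "barcode": dataset.spot_ids[idx],
            "sample_id": dataset.sample_ids[idx],
            "region": dataset.regions[idx],
            "raw_dist": raw,
            "st": st,
        }
    )
    return SpatialTimeResult(table=table, degenerate=degenerate)


def concatenate_samples(*results: SpatialTimeResult) -> SpatialTimeResult:
    """Row-wise union of per-sample results; no re-scaling."""
    if not results:
        raise ValueError("nothing to concatenate")
    table = pd.concat([r.table for r in results], ignore_index=True)
    dup = table.duplicated(subset=["sample_id", "barcode"])
    if dup.any():
        pair = table.loc[dup, ["sample_id", "barcode"]].iloc[0]
        raise ValueError(
            f"duplicate spot {(pair.sample_id, pair.barcode)!r} in concatenation"
        )
    return SpatialTimeResult(
        table=table, degenerate=any(r.degenerate for r in results)
    )


def binned_profile(
    st_result: SpatialTimeResult, values: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Mean/sd/n of ``values`` in equal-width st bins over [0, 1].

    Bins are right-open except the last; empty bins report n = 0 and NaN
    statistics.  ``values`` must align with the result's rows.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    st = st_result.table["st"].to_numpy()
    values = np.asarray(values, dtype=float)
    if values.shape[0] != st.shape[0]:
        raise ValueError("values must align with spatial-time rows")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.minimum(np.digitize(st, edges[1:-1], right=False), n_bins - 1)
    rows = []
    for b in range(n_bins):
        v = values[which == b]
        rows.append(
            {
                "bin": b,
                "lo": edges[b],
                "hi": edges[b + 1],
                "n": len(v),
                "mean": float(v.mean()) if len(v) else np.nan,
                "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def profile_contrast(
    st_a: SpatialTimeResult,
    values_a: np.ndarray,
    st_b: SpatialTimeResult,
    values_b: np.ndarray,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Two-group comparison of a value along the axis, per st bin.

    For each bin the mean of each group, their difference (a - b), and a
    two-sided rank-sum p-value over spot-level values are reported; bins where
    either group is empty get NaN statistics.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)

    def _assign(st):
        return np.minimum(np.digitize(st, edges[1:-1], right=False), n_bins - 1)

    wa = _assign(st_a.table["st"].to_numpy())
    wb = _assign(st_b.table["st"].to_numpy())
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    rows = []
    for b in range(n_bins):
        va, vb = values_a[wa == b], values_b[wb == b]
        row = {
            "bin": b,
            "lo": edges[b],
            "hi": edges[b + 1],
            "n_a": len(va),
            "n_b": len(vb),
            "mean_a": float(va.mean()) if len(va) else np.nan,
            "mean_b": float(vb.mean()) if len(vb) else np.nan,
        }
        if len(va) and len(vb):
            row["diff"] = row["mean_a"] - row["mean_b"]
            row["p"] = ranksum_p(va, vb)
        else:
            row["diff"] = np.nan
            row["p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
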