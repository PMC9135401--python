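"""Domain types and on-disk formats.

The pipeline substrate is :class:`SpotDataset`: a sparse genes-by-spots count
matrix with per-spot planar coordinates, sample ids and region labels.  On
disk a dataset is a MatrixMarket coordinate file with ``features.tsv`` /
``barcodes.tsv`` sidecars, a Visium-dialect positions CSV and a regions CSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

UNASSIGNED = "unassigned"

POSITIONS_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


class DataFormatError(ValueError):
    """Raised when an on-disk input violates the declared format."""


@dataclass
class SpotDataset:
    """Sparse genes × spots counts plus spot metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape ``(n_genes, n_spots)``; stored CSR.
    gene_ids, spot_ids
        Unique identifiers for rows and columns.
    coords
        Per-spot ``(x, y)`` in one planar frame per sample (full-resolution
        pixels for Visium-dialect inputs).
    sample_ids, regions
        Per-spot sample id and region label; ``unassigned`` is the reserved
        default region.
    array_rows, array_cols
        Optional lattice indices, retained as metadata only.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    spot_ids: np.ndarray
    coords: np.ndarray
    sample_ids: np.ndarray
    regions: np.ndarray
    array_rows: np.ndarray | None = None
    array_cols: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.regions = np.asarray(self.regions, dtype=object)
        n_genes, n_spots = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match counts rows")
        if len(self.spot_ids) != n_spots:
            raise ValueError("spot_ids length does not match counts columns")
        if self.coords.shape != (n_spots, 2):
            raise ValueError("coords must be (n_spots, 2)")
        if len(self.sample_ids) != n_spots or len(self.regions) != n_spots:
            raise ValueError("per-spot metadata length mismatch")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if len(set(self.spot_ids)) != n_spots:
            raise ValueError("duplicate spot barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords must be finite")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise KeyError(f"unknown gene: {gene!r}")
        return int(idx[0])

    def spots_in_regions(self, regions: Iterable[str]) -> np.ndarray:
        regions = set(regions)
        return np.flatnonzero(np.isin(self.regions, list(regions)))

    def subset_spots(self, idx: np.ndarray) -> "SpotDataset":
        idx = np.asarray(idx)
        return SpotDataset(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            spot_ids=self.spot_ids[idx],
            coords=self.coords[idx],
            sample_ids=self.sample_ids[idx],
            regions=self.regions[idx],
            array_rows=None if self.array_rows is None else self.array_rows[idx],
            array_cols=None if self.array_cols is None else self.array_cols[idx],
        )


@dataclass
class NormalizedMatrix:
    """Depth-normalized log expression; zero-count spots map to zero columns."""

    values: sp.csr_matrix
    scale_factor: float
    log_base: str = "natural"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ReferencePolyline:
    """Ordered reference vertex chain in the coordinate frame of one sample."""

    sample_id: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be (n, 2)")
        if len(self.vertices) < 2:
            raise ValueError("polyline needs at least 2 vertices")
        seg = np.diff(self.vertices, axis=0)
        lengths = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(lengths == 0):
            raise ValueError("consecutive polyline vertices must be distinct")


def _read_id_column(path: Path) -> list[str]:
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def _read_positions(path: Path) -> pd.DataFrame:
    # The classic Visium dialect is headerless; newer exports carry a header.
    with open(path) as fh:
        first = fh.readline()
    header: int | None = 0 if "barcode" in first.lower() else None
    pos = pd.read_csv(path, header=header, float_precision="round_trip")
    if pos.shape[1] != 6:
        raise DataFormatError(
            f"positions file {path} must have 6 columns, found {pos.shape[1]}"
        )
    pos.columns = POSITIONS_COLUMNS
    return pos


def read_dataset(
    counts_path: str | os.PathLike,
    positions_path: str | os.PathLike,
    regions_path: str | os.PathLike | None = None,
) -> SpotDataset:
    """Load a dataset from MTX counts + positions CSV + regions CSV.

    ``counts_path`` points at the ``.mtx`` file; ``features.tsv`` and
    ``barcodes.tsv`` are expected alongside it.  Spots with ``in_tissue == 0``
    are dropped.  Barcodes missing from the regions file are labeled
    ``unassigned``; a regions barcode absent from the counts is a hard error.
    """
    counts_path = Path(counts_path)
    try:
        mat = scipy.io.mmread(counts_path)
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise DataFormatError(f"malformed MatrixMarket file {counts_path}: {exc}") from exc
    mat = sp.csc_matrix(mat)
    if mat.nnz and np.any(mat.data != np.round(mat.data)):
        raise DataFormatError("counts matrix must be integer-valued")
    mat = mat.astype(np.int64)

    genes = _read_id_column(counts_path.parent / "features.tsv")
    barcodes = _read_id_column(counts_path.parent / "barcodes.tsv")
    if len(set(genes)) != len(genes):
        raise DataFormatError("duplicate feature ids in features.tsv")
    if len(set(barcodes)) != len(barcodes):
        raise DataFormatError("duplicate barcodes in barcodes.tsv")
    if mat.shape != (len(genes), len(barcodes)):
        raise DataFormatError(
            f"matrix shape {mat.shape} does not match sidecars "
            f"({len(genes)} features, {len(barcodes)} barcodes)"
        )

    pos = _read_positions(Path(positions_path))
    if pos["barcode"].duplicated().any():
        dup = pos.loc[pos["barcode"].duplicated(), "barcode"].iloc[0]
        raise DataFormatError(f"duplicate barcode in positions: {dup!r}")
    pos = pos[pos["in_tissue"].astype(int) == 1]

    regions_map: dict[str, tuple[str, str]] = {}
    if regions_path is not None:
        reg = pd.read_csv(regions_path)
        expected = {"barcode", "sample_id", "region"}
        if not expected.issubset(reg.columns):
            raise DataFormatError(
                f"regions file must have columns {sorted(expected)}"
            )
        if reg["barcode"].duplicated().any():
            dup = reg.loc[reg["barcode"].duplicated(), "barcode"].iloc[0]
            raise DataFormatError(f"duplicate barcode in regions: {dup!r}")
        counts_barcodes = set(barcodes)
        for row in reg.itertuples(index=False):
            if row.barcode not in counts_barcodes:
                raise DataFormatError(
                    f"regions barcode {row.barcode!r} not present in counts"
                )
            regions_map[row.barcode] = (str(row.sample_id), str(row.region))

    barcode_to_col = {b: i for i, b in enumerate(barcodes)}
    keep = [b for b in pos["barcode"] if b in barcode_to_col]
    pos = pos.set_index("barcode").loc[keep]
    cols = np.array([barcode_to_col[b] for b in keep], dtype=int)

    sample_ids = []
    region_labels = []
    for b in keep:
        sid, reg_label = regions_map.get(b, ("sample", UNASSIGNED))
        sample_ids.append(sid)
        region_labels.append(reg_label)

    coords = np.column_stack(
        [
            pos["pxl_col_in_fullres"].to_numpy(dtype=float),
            pos["pxl_row_in_fullres"].to_numpy(dtype=float),
        ]
    )
    return SpotDataset(
        counts=sp.csr_matrix(mat[:, cols]),
        gene_ids=np.array(genes, dtype=object),
        spot_ids=np.array(keep, dtype=object),
        coords=coords,
        sample_ids=np.array(sample_ids, dtype=object),
        regions=np.array(region_labels, dtype=object),
        array_rows=pos["array_row"].to_numpy(),
        array_cols=pos["array_col"].to_numpy(),
    )


def write_dataset(dataset: SpotDataset, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the MTX + sidecars + positions + regions file set.

    ``read_dataset`` on the emitted files reproduces counts, coordinates and
    labels exactly.
    """
    if dataset.n_spots == 0:
        raise ValueError("refusing to write a dataset with 0 spots")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
        "positions": out / "positions.csv",
        "regions": out / "regions.csv",
    }
    scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(dataset.counts), field="integer")
    paths["features"].write_text("".join(f"{g}\n" for g in dataset.gene_ids))
    paths["barcodes"].write_text("".join(f"{b}\n" for b in dataset.spot_ids))

    n = dataset.n_spots
    arr_rows = dataset.array_rows if dataset.array_rows is not None else np.zeros(n, int)
    arr_cols = dataset.array_cols if dataset.array_cols is not None else np.zeros(n, int)
    pos = pd.DataFrame(
        {
            "barcode": dataset.spot_ids,
            "in_tissue": np.ones(n, dtype=int),
            "array_row": arr_rows,
            "array_col": arr_cols,
            "pxl_row_in_fullres": dataset.coords[:, 1],
            "pxl_col_in_fullres": dataset.coords[:, 0],
        }
    )
    # %.17g round-trips IEEE doubles exactly
    pos.to_csv(paths["positions"], index=False, float_format="%.17g")
    reg = pd.DataFrame(
        {
            "barcode": dataset.spot_ids,
            "sample_id": dataset.sample_ids,
            "region": dataset.regions,
        }
    )
    reg.to_csv(paths["regions"], index=False)
    return paths


def qc_metrics(dataset: SpotDataset) -> pd.DataFrame:
    """Per-spot ``n_count`` (total UMIs) and ``n_feature`` (detected genes)."""
    csc = dataset.counts.tocsc()
    n_count = np.asarray(csc.sum(axis=0)).ravel()
    n_feature = np.diff(csc.indptr)
    return pd.DataFrame(
        {
            "barcode": dataset.spot_ids,
            "sample_id": dataset.sample_ids,
            "region": dataset.regions,
            "n_count": n_count.astype(int),
            "n_feature": n_feature.astype(int),
        }
    )


def read_polylines(path: str | os.PathLike) -> dict[str, ReferencePolyline]:
    """Read polylines from a CSV with header ``sample_id,order,x,y``."""
    df = pd.read_csv(path)
    expected = {"sample_id", "order", "x", "y"}
    if not expected.issubset(df.columns):
        raise DataFormatError(f"polyline file must have columns {sorted(expected)}")
    out: dict[str, ReferencePolyline] = {}
    for sid, grp in df.groupby("sample_id", sort=True):
        grp = grp.sort_values("order")
        out[str(sid)] = ReferencePolyline(
            sample_id=str(sid), vertices=grp[["x", "y"]].to_numpy(dtype=float)
        )
    return out


def write_polylines(
    polylines: Sequence[ReferencePolyline], path: str | os.PathLike
) -> None:
    rows = []
    for pl in polylines:
        for i, (x, y) in enumerate(pl.vertices):
            rows.append({"sample_id": pl.sample_id, "order": i, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """One gene symbol per line; ``#`` starts a comment."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    return genes


def concat_datasets(datasets: Sequence[SpotDataset]) -> SpotDataset:
    """Column-concatenate datasets sharing one gene universe.

    Barcodes must be unique across inputs (prefix them per sample upstream if
    needed).
    """
    if not datasets:
        raise ValueError("no datasets to concatenate")
    first = datasets[0]
    for ds in datasets[1:]:
        if not np.array_equal(ds.gene_ids, first.gene_ids):
            raise ValueError("datasets must share an identical gene universe")
    return SpotDataset(
        counts=sp.hstack([ds.counts for ds in datasets]).tocsr(),
        gene_ids=first.gene_ids,
        spot_ids=np.concatenate([ds.spot_ids for ds in datasets]),
        coords=np.vstack([ds.coords for ds in datasets]),
        sample_ids=np.concatenate([ds.sample_ids for ds in datasets]),
        regions=np.concatenate([ds.regions for ds in datasets]),
    )
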