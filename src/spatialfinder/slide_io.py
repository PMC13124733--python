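"""Readers and writers for every on-disk artifact the pipeline touches.

The bundle layout mirrors a 10x Visium HD dataset package: scale-factor metadata
as JSON, spot positions as Parquet, counts as a filtered feature-barcode HDF5
matrix (or an MTX triplet), plus an HDF5 nuclei table produced by segmentation
(group ``SegmentationNode`` holding centroids, detection probabilities,
embeddings and labels in parallel datasets).

All pixel coordinates are 0-based, row-major; intervals are half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

__all__ = [
    "ScaleFactors",
    "SpotTable",
    "CountMatrix",
    "NucleiTable",
    "CropBounds",
    "compute_crop_bounds",
    "read_scalefactors",
    "write_scalefactors",
    "read_spot_positions",
    "write_spot_positions",
    "read_counts",
    "write_counts_10x_h5",
    "write_counts_mtx",
    "read_nuclei",
    "write_nuclei",
    "write_roi_report",
    "read_roi_report",
    "validate_bundle",
]

POSITION_COLUMNS = ("spot_id", "in_tissue", "pxl_row_in_fullres", "pxl_col_in_fullres")


@dataclass(frozen=True)
class ScaleFactors:
    """Imaging scale metadata (``scalefactors_json.json``)."""

    microns_per_pixel: float
    spot_diameter_fullres: float

    def __post_init__(self) -> None:
        if not (self.microns_per_pixel > 0 and self.spot_diameter_fullres > 0):
            raise ValueError("scale factors must be strictly positive")


@dataclass(frozen=True)
class CropBounds:
    """Half-open pixel box ``[row_min, row_max) x [col_min, col_max)`` in the fullres frame."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise ValueError("crop bounds must be non-empty (min < max)")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min

    @property
    def width(self) -> int:
        return self.col_max - self.col_min

    def contains(self, row, col) -> np.ndarray:
        row = np.asarray(row)
        col = np.asarray(col)
        return (
            (row >= self.row_min)
            & (row < self.row_max)
            & (col >= self.col_min)
            & (col < self.col_max)
        )


class SpotTable:
    """Spot positions in the fullres pixel frame (``tissue_positions.parquet``)."""

    def __init__(self, df: pd.DataFrame):
        for col in POSITION_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"spot table missing required column {col!r}")
        if df["spot_id"].duplicated().any():
            raise ValueError("spot_id values must be unique")
        if (df["pxl_row_in_fullres"] < 0).any() or (df["pxl_col_in_fullres"] < 0).any():
            raise ValueError("spot pixel coordinates must be non-negative")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def spot_id(self) -> np.ndarray:
        return self.df["spot_id"].to_numpy()

    @property
    def rows(self) -> np.ndarray:
        return self.df["pxl_row_in_fullres"].to_numpy()

    @property
    def cols(self) -> np.ndarray:
        return self.df["pxl_col_in_fullres"].to_numpy()

    @property
    def in_tissue(self) -> np.ndarray:
        return self.df["in_tissue"].to_numpy().astype(bool)


class CountMatrix:
    """Sparse spots x genes non-negative integer counts with aligned identifiers."""

    def __init__(self, matrix, spot_ids, genes):
        matrix = sparse.csr_matrix(matrix)
        spot_ids = np.asarray(spot_ids, dtype=object)
        genes = np.asarray(genes, dtype=object)
        if matrix.shape[0] == 0:
            raise ValueError("count matrix has 0 spots")
        if matrix.shape != (len(spot_ids), len(genes)):
            raise ValueError(
                f"count matrix shape {matrix.shape} does not match "
                f"{len(spot_ids)} spots x {len(genes)} genes"
            )
        if matrix.nnz and matrix.data.min() < 0:
            raise ValueError("counts must be non-negative")
        upper = pd.Index([str(g).upper() for g in genes])
        if upper.duplicated().any():
            raise ValueError("gene symbols must be unique after upper-casing")
        self.matrix = matrix
        self.spot_ids = spot_ids
        self.genes = genes

    @property
    def shape(self):
        return self.matrix.shape

    def gene_index(self, symbol: str) -> int:
        """Case-insensitive lookup of a gene column (10x symbol case varies)."""
        target = symbol.upper()
        for i, g in enumerate(self.genes):
            if str(g).upper() == target:
                return i
        raise KeyError(symbol)


@dataclass
class NucleiTable:
    """Segmented nuclei: centroids (cropped-frame px), embeddings, labels.

    ``label`` entries are empty strings until assigned.
    """

    nucleus_id: np.ndarray
    centroid_row: np.ndarray
    centroid_col: np.ndarray
    embedding: np.ndarray
    detection_prob: np.ndarray
    label: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.nucleus_id)
        self.nucleus_id = np.asarray(self.nucleus_id, dtype=np.int64)
        self.centroid_row = np.asarray(self.centroid_row, dtype=np.int64)
        self.centroid_col = np.asarray(self.centroid_col, dtype=np.int64)
        self.embedding = np.asarray(self.embedding, dtype=np.float64)
        self.detection_prob = np.asarray(self.detection_prob, dtype=np.float64)
        if self.label is None:
            self.label = np.full(n, "", dtype=object)
        else:
            self.label = np.asarray(self.label, dtype=object)
        if self.embedding.ndim != 2 or self.embedding.shape[0] != n:
            raise ValueError("embedding must be an (n_nuclei, D) matrix")
        for name in ("centroid_row", "centroid_col", "detection_prob", "label"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match nucleus_id")
        if self.detection_prob.size and not (
            (self.detection_prob >= 0).all() and (self.detection_prob <= 1).all()
        ):
            raise ValueError("detection_prob must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.nucleus_id)

    @property
    def dim(self) -> int:
        return self.embedding.shape[1]

    def with_labels(self, labels) -> "NucleiTable":
        return NucleiTable(
            self.nucleus_id,
            self.centroid_row,
            self.centroid_col,
            self.embedding,
            self.detection_prob,
            np.asarray(labels, dtype=object),
        )


def compute_crop_bounds(spots: SpotTable, sf: ScaleFactors) -> CropBounds:
    """Minimum bounding rectangle of in-tissue spots, padded by the spot diameter.

    Padding is applied on every side and then clamped at zero, so the crop never
    leaves the image frame on the origin side.
    """
    mask = spots.in_tissue
    if not mask.any():
        raise ValueError("no in-tissue spots: cannot compute crop bounds")
    rows = spots.rows[mask]
    cols = spots.cols[mask]
    pad = int(round(sf.spot_diameter_fullres))
    return CropBounds(
        row_min=max(0, int(rows.min()) - pad),
        row_max=int(rows.max()) + pad + 1,
        col_min=max(0, int(cols.min()) - pad),
        col_max=int(cols.max()) + pad + 1,
    )


# ---------------------------------------------------------------------------
# scale factors (JSON)


def read_scalefactors(path) -> ScaleFactors:
    with open(path) as fh:
        obj = json.load(fh)
    for key in ("microns_per_pixel", "spot_diameter_fullres"):
        if key not in obj:
            raise ValueError(f"scalefactors file missing field {key!r}")
    return ScaleFactors(
        microns_per_pixel=float(obj["microns_per_pixel"]),
        spot_diameter_fullres=float(obj["spot_diameter_fullres"]),
    )


def write_scalefactors(sf: ScaleFactors, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "microns_per_pixel": sf.microns_per_pixel,
                "spot_diameter_fullres": sf.spot_diameter_fullres,
            },
            fh,
            indent=1,
        )


# ---------------------------------------------------------------------------
# spot positions (Parquet)


def read_spot_positions(path) -> SpotTable:
    df = pd.read_parquet(path)
    # 10x names the identifier column "barcode"
    if "barcode" in df.columns and "spot_id" not in df.columns:
        df = df.rename(columns={"barcode": "spot_id"})
    for col in POSITION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"positions file missing column {col!r}")
    return SpotTable(df[list(POSITION_COLUMNS)])


def write_spot_positions(spots: SpotTable, path) -> None:
    spots.df.to_parquet(path, index=False)


# ---------------------------------------------------------------------------
# counts (10x filtered feature-barcode HDF5, or MTX triplet)


def read_counts(path) -> CountMatrix:
    """Read counts from a 10x HDF5 file or an MTX directory.

    HDF5 files store genes x barcodes CSC under the ``matrix`` group; the
    returned matrix is transposed to spots x genes.
    """
    path = Path(path)
    if path.is_dir():
        return _read_counts_mtx(path)
    with h5py.File(path, "r") as fh:
        if "matrix" not in fh:
            raise ValueError("counts HDF5 missing group 'matrix'")
        grp = fh["matrix"]
        for key in ("data", "indices", "indptr", "shape", "barcodes"):
            if key not in grp:
                raise ValueError(f"counts HDF5 missing dataset 'matrix/{key}'")
        if "features" not in grp or "name" not in grp["features"]:
            raise ValueError("counts HDF5 missing dataset 'matrix/features/name'")
        shape = tuple(grp["shape"][:])  # (genes, barcodes)
        mat = sparse.csc_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]), shape=shape
        )
        barcodes = [b.decode() for b in grp["barcodes"][:]]
        genes = [g.decode() for g in grp["features"]["name"][:]]
    return CountMatrix(mat.T.tocsr(), barcodes, genes)


def write_counts_10x_h5(cm: CountMatrix, path) -> None:
    """Write a 10x-style filtered feature-barcode HDF5 (CSC, genes x barcodes)."""
    mat = cm.matrix.T.tocsc()  # genes x barcodes
    n_genes = len(cm.genes)
    ids = np.array([f"GENE{i:05d}".encode() for i in range(n_genes)])
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("matrix")
        grp.create_dataset("data", data=mat.data.astype(np.int32))
        grp.create_dataset("indices", data=mat.indices.astype(np.int64))
        grp.create_dataset("indptr", data=mat.indptr.astype(np.int64))
        grp.create_dataset("shape", data=np.asarray(mat.shape, dtype=np.int32))
        grp.create_dataset(
            "barcodes", data=np.array([str(b).encode() for b in cm.spot_ids])
        )
        feat = grp.create_group("features")
        feat.create_dataset("id", data=ids)
        feat.create_dataset(
            "name", data=np.array([str(g).encode() for g in cm.genes])
        )
        feat.create_dataset(
            "feature_type", data=np.array([b"Gene Expression"] * n_genes)
        )
        feat.create_dataset("genome", data=np.array([b"synthetic"] * n_genes))
        feat.create_dataset("_all_tag_keys", data=np.array([b"genome"]))


def write_counts_mtx(cm: CountMatrix, outdir) -> None:
    """Write an MTX triplet: matrix.mtx (genes x spots), features.tsv, barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), cm.matrix.T.tocoo())
    pd.Series(cm.genes).to_csv(outdir / "features.tsv", index=False, header=False, sep="\t")
    pd.Series(cm.spot_ids).to_csv(outdir / "barcodes.tsv", index=False, header=False, sep="\t")


def _read_counts_mtx(outdir: Path) -> CountMatrix:
    mtx = outdir / "matrix.mtx"
    if not mtx.exists():
        raise ValueError(f"MTX directory {outdir} missing matrix.mtx")
    mat = sparse.csr_matrix(mmread(str(mtx)).T)
    genes = pd.read_csv(outdir / "features.tsv", header=None, sep="\t")[0].tolist()
    barcodes = pd.read_csv(outdir / "barcodes.tsv", header=None, sep="\t")[0].tolist()
    return CountMatrix(mat, barcodes, genes)


# ---------------------------------------------------------------------------
# nuclei (HDF5, group SegmentationNode)

_NUCLEI_GROUP = "SegmentationNode"
_NUCLEI_DATASETS = ("nucleus_id", "centroid_row", "centroid_col", "detection_prob")


def read_nuclei(path) -> NucleiTable:
    with h5py.File(path, "r") as fh:
        if _NUCLEI_GROUP not in fh:
            raise ValueError(f"nuclei HDF5 missing group {_NUCLEI_GROUP!r}")
        grp = fh[_NUCLEI_GROUP]
        if "embedding" not in grp:
            raise ValueError(f"nuclei HDF5 missing dataset {_NUCLEI_GROUP}/embedding")
        for key in _NUCLEI_DATASETS:
            if key not in grp:
                raise ValueError(f"nuclei HDF5 missing dataset {_NUCLEI_GROUP}/{key}")
        label = (
            np.array([s.decode() for s in grp["label"][:]], dtype=object)
            if "label" in grp
            else None
        )
        return NucleiTable(
            nucleus_id=grp["nucleus_id"][:],
            centroid_row=grp["centroid_row"][:],
            centroid_col=grp["centroid_col"][:],
            embedding=grp["embedding"][:],
            detection_prob=grp["detection_prob"][:],
            label=label,
        )


def write_nuclei(nuclei: NucleiTable, path) -> None:
    with h5py.File(path, "w") as fh:
        grp = fh.create_group(_NUCLEI_GROUP)
        grp.create_dataset("nucleus_id", data=nuclei.nucleus_id)
        grp.create_dataset("centroid_row", data=nuclei.centroid_row)
        grp.create_dataset("centroid_col", data=nuclei.centroid_col)
        grp.create_dataset("embedding", data=nuclei.embedding)
        grp.create_dataset("detection_prob", data=nuclei.detection_prob)
        grp.create_dataset(
            "label", data=np.array([str(s).encode() for s in nuclei.label])
        )


# ---------------------------------------------------------------------------
# ROI report (CSV + JSON run manifest)


def write_roi_report(ranking, path, manifest: dict | None = None) -> None:
    """Write a ranked ROI table as CSV plus a JSON run manifest alongside it.

    ``ranking`` is an :class:`~spatialfinder.evaluation.RegionRanking`; component
    scores, when attached, become extra columns.
    """
    if len(ranking) == 0:
        raise ValueError("cannot write a report for an empty ranking")
    path = Path(path)
    data = {
        "rank": np.arange(1, len(ranking) + 1),
        "anchor_row": ranking.anchors[:, 0],
        "anchor_col": ranking.anchors[:, 1],
        "score": ranking.scores,
    }
    for name, values in (ranking.components or {}).items():
        data[name] = values
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")
    import spatialfinder

    info = {
        "method": ranking.method,
        "n_windows": len(ranking),
        "spatialfinder_version": spatialfinder.__version__,
        "numpy_version": np.__version__,
    }
    info.update(manifest or {})
    with open(path.with_suffix(".manifest.json"), "w") as fh:
        json.dump(info, fh, indent=1, default=str)


def read_roi_report(path):
    from .evaluation import RegionRanking

    df = pd.read_csv(path)
    components = {
        c: df[c].to_numpy()
        for c in df.columns
        if c not in ("rank", "anchor_row", "anchor_col", "score")
    }
    return RegionRanking(
        anchors=df[["anchor_row", "anchor_col"]].to_numpy(),
        scores=df["score"].to_numpy(),
        method="report",
        components=components or None,
    )


def validate_bundle(bundle_dir) -> dict:
    """Parse every artifact in a slide bundle directory; return a summary dict."""
    bundle_dir = Path(bundle_dir)
    summary = {}
    sf = read_scalefactors(bundle_dir / "scalefactors_json.json")
    summary["microns_per_pixel"] = sf.microns_per_pixel
    spots = read_spot_positions(bundle_dir / "tissue_positions.parquet")
    summary["n_spots"] = len(spots)
    h5 = bundle_dir / "filtered_feature_bc_matrix.h5"
    counts = read_counts(h5 if h5.exists() else bundle_dir / "counts_mtx")
    summary["n_genes"] = counts.shape[1]
    if set(counts.spot_ids) != set(spots.spot_id):
        raise ValueError("count matrix barcodes do not match spot positions")
    nuclei_path = bundle_dir / "nuclei.h5"
    if nuclei_path.exists():
        nuclei = read_nuclei(nuclei_path)
        summary["n_nuclei"] = len(nuclei)
        summary["embedding_dim"] = nuclei.dim
    crop = compute_crop_bounds(spots, sf)
    summary["crop_height_px"] = crop.height
    summary["crop_width_px"] = crop.width
    return summary
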