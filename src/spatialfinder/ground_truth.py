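"""Benchmark regional rankings from spot-level gene expression.

Ground truth is built without looking at the image: each expression spot is
CP10K/log1p-normalized and classified by the argmax of mean marker-set
expression (spots whose best score falls below 1.0 normalized units are
"Unclassified"), then spot classifications are aggregated over the same 8x8
patch window lattice the model uses — density-weighted Shannon entropy for
the diversity benchmark, tumor-spot counts for the targeted benchmark.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources

import numpy as np
from scipy import sparse

from .patch_grid import PATCH_PX, PatchGrid
from .roi_scoring import ScoreConfig, rank_windows, sliding_windows, window_label_counts
from .slide_io import CountMatrix, CropBounds, SpotTable

__all__ = [
    "MarkerSet",
    "load_marker_set",
    "normalize_counts",
    "classify_spots",
    "assign_spots_to_patches",
    "gt_diversity_ranking",
    "gt_tumor_ranking",
    "UNCLASSIFIED",
]

UNCLASSIFIED = "Unclassified"
SCORE_THRESHOLD = 1.0  # log-normalized expression units


class MarkerSet:
    """Ordered mapping of cell-type name -> canonical marker gene symbols."""

    def __init__(self, markers: dict):
        if not markers:
            raise ValueError("marker set is empty")
        for name, genes in markers.items():
            if not genes:
                raise ValueError(f"cell type {name!r} has an empty gene list")
        if len(set(markers)) != len(markers):
            raise ValueError("cell-type names must be unique")
        self.markers = {str(k): [str(g) for g in v] for k, v in markers.items()}

    @property
    def types(self) -> list[str]:
        return list(self.markers)

    def __getitem__(self, name: str) -> list[str]:
        return self.markers[name]


def load_marker_set(name_or_path) -> MarkerSet:
    """Load a packaged marker set by name (lung_colon, prostate, kidney) or a JSON path."""
    name = str(name_or_path)
    pkg_file = resources.files("spatialfinder.markers").joinpath(f"{name}.json")
    if pkg_file.is_file():
        return MarkerSet(json.loads(pkg_file.read_text()))
    with open(name) as fh:
        return MarkerSet(json.load(fh))


def normalize_counts(cm: CountMatrix):
    """CP10K + log1p normalization: ``x_g = ln(1 + 10000 * c_g / total)`` per spot.

    Zero-total spots are dropped with a warning. Returns
    ``(normalized csr matrix, spot_ids, genes)``.
    """
    mat = cm.matrix.tocsr().astype(np.float64)
    totals = np.asarray(mat.sum(axis=1)).ravel()
    keep = totals > 0
    if not keep.any():
        raise ValueError("all spots have zero total counts")
    if not keep.all():
        warnings.warn(f"dropping {(~keep).sum()} spots with zero total counts")
        mat = mat[keep]
        totals = totals[keep]
    scale = sparse.diags(1e4 / totals)
    normed = scale @ mat
    normed.data = np.log1p(normed.data)
    return normed.tocsr(), cm.spot_ids[keep], cm.genes


def classify_spots(normed, spot_ids, genes, markers: MarkerSet):
    """Assign each spot the argmax marker-set mean score, or "Unclassified".

    Gene symbols are matched case-insensitively; markers absent from the gene
    universe are dropped per type with a warning, and a type with no present
    marker raises. Exact score ties resolve to the first type in marker order.

    Returns ``(assigned labels, score matrix spots x types, type order)``.
    """
    gene_pos = {str(g).upper(): i for i, g in enumerate(genes)}
    types = markers.types
    scores = np.zeros((normed.shape[0], len(types)))
    for t, name in enumerate(types):
        cols = [gene_pos[g.upper()] for g in markers[name] if g.upper() in gene_pos]
        missing = [g for g in markers[name] if g.upper() not in gene_pos]
        if missing:
            warnings.warn(f"type {name!r}: markers absent from matrix: {missing}")
        if not cols:
            raise ValueError(f"no marker of type {name!r} found in the gene universe")
        scores[:, t] = np.asarray(normed[:, cols].mean(axis=1)).ravel()
    best = np.argmax(scores, axis=1)  # first max wins ties
    assigned = np.array([types[b] for b in best], dtype=object)
    assigned[scores[np.arange(len(best)), best] < SCORE_THRESHOLD] = UNCLASSIFIED
    return assigned, scores, types


def assign_spots_to_patches(spots: SpotTable, crop: CropBounds, patch_px: int = PATCH_PX):
    """Patch (row, col) containing each spot's pixel; spots outside the crop dropped.

    Returns ``(patch_rc array, kept-index array into the spot table)``.
    """
    inside = crop.contains(spots.rows, spots.cols)
    keep = np.flatnonzero(inside)
    pr = (spots.rows[keep] - crop.row_min) // patch_px
    pc = (spots.cols[keep] - crop.col_min) // patch_px
    return np.column_stack([pr, pc]).astype(np.int64), keep


def _windowed_spot_counts(spot_patch_rc, spot_types, type_order, grid, cfg):
    anchors = sliding_windows(grid, cfg)
    counts = window_label_counts(
        spot_patch_rc, spot_types, type_order, grid.shape, cfg.window, anchors
    )
    return anchors, counts


def gt_diversity_ranking(
    spot_patch_rc,
    spot_types,
    grid: PatchGrid,
    cfg: ScoreConfig = ScoreConfig(),
    min_spots: int = 10,
    include_unclassified: bool = False,
):
    """Ground-truth diversity: spot-type entropy (base 2) x ln(1 + N_spots) per window.

    Windows with fewer than ``min_spots`` classified spots score zero.
    "Unclassified" spots are excluded from both the proportions and N unless
    ``include_unclassified``.
    """
    type_order = [
        t for t in dict.fromkeys(spot_types)
        if include_unclassified or t != UNCLASSIFIED
    ]
    anchors = sliding_windows(grid, cfg)
    if not type_order:
        return rank_windows(anchors, np.zeros(len(anchors)), method="gt_diversity")
    counts = window_label_counts(
        spot_patch_rc, spot_types, type_order, grid.shape, cfg.window, anchors
    )
    n = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / np.maximum(n, 1)[:, None]
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    scores = -(p * logp).sum(axis=1) * np.log1p(n)
    scores[n < min_spots] = 0.0
    return rank_windows(anchors, scores, method="gt_diversity")


def gt_tumor_ranking(
    spot_patch_rc,
    spot_types,
    grid: PatchGrid,
    cfg: ScoreConfig = ScoreConfig(),
    tumor_type: str = "tumor",
):
    """Ground-truth targeted ranking: tumor-spot count per window, descending."""
    present = set(spot_types)
    if tumor_type not in present:
        raise ValueError(f"no spots classified as {tumor_type!r}")
    anchors, counts = _windowed_spot_counts(
        spot_patch_rc, spot_types, [tumor_type], grid, cfg
    )
    return rank_windows(anchors, counts[:, 0].astype(float), method="gt_tumor")
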