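"""Sliding-window ROI generation and the two window scores.

Each candidate ROI is an 8x8-patch window (1792x1792 px at 224-px patches),
scanned over the patch grid with a configurable stride (default one patch,
giving ~10,000 overlapping windows on a ~105x105-patch slide).

Two scores rank windows:

* **Regional diversity** — ``w * visual + (1 - w) * cellular`` where the
  visual component is the median pairwise Euclidean distance between
  UMAP-reduced patch embeddings inside the window, and the cellular component
  is the base-2 Shannon entropy of the window's cell-type proportions weighted
  by ``ln(1 + N)`` cell density (zero below 10 cells). Both components are
  min-max normalized over all windows before blending.
* **Targeted conditional** — ``w * vlm + (1 - w) * count`` where the VLM
  component is the 0.9-quantile of patch-to-prompt cosine similarity, clipped
  at zero and sharpened by an exponent (default 10), and the count component
  is ``ln(1 + #target cells)``. Again min-max normalized before blending.

Top regions are picked greedily in descending score order, accepting a window
only if it is spatially compatible with everything already accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .patch_grid import PATCH_PX, PatchGrid

__all__ = [
    "WINDOW_PATCHES",
    "ScoreConfig",
    "sliding_windows",
    "reduce_embeddings",
    "visual_diversity",
    "visual_diversity_scores",
    "cellular_entropy",
    "cellular_entropy_scores",
    "minmax_normalize",
    "diversity_score",
    "text_similarity_score",
    "text_similarity_scores",
    "cell_abundance_score",
    "cell_abundance_scores",
    "targeted_score",
    "rank_windows",
    "greedy_nonoverlap_select",
    "weight_sweep",
    "window_geometry",
    "score_windows",
]

WINDOW_PATCHES = 8


@dataclass(frozen=True)
class ScoreConfig:
    """Tunable parameters of the window scores.

    ``w`` blends the two components of either score (default 0.5); ``quantile``
    and ``exponent`` shape the text-similarity aggregation; ``min_cells`` is
    the density floor below which the entropy component is zero.
    """

    w: float = 0.5
    umap_dims: int = 30
    umap_neighbors: int = 15
    umap_min_dist: float = 0.1
    umap_seed: int = 42
    quantile: float = 0.9
    exponent: float = 10.0
    min_cells: int = 10
    stride: int = 1
    window: int = WINDOW_PATCHES
    prompt: str = "tumor"
    entropy_exclude: tuple = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must lie in (0, 1)")
        if self.stride < 1 or self.window < 1 or self.min_cells < 0:
            raise ValueError("stride/window/min_cells out of range")


# ---------------------------------------------------------------------------
# window lattice


def sliding_windows(grid: PatchGrid, cfg: ScoreConfig = ScoreConfig()) -> np.ndarray:
    """Anchors (top-left patch coords) of all fully-contained windows.

    Returns an (M, 2) int array on the lattice {0, stride, 2*stride, ...};
    count = ceil((n_rows - window + 1)/stride) * ceil((n_cols - window + 1)/stride).
    """
    w, s = cfg.window, cfg.stride
    if grid.n_rows < w or grid.n_cols < w:
        raise ValueError(
            f"grid {grid.shape} smaller than the {w}x{w} window"
        )
    rows = np.arange(0, grid.n_rows - w + 1, s)
    cols = np.arange(0, grid.n_cols - w + 1, s)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


# ---------------------------------------------------------------------------
# visual diversity


def reduce_embeddings(emb, cfg: ScoreConfig = ScoreConfig()):
    """Reduce patch embeddings to ``umap_dims`` dimensions with a seeded UMAP fit.

    The reduction is fit globally on all retained patches. If the input
    dimension is already <= the target, vectors pass through unchanged.
    """
    from .embedding_backend import EmbeddingMatrix

    x = emb.vectors if hasattr(emb, "vectors") else np.asarray(emb, dtype=np.float64)
    ids = emb.ids if hasattr(emb, "ids") else list(range(len(x)))
    if len(x) < cfg.umap_neighbors + 1:
        raise ValueError(
            f"{len(x)} patches is too few for n_neighbors={cfg.umap_neighbors}; "
            "lower umap_neighbors"
        )
    if x.shape[1] <= cfg.umap_dims:
        return EmbeddingMatrix(ids=list(ids), vectors=x.copy())
    import warnings

    import umap

    reducer = umap.UMAP(
        n_components=cfg.umap_dims,
        n_neighbors=cfg.umap_neighbors,
        min_dist=cfg.umap_min_dist,
        random_state=cfg.umap_seed,
    )
    with warnings.catch_warnings():
        # umap notes that a fixed random_state forces single-threaded fitting
        warnings.filterwarnings("ignore", message=".*n_jobs value.*", category=UserWarning)
        reduced = reducer.fit_transform(x)
    return EmbeddingMatrix(ids=list(ids), vectors=np.asarray(reduced, dtype=np.float64))


def visual_diversity(vectors: np.ndarray) -> float:
    """Median pairwise Euclidean distance among a window's patch vectors.

    Windows with fewer than two retained patches score zero.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    if len(vectors) < 2:
        return 0.0
    return float(np.median(pdist(vectors)))


def _patch_index_grid(ids, grid_shape) -> np.ndarray:
    """Map (row, col) -> row index into the reduced matrix; -1 where absent."""
    idx = np.full(grid_shape, -1, dtype=np.int64)
    for i, (r, c) in enumerate(ids):
        idx[r, c] = i
    return idx


def visual_diversity_scores(anchors, reduced, grid: PatchGrid, cfg: ScoreConfig = ScoreConfig()):
    """Raw (un-normalized) visual diversity for every window anchor."""
    idx = _patch_index_grid(reduced.ids, grid.shape)
    x = reduced.vectors
    w = cfg.window
    out = np.zeros(len(anchors))
    for i, (r, c) in enumerate(anchors):
        members = idx[r : r + w, c : c + w].ravel()
        members = members[members >= 0]
        if len(members) >= 2:
            out[i] = float(np.median(pdist(x[members])))
    return out


# ---------------------------------------------------------------------------
# cellular entropy


def shannon_entropy(counts) -> float:
    """Base-2 Shannon entropy of a count vector (0 log 0 := 0)."""
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def cellular_entropy(type_counts, min_cells: int = 10) -> float:
    """Density-weighted entropy: ``H * ln(1 + N)``; zero if ``N < min_cells``."""
    counts = np.asarray(type_counts, dtype=np.float64)
    n = counts.sum()
    if n < min_cells:
        return 0.0
    return shannon_entropy(counts) * math.log1p(n)


def window_label_counts(patch_rc, labels, label_order, grid_shape, window, anchors) -> np.ndarray:
    """Per-window per-label counts of items assigned to patches.

    ``patch_rc`` is an (N, 2) array of patch coordinates per item; items
    outside the grid are ignored. Returns an (M, T) count matrix via a
    summed-area table over the per-patch count grid.
    """
    patch_rc = np.asarray(patch_rc)
    label_idx = {name: t for t, name in enumerate(label_order)}
    t_count = len(label_order)
    per_patch = np.zeros((grid_shape[0], grid_shape[1], t_count), dtype=np.int64)
    for (r, c), lab in zip(patch_rc, labels):
        if 0 <= r < grid_shape[0] and 0 <= c < grid_shape[1] and lab in label_idx:
            per_patch[r, c, label_idx[lab]] += 1
    # summed-area table with a zero border
    sat = np.zeros((grid_shape[0] + 1, grid_shape[1] + 1, t_count), dtype=np.int64)
    np.cumsum(per_patch, axis=0, out=sat[1:, 1:])
    np.cumsum(sat[1:, 1:], axis=1, out=sat[1:, 1:])
    anchors = np.asarray(anchors)
    r0, c0 = anchors[:, 0], anchors[:, 1]
    r1, c1 = r0 + window, c0 + window
    return sat[r1, c1] - sat[r0, c1] - sat[r1, c0] + sat[r0, c0]


def cellular_entropy_scores(
    anchors, nuclei_patch_rc, nuclei_labels, grid: PatchGrid, cfg: ScoreConfig = ScoreConfig()
) -> np.ndarray:
    """Raw density-weighted entropy for every window.

    Nuclei are assigned to patches by centroid containment; classes listed in
    ``cfg.entropy_exclude`` are removed from both the proportions and N.
    """
    label_order = [
        l for l in dict.fromkeys(nuclei_labels) if l and l not in cfg.entropy_exclude
    ]
    if not label_order:
        return np.zeros(len(anchors))
    counts = window_label_counts(
        nuclei_patch_rc, nuclei_labels, label_order, grid.shape, cfg.window, anchors
    )
    n = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / np.maximum(n, 1)[:, None]
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    h = -(p * logp).sum(axis=1)
    scores = h * np.log1p(n)
    scores[n < cfg.min_cells] = 0.0
    return scores


# ---------------------------------------------------------------------------
# normalization and blends


def minmax_normalize(scores) -> np.ndarray:
    """Map scores onto [0, 1] via (x - min)/(max - min); constant input -> all 0."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("need at least one window to normalize")
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        return np.zeros_like(scores)
    return (scores - lo) / (hi - lo)


def _blend(a, b, w: float) -> np.ndarray:
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    return w * np.asarray(a, dtype=np.float64) + (1.0 - w) * np.asarray(b, dtype=np.float64)


def diversity_score(visual_norm, cellular_norm, w: float = 0.5) -> np.ndarray:
    """Regional diversity blend ``w * visual + (1 - w) * cellular`` (normalized inputs)."""
    return _blend(visual_norm, cellular_norm, w)


def targeted_score(vlm_norm, count_norm, w: float = 0.5) -> np.ndarray:
    """Targeted conditional blend ``w * vlm + (1 - w) * count`` (normalized inputs)."""
    return _blend(vlm_norm, count_norm, w)


# ---------------------------------------------------------------------------
# targeted components


def text_similarity_score(similarities, cfg: ScoreConfig = ScoreConfig()) -> float:
    """Aggregate per-patch prompt similarities for one window.

    Linear-interpolation ``quantile`` of the similarities, clipped below at 0,
    raised to ``exponent``. Empty windows score 0. Min-max normalization over
    all windows happens afterwards, at combination time.
    """
    similarities = np.asarray(similarities, dtype=np.float64)
    if similarities.size == 0:
        return 0.0
    q = float(np.quantile(similarities, cfg.quantile))
    return max(q, 0.0) ** cfg.exponent


def text_similarity_scores(anchors, emb, text_vec, grid: PatchGrid, cfg: ScoreConfig = ScoreConfig()):
    """Raw VLM text-similarity component for every window."""
    from .embedding_backend import cosine_similarity_matrix

    sims = cosine_similarity_matrix(emb.vectors, text_vec)
    sim_grid = np.full(grid.shape, np.nan)
    for (r, c), s in zip(emb.ids, sims):
        sim_grid[r, c] = s
    w = cfg.window
    out = np.zeros(len(anchors))
    for i, (r, c) in enumerate(anchors):
        vals = sim_grid[r : r + w, c : c + w].ravel()
        vals = vals[~np.isnan(vals)]
        out[i] = text_similarity_score(vals, cfg)
    return out


def cell_abundance_score(target_count: int) -> float:
    """``ln(1 + count)`` of target-class nuclei in the window."""
    if target_count < 0:
        raise ValueError("count must be non-negative")
    return math.log1p(target_count)


def cell_abundance_scores(
    anchors, nuclei_patch_rc, nuclei_labels, target_class: str, grid: PatchGrid,
    cfg: ScoreConfig = ScoreConfig(),
) -> np.ndarray:
    if target_class not in set(nuclei_labels):
        raise ValueError(f"target class {target_class!r} absent from nucleus labels")
    counts = window_label_counts(
        nuclei_patch_rc, nuclei_labels, [target_class], grid.shape, cfg.window, anchors
    )[:, 0]
    return np.log1p(counts.astype(np.float64))


# ---------------------------------------------------------------------------
# ranking, selection, sweeps


def rank_windows(anchors, scores, method: str = "model", components: dict | None = None):
    """Build a RegionRanking sorted by descending score, ties by (row, col)."""
    from .evaluation import RegionRanking

    anchors = np.asarray(anchors)
    scores = np.asarray(scores, dtype=np.float64)
    order = np.lexsort((anchors[:, 1], anchors[:, 0], -scores))
    comp = None
    if components:
        comp = {k: np.asarray(v)[order] for k, v in components.items()}
    return RegionRanking(
        anchors=anchors[order], scores=scores[order], method=method, components=comp
    )


def greedy_nonoverlap_select(ranking, k: int, mode: str = "any_axis", window: int = WINDOW_PATCHES):
    """Greedy top-k selection of spatially compatible windows.

    Scanning in ranked order, a candidate is accepted iff against **every**
    accepted window the separation test passes:

    * ``any_axis`` (default): |dRow| >= window OR |dCol| >= window — guarantees
      zero patch overlap between selected windows;
    * ``both_axes`` (literal center-separation rule): AND of the two.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("any_axis", "both_axes"):
        raise ValueError(f"unknown separation mode {mode!r}")
    accepted: list[int] = []
    for i, (r, c) in enumerate(ranking.anchors):
        ok = True
        for j in accepted:
            dr = abs(int(r) - int(ranking.anchors[j, 0]))
            dc = abs(int(c) - int(ranking.anchors[j, 1]))
            sep = (dr >= window or dc >= window) if mode == "any_axis" else (
                dr >= window and dc >= window
            )
            if not sep:
                ok = False
                break
        if ok:
            accepted.append(i)
            if len(accepted) == k:
                break
    from .evaluation import RegionRanking

    idx = np.asarray(accepted, dtype=int)
    return RegionRanking(
        anchors=ranking.anchors[idx],
        scores=ranking.scores[idx],
        method=f"{ranking.method}:top{k}",
    )


def weight_sweep(anchors, component_a, component_b, w_grid, method: str = "model"):
    """Rankings for each blend weight, reusing cached normalized components.

    ``component_a`` carries weight ``w`` (visual or VLM), ``component_b``
    weight ``1 - w`` (cellular or count). Returns ``{w: RegionRanking}``.
    """
    w_grid = list(w_grid)
    if not w_grid:
        raise ValueError("weight grid must be non-empty")
    a = minmax_normalize(component_a)
    b = minmax_normalize(component_b)
    return {
        w: rank_windows(anchors, _blend(a, b, w), method=f"{method}:w={w}")
        for w in w_grid
    }


# ---------------------------------------------------------------------------
# geometry


def window_geometry(
    microns_per_pixel: float,
    patch_px: int = PATCH_PX,
    window: int = WINDOW_PATCHES,
    capture_mm: float = 6.5,
) -> dict:
    """Physical size of a patch and window, and the window's share of the capture area."""
    patch_um = patch_px * microns_per_pixel
    window_um = window * patch_um
    frac = (window_um / 1000.0) ** 2 / capture_mm**2
    return {
        "patch_um": patch_um,
        "window_um": window_um,
        "capture_area_percent": 100.0 * frac,
    }


# ---------------------------------------------------------------------------
# end-to-end scoring convenience


def score_windows(
    grid: PatchGrid,
    cfg: ScoreConfig,
    mode: str = "diversity",
    embeddings=None,
    nuclei_patch_rc=None,
    nuclei_labels=None,
    text_vec=None,
    target_class: str | None = None,
    reduced=None,
):
    """Compute one of the two window scores end to end and return a ranking.

    ``mode='diversity'`` needs embeddings (reduced or raw) and labeled nuclei;
    ``mode='targeted'`` needs embeddings + a text vector and a target class.
    Component scores are attached to the returned ranking.
    """
    anchors = sliding_windows(grid, cfg)
    if mode == "diversity":
        if reduced is None:
            reduced = reduce_embeddings(embeddings, cfg)
        vis = minmax_normalize(visual_diversity_scores(anchors, reduced, grid, cfg))
        cell = minmax_normalize(
            cellular_entropy_scores(anchors, nuclei_patch_rc, nuclei_labels, grid, cfg)
        )
        combined = diversity_score(vis, cell, cfg.w)
        comps = {"score_visual": vis, "score_cellular": cell}
    elif mode == "targeted":
        vlm = minmax_normalize(
            text_similarity_scores(anchors, embeddings, text_vec, grid, cfg)
        )
        count = minmax_normalize(
            cell_abundance_scores(
                anchors, nuclei_patch_rc, nuclei_labels, target_class, grid, cfg
            )
        )
        combined = targeted_score(vlm, count, cfg.w)
        comps = {"score_vlm": vlm, "score_count": count}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return rank_windows(anchors, combined, method=mode, components=comps)
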