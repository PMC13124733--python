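"""Ranking comparison metrics: Spearman's rho, Overlap@K, Set IoU@K.

A model ranking is compared against a ground-truth ranking over the same
window lattice. Spearman's rho is computed over the anchor intersection with
average ranks for tied scores; Overlap@K counts exact anchor matches in the
two top-K sets; Set IoU@K rasterizes each top-K set into its union of patch
cells and takes the intersection-over-union. Bootstrap confidence intervals
resample the evaluated windows with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .roi_scoring import WINDOW_PATCHES

__all__ = [
    "RegionRanking",
    "EvalReport",
    "BootstrapCI",
    "RandomBaselineResult",
    "spearman_common",
    "overlap_at_k",
    "set_iou_at_k",
    "bootstrap_rho_ci",
    "random_baseline",
    "evaluate_rankings",
]


@dataclass
class RegionRanking:
    """An ordered list of window anchors with scores, comparable across methods."""

    anchors: np.ndarray
    scores: np.ndarray
    method: str = "model"
    components: dict | None = None

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, dtype=np.int64).reshape(-1, 2)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.scores) != len(self.anchors):
            raise ValueError("scores and anchors must align")
        keys = {tuple(a) for a in self.anchors}
        if len(keys) != len(self.anchors):
            raise ValueError("window anchors must be unique")
        if len(self.scores) > 1 and (np.diff(self.scores) > 1e-12).any():
            raise ValueError("scores must be non-increasing in rank order")

    def __len__(self) -> int:
        return len(self.anchors)

    def top_k_anchors(self, k: int) -> set:
        if k > len(self):
            raise ValueError(f"K={k} exceeds ranking length {len(self)}")
        return {tuple(a) for a in self.anchors[:k]}

    def score_map(self) -> dict:
        return {tuple(a): s for a, s in zip(self.anchors, self.scores)}


@dataclass
class BootstrapCI:
    lo: float
    hi: float
    n_used: int
    n_skipped: int


@dataclass
class EvalReport:
    rho: float
    rho_ci: tuple
    overlap_at: dict
    set_iou_at: dict
    n_common: int


@dataclass
class RandomBaselineResult:
    mean_rho: float
    mean_overlap: float
    rhos: np.ndarray
    overlaps: np.ndarray
    k: int


def _common_scores(model: RegionRanking, gt: RegionRanking):
    ms, gs = model.score_map(), gt.score_map()
    common = sorted(set(ms) & set(gs))
    return (
        np.array([ms[a] for a in common]),
        np.array([gs[a] for a in common]),
        common,
    )


def spearman_common(model: RegionRanking, gt: RegionRanking) -> float:
    """Spearman rank correlation over the anchors common to both rankings."""
    a, b, common = _common_scores(model, gt)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common anchors; need >= 3")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def overlap_at_k(model: RegionRanking, gt: RegionRanking, k: int) -> float:
    """Percent of the top-K anchor sets shared (coordinates matched exactly)."""
    return 100.0 * len(model.top_k_anchors(k) & gt.top_k_anchors(k)) / k


def rasterize_windows(anchors, window: int = WINDOW_PATCHES) -> set:
    """Union of patch cells covered by a set of window anchors."""
    cells = set()
    for r, c in anchors:
        for dr in range(window):
            for dc in range(window):
                cells.add((r + dr, c + dc))
    return cells


def set_iou_at_k(
    model: RegionRanking, gt: RegionRanking, k: int, window: int = WINDOW_PATCHES
) -> float:
    """IoU of the patch-cell unions covered by the two top-K window sets."""
    a = rasterize_windows(model.top_k_anchors(k), window)
    b = rasterize_windows(gt.top_k_anchors(k), window)
    return len(a & b) / len(a | b)


def bootstrap_rho_ci(
    model: RegionRanking, gt: RegionRanking, n_boot: int = 1000, seed: int = 0
) -> BootstrapCI:
    """95% bootstrap CI for rho, resampling the evaluated windows with replacement.

    Replicates whose resampled score vectors are constant (rank correlation
    undefined) are skipped and counted.
    """
    a, b, common = _common_scores(model, gt)
    n = len(common)
    if n < 10:
        raise ValueError(f"only {n} common anchors; need >= 10 for a bootstrap CI")
    rng = np.random.default_rng(seed)
    rhos = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        ra, rb = a[idx], b[idx]
        if np.ptp(ra) == 0 or np.ptp(rb) == 0:
            skipped += 1
            continue
        rhos.append(stats.spearmanr(ra, rb).statistic)
    if not rhos:
        raise ValueError("all bootstrap replicates were degenerate")
    lo, hi = np.percentile(rhos, [2.5, 97.5])
    return BootstrapCI(lo=float(lo), hi=float(hi), n_used=len(rhos), n_skipped=skipped)


def random_baseline(
    gt: RegionRanking, frac_k: float = 0.10, n_seeds: int = 100, seed: int = 0
) -> RandomBaselineResult:
    """Chance-level reference: rank the ground-truth window set by uniform noise.

    For each replicate, every window receives an independent Uniform(0,1)
    score; Spearman's rho against the ground truth and Overlap@K with
    K = round(frac_k * N) are recorded and averaged over replicates.
    """
    n = len(gt)
    k = int(round(frac_k * n))
    if k < 1:
        raise ValueError("frac_k too small: K would be 0")
    gt_scores = gt.scores
    gt_top = gt.top_k_anchors(k)
    rng = np.random.default_rng(seed)
    rhos = np.empty(n_seeds)
    overlaps = np.empty(n_seeds)
    for i in range(n_seeds):
        u = rng.random(n)
        rhos[i] = stats.spearmanr(u, gt_scores).statistic
        top_idx = np.argsort(-u)[:k]
        top = {tuple(gt.anchors[j]) for j in top_idx}
        overlaps[i] = 100.0 * len(top & gt_top) / k
    return RandomBaselineResult(
        mean_rho=float(rhos.mean()),
        mean_overlap=float(overlaps.mean()),
        rhos=rhos,
        overlaps=overlaps,
        k=k,
    )


def evaluate_rankings(
    model: RegionRanking,
    gt: RegionRanking,
    ks=(10, 50, 100),
    overlap_frac: float | None = 0.10,
    n_boot: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Full three-metric comparison with a bootstrap CI on rho."""
    _, _, common = _common_scores(model, gt)
    rho = spearman_common(model, gt)
    ci = bootstrap_rho_ci(model, gt, n_boot=n_boot, seed=seed)
    ks = list(ks)
    if overlap_frac is not None:
        ks.append(int(round(overlap_frac * len(common))))
    overlap = {k: overlap_at_k(model, gt, k) for k in ks if 1 <= k <= min(len(model), len(gt))}
    iou = {k: set_iou_at_k(model, gt, k) for k in overlap}
    return EvalReport(
        rho=rho, rho_ci=(ci.lo, ci.hi), overlap_at=overlap, set_iou_at=iou,
        n_common=len(common),
    )
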