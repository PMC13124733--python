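"""Patch lattice construction and the two-tier background filtering cascade.

The cropped tissue image is divided into a non-overlapping grid of 224x224-px
patches; incomplete edge tiles are padded with white pixels. Filtering runs in
short-circuit order: a pre-embedding filter drops exactly-saturated patches,
then tier 1 removes bright uniform background and tier 2 removes residual
low-variance patches. Padding pixels participate in patch statistics, so edge
patches tend to be tier-1 filtered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PATCH_PX",
    "PatchGrid",
    "build_grid",
    "extract_patch",
    "patch_stats",
    "prefilter_patch",
    "tier1_background",
    "tier2_lowvar",
    "apply_filters",
    "write_patch_zarr",
    "read_patch_zarr",
]

PATCH_PX = 224

# tier-1 / tier-2 thresholds
TIER1_MEAN = 235.0
TIER1_STD = 20.0
TIER1_RGB = 230
TIER1_FRAC = 0.85
TIER2_STD = 10.0


@dataclass
class PatchGrid:
    """A row/col-indexed patch lattice with retention flags and pixel stats."""

    n_rows: int
    n_cols: int
    patch_px: int = PATCH_PX
    prefiltered_out: np.ndarray = field(default=None)
    tier1_background: np.ndarray = field(default=None)
    tier2_lowvar: np.ndarray = field(default=None)
    mean_gray: np.ndarray = field(default=None)
    std_gray: np.ndarray = field(default=None)
    frac_bright_rgb: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        shape = (self.n_rows, self.n_cols)
        for name in ("prefiltered_out", "tier1_background", "tier2_lowvar"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(shape, dtype=bool))
        for name in ("mean_gray", "std_gray", "frac_bright_rgb"):
            if getattr(self, name) is None:
                setattr(self, name, np.full(shape, np.nan))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def retained(self) -> np.ndarray:
        """Boolean mask of patches surviving all filters."""
        return ~(self.prefiltered_out | self.tier1_background | self.tier2_lowvar)


def build_grid(image_height_px: int, image_width_px: int, patch_px: int = PATCH_PX) -> PatchGrid:
    """Patch lattice covering an image; the last row/col is white-padded if short."""
    if image_height_px < 1 or image_width_px < 1:
        raise ValueError("image dimensions must be positive")
    n_rows = -(-image_height_px // patch_px)  # ceil
    n_cols = -(-image_width_px // patch_px)
    return PatchGrid(n_rows=n_rows, n_cols=n_cols, patch_px=patch_px)


def extract_patch(image: np.ndarray, row: int, col: int, patch_px: int = PATCH_PX) -> np.ndarray:
    """Cut patch (row, col) out of an HxWx3 uint8 image, white-padding at edges."""
    r0, c0 = row * patch_px, col * patch_px
    tile = image[r0 : r0 + patch_px, c0 : c0 + patch_px]
    if tile.shape[:2] == (patch_px, patch_px):
        return np.ascontiguousarray(tile)
    out = np.full((patch_px, patch_px, 3), 255, dtype=np.uint8)
    out[: tile.shape[0], : tile.shape[1]] = tile
    return out


def _grayscale(patch: np.ndarray) -> np.ndarray:
    # ITU-R 601 luma, rounded to integer gray levels
    p = patch.astype(np.float64)
    return np.round(0.299 * p[..., 0] + 0.587 * p[..., 1] + 0.114 * p[..., 2])


def patch_stats(patch: np.ndarray) -> tuple[float, float, float]:
    """(mean_gray, std_gray, frac of pixels with all RGB channels >= 230).

    Standard deviation is the population std over the grayscale patch.
    """
    gray = _grayscale(patch)
    frac = float((patch.min(axis=-1) >= TIER1_RGB).mean())
    return float(gray.mean()), float(gray.std()), frac


def prefilter_patch(patch: np.ndarray) -> bool:
    """Pre-embedding filter: completely white (all 255) or completely black (all 0)."""
    lo, hi = patch.min(), patch.max()
    return bool((lo == 255 and hi == 255) or (lo == 0 and hi == 0))


def tier1_background(patch: np.ndarray, color_check_enabled: bool = False) -> bool:
    """Strong background: mean gray >= 235 and std < 20 (+ optional RGB color check)."""
    mean, std, frac = patch_stats(patch)
    flag = mean >= TIER1_MEAN and std < TIER1_STD
    if flag and color_check_enabled:
        flag = frac >= TIER1_FRAC
    return bool(flag)


def tier2_lowvar(patch: np.ndarray) -> bool:
    """Residual low-variance tissue: grayscale std < 10."""
    _, std, _ = patch_stats(patch)
    return bool(std < TIER2_STD)


def apply_filters(grid: PatchGrid, patch_source, color_check_enabled: bool = False) -> PatchGrid:
    """Run the filtering cascade over every patch in the grid, in place.

    ``patch_source(row, col)`` must return the patch pixel array. Order:
    prefilter first; tier 1 only on prefilter survivors; tier 2 only on tier-1
    survivors — so no patch carries more than one flag.
    """
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            patch = patch_source(r, c)
            mean, std, frac = patch_stats(patch)
            grid.mean_gray[r, c] = mean
            grid.std_gray[r, c] = std
            grid.frac_bright_rgb[r, c] = frac
            if prefilter_patch(patch):
                grid.prefiltered_out[r, c] = True
                continue
            t1 = mean >= TIER1_MEAN and std < TIER1_STD
            if t1 and color_check_enabled:
                t1 = frac >= TIER1_FRAC
            if t1:
                grid.tier1_background[r, c] = True
                continue
            if std < TIER2_STD:
                grid.tier2_lowvar[r, c] = True
    return grid


def write_patch_zarr(grid: PatchGrid, patch_source, path) -> None:
    """Persist all patches as a compressed Zarr array indexed (row, col, y, x, channel)."""
    import zarr

    p = grid.patch_px
    arr = zarr.open(
        str(path),
        mode="w",
        shape=(grid.n_rows, grid.n_cols, p, p, 3),
        chunks=(1, 1, p, p, 3),
        dtype="u1",
    )
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            arr[r, c] = patch_source(r, c)


def read_patch_zarr(path):
    import zarr

    return zarr.open(str(path), mode="r")
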