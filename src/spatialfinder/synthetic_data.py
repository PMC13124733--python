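"""Self-contained synthetic slides with planted spatial structure.

A scenario lays rectangular zones over a patch grid. Each zone carries a
visual appearance (one or more embedding prototypes; more than one gives a
patch-level checkerboard of mixed morphology), a nucleus cell-type mixture
with a density, and a spot cell-type mixture. From this the generator emits
every artifact the pipeline consumes — patch grid with retention flags, patch
embeddings, a nuclei table with hidden truth labels, a spot table with a
count matrix whose marker genes are up-shifted in matching spots — plus the
planted ground-truth diversity and tumor rankings computed from the true spot
labels with the same formulas the expression-based benchmark uses.

In deterministic mode, per-patch cell and spot counts are exact and type
allocation uses largest-remainder rounding, so planted rankings are exactly
recoverable; in stochastic mode types are drawn multinomially and counts are
negative-binomial (the standard overdispersed model for sequencing counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .embedding_backend import EmbeddingMatrix, SyntheticBackend
from .ground_truth import MarkerSet, gt_diversity_ranking, gt_tumor_ranking
from .patch_grid import PatchGrid, apply_filters
from .roi_scoring import ScoreConfig, score_windows, sliding_windows
from .slide_io import CountMatrix, NucleiTable, ScaleFactors, SpotTable

__all__ = [
    "Zone",
    "SyntheticScenario",
    "SyntheticSlide",
    "make_slide",
    "make_nuclei_scenario",
    "margin_preset",
    "complementary_preset",
    "prostate_like_preset",
    "lung_like_preset",
    "background_only_preset",
    "recovery_experiment",
]

# canonical marker genes reused so packaged marker sets classify synthetic spots
_DEFAULT_MARKERS = {
    "tumor": ["EPCAM", "CEACAM5"],
    "immune": ["PTPRC", "CD3D", "CD8A", "MS4A1"],
    "stromal": ["COL1A1"],
    "endothelial": ["PECAM1"],
}

_PALETTE = [
    (150, 90, 160),
    (200, 140, 180),
    (120, 80, 140),
    (210, 170, 150),
    (160, 130, 190),
    (180, 100, 120),
]
_BACKGROUND_RGB = (246, 246, 246)


@dataclass(frozen=True)
class Zone:
    """A rectangular region of the patch grid (half-open patch-unit bounds)."""

    name: str
    row0: int
    row1: int
    col0: int
    col1: int
    visual_classes: tuple = (0,)
    nuclei_mixture: dict | None = None
    spot_mixture: dict | None = None
    nuclei_per_patch: int = 20

    @property
    def is_background(self) -> bool:
        return self.nuclei_mixture is None and self.spot_mixture is None


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for one synthetic slide."""

    n_rows: int
    n_cols: int
    zones: tuple
    cell_types: tuple
    patch_px: int = 224
    embedding_dim_patch: int = 32
    embedding_dim_nucleus: int = 64
    sigma_patch: float = 0.0
    sigma_nucleus: float = 0.0
    modality_gap_deg: float = 0.0
    spots_per_patch_side: int = 2
    filler_genes: int = 40
    filler_mean: float = 5.0
    marker_baseline: float = 0.02
    marker_effect: float = 8.0
    deterministic: bool = True
    nb_dispersion: float = 10.0
    microns_per_pixel: float = 0.274
    seed: int = 0
    render_images: bool = False


@dataclass
class SyntheticSlide:
    """Everything make_slide emits, aligned to one patch grid."""

    scenario: SyntheticScenario
    grid: PatchGrid
    patch_embeddings: EmbeddingMatrix
    patch_backend: SyntheticBackend
    nuclei: NucleiTable
    nuclei_truth: np.ndarray
    nucleus_backend: SyntheticBackend
    spots: SpotTable
    spot_truth: np.ndarray
    spot_patch_rc: np.ndarray
    counts: CountMatrix
    markers: MarkerSet
    scalefactors: ScaleFactors
    planted_diversity: object
    planted_tumor: object | None
    render_patch: object = None

    @property
    def nuclei_patch_rc(self) -> np.ndarray:
        pr = self.nuclei.centroid_row // self.grid.patch_px
        pc = self.nuclei.centroid_col // self.grid.patch_px
        return np.column_stack([pr, pc])

    def write_bundle(self, outdir) -> None:
        """Write the slide in the same on-disk formats the readers consume."""
        from pathlib import Path

        from . import slide_io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        slide_io.write_scalefactors(self.scalefactors, outdir / "scalefactors_json.json")
        slide_io.write_spot_positions(self.spots, outdir / "tissue_positions.parquet")
        slide_io.write_counts_10x_h5(self.counts, outdir / "filtered_feature_bc_matrix.h5")
        slide_io.write_nuclei(
            self.nuclei.with_labels(self.nuclei_truth), outdir / "nuclei.h5"
        )
        slide_io.write_roi_report(self.planted_diversity, outdir / "planted_diversity.csv")
        if self.planted_tumor is not None:
            slide_io.write_roi_report(self.planted_tumor, outdir / "planted_tumor.csv")


def _allocate_types(n: int, mixture: dict, cell_types, deterministic: bool,
                    rng: np.random.Generator) -> np.ndarray:
    """Type indices for n items from a mixture (largest remainder or multinomial)."""
    names = list(mixture)
    probs = np.array([mixture[k] for k in names], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ValueError(f"mixture {mixture} does not sum to 1")
    if deterministic:
        raw = probs * n
        counts = np.floor(raw).astype(int)
        rem = n - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
    else:
        counts = rng.multinomial(n, probs)
    idx = np.repeat([cell_types.index(k) for k in names], counts)
    return idx


def _zone_map(scn: SyntheticScenario) -> np.ndarray:
    zmap = np.full((scn.n_rows, scn.n_cols), -1, dtype=int)
    for zi, z in enumerate(scn.zones):
        if not (0 <= z.row0 < z.row1 <= scn.n_rows and 0 <= z.col0 < z.col1 <= scn.n_cols):
            raise ValueError(f"zone {z.name!r} exceeds the grid")
        zmap[z.row0 : z.row1, z.col0 : z.col1] = zi
    return zmap


def _patch_renderer(scn: SyntheticScenario, zmap: np.ndarray):
    """Deterministic zone-colored texture renderer for patch (r, c)."""

    def render(r: int, c: int) -> np.ndarray:
        zi = zmap[r, c]
        if zi < 0 or scn.zones[zi].is_background:
            base, noise = _BACKGROUND_RGB, 4.0
        else:
            z = scn.zones[zi]
            vc = z.visual_classes[(r + c) % len(z.visual_classes)]
            base, noise = _PALETTE[vc % len(_PALETTE)], 28.0
        rng = np.random.default_rng([scn.seed, 7, r, c])
        img = rng.normal(loc=base, scale=noise, size=(scn.patch_px, scn.patch_px, 3))
        return np.clip(img, 0, 255).astype(np.uint8)

    return render


def make_slide(scn: SyntheticScenario, cfg: ScoreConfig = ScoreConfig()) -> SyntheticSlide:
    """Generate a full synthetic slide; bit-identical for a fixed scenario seed."""
    zmap = _zone_map(scn)
    grid = PatchGrid(n_rows=scn.n_rows, n_cols=scn.n_cols, patch_px=scn.patch_px)
    cell_types = list(scn.cell_types)
    ss = np.random.SeedSequence(scn.seed)
    s_patch, s_nuc, s_spot, s_count, s_backend = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(5)
    )
    render = _patch_renderer(scn, zmap)
    background = np.zeros(grid.shape, dtype=bool)
    for r in range(scn.n_rows):
        for c in range(scn.n_cols):
            zi = zmap[r, c]
            background[r, c] = zi < 0 or scn.zones[zi].is_background
    if scn.render_images:
        apply_filters(grid, render)
    else:
        grid.tier1_background[:] = background

    # ---- patch embeddings (retained patches only) --------------------------
    n_visual = max(
        (max(z.visual_classes) for z in scn.zones if not z.is_background), default=0
    ) + 1
    n_visual = max(n_visual, 2)
    # name each visual class after the first zone that wears it, so text
    # prompts like "tumor" retrieve that zone's appearance prototype
    visual_names = []
    for k in range(n_visual):
        name = next(
            (z.name for z in scn.zones if not z.is_background and k in z.visual_classes),
            None,
        )
        if name is None or name in visual_names:
            name = f"visual_{k}"
        visual_names.append(name)
    patch_backend = SyntheticBackend(
        n_classes=n_visual, dim=scn.embedding_dim_patch, sigma=scn.sigma_patch,
        seed=s_backend, class_names=visual_names,
    )
    rng_patch = np.random.default_rng(s_patch)
    ids, vcls = [], []
    for r in range(scn.n_rows):
        for c in range(scn.n_cols):
            if not grid.retained[r, c]:
                continue
            zi = zmap[r, c]
            z = scn.zones[zi] if zi >= 0 else None
            vc = 0 if z is None else z.visual_classes[(r + c) % len(z.visual_classes)]
            ids.append((r, c))
            vcls.append(vc)
    vectors = patch_backend.embed_classes(np.asarray(vcls, dtype=int), rng_patch) \
        if ids else np.zeros((0, scn.embedding_dim_patch))
    patch_emb = EmbeddingMatrix(ids=ids, vectors=vectors)

    # ---- nuclei ------------------------------------------------------------
    nucleus_backend = SyntheticBackend(
        n_classes=len(cell_types), dim=scn.embedding_dim_nucleus,
        sigma=scn.sigma_nucleus, seed=s_backend + 1, class_names=cell_types,
        modality_gap_deg=scn.modality_gap_deg,
    )
    rng_nuc = np.random.default_rng(s_nuc)
    rows_, cols_, types_ = [], [], []
    for r in range(scn.n_rows):
        for c in range(scn.n_cols):
            zi = zmap[r, c]
            if zi < 0:
                continue
            z = scn.zones[zi]
            if z.nuclei_mixture is None or z.nuclei_per_patch < 1:
                continue
            n = z.nuclei_per_patch
            tidx = _allocate_types(n, z.nuclei_mixture, cell_types, scn.deterministic, rng_nuc)
            if scn.deterministic:
                side = int(np.ceil(np.sqrt(n)))
                step = scn.patch_px / side
                k = np.arange(n)
                pr = (k // side + 0.5) * step
                pc = (k % side + 0.5) * step
            else:
                pr = rng_nuc.random(n) * scn.patch_px
                pc = rng_nuc.random(n) * scn.patch_px
            rows_.append(r * scn.patch_px + pr.astype(int))
            cols_.append(c * scn.patch_px + pc.astype(int))
            types_.append(tidx)
    if types_:
        nuc_rows = np.concatenate(rows_)
        nuc_cols = np.concatenate(cols_)
        nuc_types = np.concatenate(types_)
    else:
        nuc_rows = nuc_cols = np.zeros(0, dtype=int)
        nuc_types = np.zeros(0, dtype=int)
    nuc_emb = nucleus_backend.embed_classes(nuc_types, rng_nuc) if len(nuc_types) \
        else np.zeros((0, scn.embedding_dim_nucleus))
    nuclei = NucleiTable(
        nucleus_id=np.arange(len(nuc_types)),
        centroid_row=nuc_rows,
        centroid_col=nuc_cols,
        embedding=nuc_emb,
        detection_prob=np.ones(len(nuc_types)),
    )
    nuclei_truth = np.array([cell_types[t] for t in nuc_types], dtype=object)

    # ---- spots -------------------------------------------------------------
    rng_spot = np.random.default_rng(s_spot)
    s = scn.spots_per_patch_side
    step = scn.patch_px / s
    sp_rows, sp_cols, sp_types, sp_patch = [], [], [], []
    for r in range(scn.n_rows):
        for c in range(scn.n_cols):
            zi = zmap[r, c]
            if zi < 0 or scn.zones[zi].spot_mixture is None:
                continue
            z = scn.zones[zi]
            tidx = _allocate_types(s * s, z.spot_mixture, cell_types, scn.deterministic, rng_spot)
            k = np.arange(s * s)
            sp_rows.append((r * scn.patch_px + (k // s + 0.5) * step).astype(int))
            sp_cols.append((c * scn.patch_px + (k % s + 0.5) * step).astype(int))
            sp_types.append(tidx)
            sp_patch.append(np.tile([r, c], (s * s, 1)))
    if sp_types:
        spot_rows = np.concatenate(sp_rows)
        spot_cols = np.concatenate(sp_cols)
        spot_types = np.concatenate(sp_types)
        spot_patch_rc = np.concatenate(sp_patch)
    else:
        raise ValueError("scenario has no tissue zone with spots")
    n_spots = len(spot_types)
    spot_ids = np.array([f"spot_{i:06d}" for i in range(n_spots)], dtype=object)
    spots = SpotTable(
        pd.DataFrame(
            {
                "spot_id": spot_ids,
                "in_tissue": np.ones(n_spots, dtype=np.int8),
                "pxl_row_in_fullres": spot_rows,
                "pxl_col_in_fullres": spot_cols,
            }
        )
    )
    spot_truth = np.array([cell_types[t] for t in spot_types], dtype=object)

    # ---- counts ------------------------------------------------------------
    marker_map = {
        t: _DEFAULT_MARKERS.get(t, [f"{t.upper()}M1", f"{t.upper()}M2"])
        for t in cell_types
    }
    markers = MarkerSet(marker_map)
    marker_genes = [g for t in cell_types for g in marker_map[t]]
    # carry the remaining canonical markers at baseline so packaged marker
    # sets can always be scored against synthetic matrices
    extra_genes = [
        g for t, gl in _DEFAULT_MARKERS.items() if t not in cell_types for g in gl
    ]
    genes = marker_genes + extra_genes + [f"FILLER{i:03d}" for i in range(scn.filler_genes)]
    means = np.full((n_spots, len(genes)), scn.marker_baseline)
    means[:, len(marker_genes) + len(extra_genes):] = scn.filler_mean
    col0 = 0
    for t, name in enumerate(cell_types):
        ncols = len(marker_map[name])
        means[spot_types == t, col0 : col0 + ncols] = scn.marker_effect
        col0 += ncols
    rng_count = np.random.default_rng(s_count)
    if scn.deterministic:
        counts_arr = np.rint(means).astype(np.int64)
    else:
        disp = scn.nb_dispersion
        counts_arr = rng_count.negative_binomial(disp, disp / (disp + means))
    counts = CountMatrix(counts_arr, spot_ids, genes)

    # ---- planted ground truth from true spot labels ------------------------
    planted_div = gt_diversity_ranking(spot_patch_rc, spot_truth, grid, cfg)
    planted_div.method = "planted_diversity"
    planted_tum = None
    if "tumor" in spot_truth:
        planted_tum = gt_tumor_ranking(spot_patch_rc, spot_truth, grid, cfg)
        planted_tum.method = "planted_tumor"

    sf = ScaleFactors(
        microns_per_pixel=scn.microns_per_pixel,
        spot_diameter_fullres=max(step / 2.0, 1.0),
    )
    return SyntheticSlide(
        scenario=scn,
        grid=grid,
        patch_embeddings=patch_emb,
        patch_backend=patch_backend,
        nuclei=nuclei,
        nuclei_truth=nuclei_truth,
        nucleus_backend=nucleus_backend,
        spots=spots,
        spot_truth=spot_truth,
        spot_patch_rc=spot_patch_rc,
        counts=counts,
        markers=markers,
        scalefactors=sf,
        planted_diversity=planted_div,
        planted_tumor=planted_tum,
        render_patch=render,
    )


# ---------------------------------------------------------------------------
# nucleus-only scenario for the annotation loop


def make_nuclei_scenario(
    n_per_class: int = 600,
    cell_types=("tumor", "immune", "stromal"),
    dim: int = 64,
    sigma: float = 0.3,
    modality_gap_deg: float = 30.0,
    seed: int = 0,
):
    """Planted nucleus embeddings for annotation experiments.

    Classes occupy contiguous horizontal bands (so region-sweep annotators are
    meaningful); embeddings are class prototypes plus isotropic noise with an
    image-text modality gap that makes zero-shot labeling imperfect.

    Returns ``(nuclei, truth, backend, label_set)``.
    """
    from .nuclei_annotation import LabelSet

    cell_types = list(cell_types)
    backend = SyntheticBackend(
        n_classes=len(cell_types), dim=dim, sigma=sigma, seed=seed,
        class_names=cell_types, modality_gap_deg=modality_gap_deg,
    )
    rng = np.random.default_rng(seed + 1)
    n = n_per_class * len(cell_types)
    types = np.repeat(np.arange(len(cell_types)), n_per_class)
    emb = backend.embed_classes(types, rng)
    band_h = 1000
    rows = np.concatenate(
        [k * band_h + rng.integers(0, band_h, n_per_class) for k in range(len(cell_types))]
    )
    cols = rng.integers(0, 3000, n)
    nuclei = NucleiTable(
        nucleus_id=np.arange(n),
        centroid_row=rows,
        centroid_col=cols,
        embedding=emb,
        detection_prob=np.ones(n),
    )
    truth = np.array([cell_types[t] for t in types], dtype=object)
    return nuclei, truth, backend, LabelSet(cell_types)


# ---------------------------------------------------------------------------
# presets


def margin_preset(n: int = 36, deterministic: bool = True, sigma: float = 0.0,
                  seed: int = 0, render_images: bool = False) -> SyntheticScenario:
    """Tumor / invasive-margin / stroma slide.

    The margin band is window-width (8 patches) and mixes tumor, immune and
    stromal cells at 1/2:1/4:1/4, with a two-class visual checkerboard — the
    mixed morphology of an invasive edge. Spot and nucleus mixtures coincide,
    so the planted diversity signal peaks in and around the margin.
    """
    m0 = (n - 8) // 2
    zones = (
        Zone("tumor", 0, n, 0, m0, visual_classes=(0,),
             nuclei_mixture={"tumor": 1.0}, spot_mixture={"tumor": 1.0}),
        Zone("tumor_margin", 0, n, m0, m0 + 8, visual_classes=(1, 3),
             nuclei_mixture={"tumor": 0.5, "immune": 0.25, "stromal": 0.25},
             spot_mixture={"tumor": 0.5, "immune": 0.25, "stromal": 0.25}),
        Zone("stroma", 0, n, m0 + 8, n, visual_classes=(2,),
             nuclei_mixture={"stromal": 1.0}, spot_mixture={"stromal": 1.0}),
    )
    return SyntheticScenario(
        n_rows=n, n_cols=n, zones=zones, cell_types=("tumor", "immune", "stromal"),
        sigma_patch=sigma, sigma_nucleus=sigma, deterministic=deterministic,
        seed=seed, render_images=render_images,
    )


def complementary_preset(n: int = 36, seed: int = 0) -> SyntheticScenario:
    """Visual and cellular signals informative about different zones.

    Zone A is morphologically mixed (visual checkerboard) but its nuclei are a
    single type; zone B is morphologically uniform but cellularly mixed. The
    expression ground truth carries diversity in both, so neither pure score
    arm sees the whole picture while the blend does.
    """
    third = n // 3
    zones = (
        Zone("zoneA_visual", 0, n, 0, third, visual_classes=(0, 1),
             nuclei_mixture={"tumor": 1.0},
             spot_mixture={"tumor": 0.5, "immune": 0.5}),
        Zone("neutral", 0, n, third, 2 * third, visual_classes=(2,),
             nuclei_mixture={"stromal": 1.0}, spot_mixture={"stromal": 1.0}),
        Zone("zoneB_cellular", 0, n, 2 * third, n, visual_classes=(3,),
             nuclei_mixture={"tumor": 0.5, "immune": 0.5},
             spot_mixture={"tumor": 0.5, "immune": 0.5}),
    )
    return SyntheticScenario(
        n_rows=n, n_cols=n, zones=zones, cell_types=("tumor", "immune", "stromal"),
        sigma_patch=0.1, sigma_nucleus=0.1, deterministic=False, seed=seed,
    )


def prostate_like_preset(n: int = 36, seed: int = 0) -> SyntheticScenario:
    """Dense glandular tissue: a tumor block inside epithelium-rich stroma."""
    h = n // 2
    zones = (
        Zone("gland_field", 0, n, 0, n, visual_classes=(2,), nuclei_per_patch=35,
             nuclei_mixture={"tumor": 0.1, "stromal": 0.6, "immune": 0.3},
             spot_mixture={"tumor": 0.1, "stromal": 0.6, "immune": 0.3}),
        Zone("tumor_focus", n // 4, n // 4 + h, n // 4, n // 4 + h,
             visual_classes=(0,), nuclei_per_patch=45,
             nuclei_mixture={"tumor": 0.8, "stromal": 0.1, "immune": 0.1},
             spot_mixture={"tumor": 0.8, "stromal": 0.1, "immune": 0.1}),
    )
    return SyntheticScenario(
        n_rows=n, n_cols=n, zones=zones, cell_types=("tumor", "immune", "stromal"),
        sigma_patch=0.1, sigma_nucleus=0.1, deterministic=False, seed=seed,
    )


def lung_like_preset(n: int = 36, seed: int = 0) -> SyntheticScenario:
    """Sparse cellularity: low densities push many windows under the 10-cell floor."""
    zones = (
        Zone("alveolar", 0, n, 0, n // 2, visual_classes=(1,), nuclei_per_patch=0,
             nuclei_mixture={"stromal": 1.0}, spot_mixture={"stromal": 1.0}),
        Zone("lesion", 0, n, n // 2, n, visual_classes=(0,), nuclei_per_patch=6,
             nuclei_mixture={"tumor": 0.6, "immune": 0.4},
             spot_mixture={"tumor": 0.6, "immune": 0.4}),
    )
    return SyntheticScenario(
        n_rows=n, n_cols=n, zones=zones, cell_types=("tumor", "immune", "stromal"),
        sigma_patch=0.1, sigma_nucleus=0.1, deterministic=False, seed=seed,
    )


def background_only_preset(n: int = 10, seed: int = 0) -> SyntheticScenario:
    """All-background slide (a single tissue spot zone keeps the spot table non-empty)."""
    zones = (
        Zone("background", 0, n, 0, n),
        Zone("speck", 0, 1, 0, 1, nuclei_per_patch=0,
             nuclei_mixture={"stromal": 1.0}, spot_mixture={"stromal": 1.0}),
    )
    return SyntheticScenario(
        n_rows=n, n_cols=n, zones=zones, cell_types=("tumor", "immune", "stromal"),
        seed=seed, render_images=True,
    )


# ---------------------------------------------------------------------------
# recovery experiments


def recovery_experiment(
    scn: SyntheticScenario,
    cfg: ScoreConfig = ScoreConfig(),
    n_seeds: int = 1,
    mode: str = "diversity",
    label_source: str = "true",
    overlap_frac: float = 0.10,
) -> pd.DataFrame:
    """Run the full pipeline against planted truth over seeds.

    ``label_source``: 'true' uses planted nucleus labels, 'zero_shot' uses
    argmax-cosine labels, 'random' ranks windows by uniform noise (chance
    control). Returns one row per seed with rho and Overlap@``overlap_frac``.
    """
    from .evaluation import overlap_at_k, spearman_common
    from .nuclei_annotation import LabelSet, zero_shot_label

    if scn.n_rows < 30 or scn.n_cols < 30:
        raise ValueError("recovery experiments need at least a 30x30 patch grid")
    rows = []
    for i in range(n_seeds):
        slide = make_slide(replace(scn, seed=scn.seed + i), cfg)
        gt = slide.planted_diversity if mode == "diversity" else slide.planted_tumor
        if gt is None:
            raise ValueError("scenario plants no tumor ranking")
        if label_source == "random":
            rng = np.random.default_rng(scn.seed + i)
            anchors = sliding_windows(slide.grid, cfg)
            from .roi_scoring import rank_windows

            ranking = rank_windows(anchors, rng.random(len(anchors)), method="random")
        else:
            if label_source == "true":
                labels = slide.nuclei_truth
            elif label_source == "zero_shot":
                labeled = zero_shot_label(
                    slide.nuclei, LabelSet(slide.scenario.cell_types),
                    slide.nucleus_backend,
                )
                labels = labeled.label
            else:
                raise ValueError(f"unknown label_source {label_source!r}")
            ranking = score_windows(
                slide.grid,
                cfg,
                mode=mode,
                embeddings=slide.patch_embeddings,
                nuclei_patch_rc=slide.nuclei_patch_rc,
                nuclei_labels=labels,
                text_vec=slide.patch_backend.embed_text(cfg.prompt),
                target_class="tumor" if mode == "targeted" else None,
            )
        k = max(1, int(round(overlap_frac * len(gt))))
        rows.append(
            {
                "seed": scn.seed + i,
                "rho": spearman_common(ranking, gt),
                "overlap_frac_pct": overlap_at_k(ranking, gt, k),
                "k": k,
                "n_windows": len(gt),
            }
        )
    return pd.DataFrame(rows)
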