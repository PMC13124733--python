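# Methods

This note records the model, its parameters and defaults, the numerical
choices made where the procedure was underdetermined, and what the synthetic
data does and does not establish.

## Pipeline overview

1. **Crop.** The tissue region is the minimum bounding rectangle of all
   in-tissue spots (fullres pixel coordinates from the positions table),
   padded on every side by the spot diameter from the scale-factor metadata
   and clamped at zero after padding. All pixel coordinates in the package
   are 0-based, row-major, with half-open intervals.
2. **Tile.** The crop is divided into a non-overlapping 224 × 224-px patch
   lattice, `ceil` division with white padding on the bottom/right edges.
   Padding pixels participate in patch statistics, so edge patches tend to be
   background-filtered — intended behavior.
3. **Filter.** Short-circuit cascade: a pre-embedding filter drops patches
   that are exactly all-255 or all-0; tier 1 drops bright uniform background
   (mean grayscale ≥ 235 **and** population std < 20, optionally also
   requiring ≥ 85% of pixels with all RGB channels ≥ 230); tier 2 drops
   residual low-variance patches (std < 10). Grayscale is ITU-R 601 luma,
   rounded (`round(0.299 R + 0.587 G + 0.114 B)`); the std is the population
   std over the grayscale patch. The cascade order means no patch carries two
   flags. The color check defaults to **off** and is exposed as a flag.
4. **Embed.** Retained patches go through a pluggable backend (contract:
   deterministic `embed_images`/`embed_text` with a declared dimension —
   frozen-extractor semantics). Real pathology VLM encoders are plug-ins the
   core never imports; all tests run on the synthetic backend.
5. **Score windows.** 8 × 8-patch sliding windows (stride configurable,
   default 1) receive the diversity and/or targeted scores described in the
   README. Components are min-max normalized globally across all windows of a
   run before blending.
6. **Select.** Greedy descending-score scan; a candidate is accepted iff for
   every already-accepted window |Δrow| ≥ 8 **or** |Δcol| ≥ 8 (mode
   `any_axis`, the default — this is exactly the zero-spatial-overlap
   condition for axis-aligned equal windows). The stricter AND-rule
   (`both_axes`), a literal center-separation-in-both-dimensions reading, is
   retained behind a flag; it also forbids diagonal-neighbor windows that do
   not overlap, so it selects sparser layouts.

## Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| patch size | 224 | px | standard vision-encoder tile; ~61 µm at 0.274 µm/px |
| window | 8 × 8 | patches | ~491 µm ≈ the ~500 µm field of view of targeted ST platforms; ~0.6% of a 6.5 mm capture square |
| stride | 1 | patches | maximal coverage; rankings are stable vs stride 2 (tested) |
| blend weight w | 0.5 | — | robust default; sweeps show an inverted-U with the peak tissue-dependent |
| UMAP dims / neighbors / min_dist / seed | 30 / 15 / 0.1 / 42 | — | global fit on all retained patches; fixed seed for reproducibility |
| similarity quantile | 0.9 | — | emphasizes strong matches, robust to outliers |
| similarity exponent | 10.0 | — | contrast sharpening of the aggregated similarity |
| min cells (or spots) per window | 10 | count | entropy below this is noise; score set to 0 |
| CP10K target | 10,000 | counts | library-size normalization before log1p |
| spot-score floor | 1.0 | log-normalized units | below it a spot is "Unclassified" |
| XGBoost | 100 trees, depth 6, lr 0.3, softprob | — | stock gradient-boosting defaults, no tuning |
| bootstrap | 1,000 resamples, 2.5/97.5 percentiles | — | CI over the evaluated windows |

## Numerical and tie-break choices

- **Entropy and density weight.** Entropy is base 2; the density weight
  `log(1 + N)` uses the natural log (only the entropy base is dictated by the
  formula; ln is kept for the weight and for `log(1 + count)`).
- **Quantile.** Linear interpolation between order statistics.
- **Negative similarities** are clipped to 0 before the exponent, avoiding
  sign artifacts under even powers.
- **Order of operations (VLM arm):** quantile → clip → exponent → global
  min-max, then blending.
- **Degenerate windows.** Fewer than 2 retained patches → visual score 0;
  fully filtered windows score 0 on both arms. Min-max of a constant score
  field maps everything to 0.
- **Ties.** Argmax ties (cosine, class probability, spot-type scores) resolve
  to the lowest index / first listed class. Ranking ties resolve by ascending
  (anchor_row, anchor_col). Spearman ranks use average ranks for tied scores.
- **Overlap@10%** uses K = round(0.10 · N) over the window set common to both
  rankings (configurable).
- **Nucleus→window assignment** is by centroid containment in the window's
  pixel footprint; spot→patch assignment by floor division of crop-relative
  pixels.
- **Unclassified spots** are excluded from both the entropy proportions and N
  in the ground-truth diversity score (they mark classification failure, not
  a biological type); a flag can include them as a category. The same
  exclusion mechanism lets "negative control" nuclei be dropped from the
  model-side entropy.
- **Zero-shot labels never enter the training set**; the classifier trains on
  annotations only, and later annotations of the same nucleus override
  earlier ones.
- **Uncertainty queries** (lowest max-probability first) break ties randomly,
  so flat confidence fields are sampled across the tissue rather than in
  storage order.
- **UMAP pass-through.** If the input dimension is already ≤ 30 the reduction
  is the identity; the synthetic patch backend uses 32 dimensions so the UMAP
  path is exercised.

## The synthetic data

`synthetic_data` plants known structure so every stage is measurable:

- **Zones** are rectangles of the patch grid carrying a visual appearance
  (one prototype, or two alternating in a checkerboard for mixed morphology —
  used for the invasive margin, whose glands/stroma/immune interleaving is
  visually heterogeneous at patch scale), a nucleus type mixture with a
  density, and a spot type mixture. Patches outside any tissue zone are
  background (near-white when rendered, tier-1 flagged).
- **Embeddings** come from a seeded orthonormal-prototype backend with
  configurable Gaussian noise. Nucleus backends support an **image–text
  modality gap**: class image centroids are rotated by a configurable angle
  toward the next class prototype while text embeddings stay on the
  prototypes. This reproduces the well-documented misalignment between image
  and text embeddings in CLIP-style joint spaces and is what makes zero-shot
  labeling imperfect (so annotation has something to improve). The gap
  defaults to 0; the annotation scenario uses 30°, giving ~0.8 zero-shot
  accuracy at noise σ = 0.3.
- **Counts** are per-gene means (marker genes up-shifted in spots of the
  matching type, canonical marker symbols reused so the packaged marker sets
  apply) drawn negative-binomially in stochastic mode, or deterministically
  rounded in noiseless mode. Default means: filler genes 5, matching markers
  8, non-matching markers 0.02 — chosen so matching marker scores sit far
  above the 1.0 floor and non-matching ones below it, as real canonical
  markers do.
- **Planted rankings** are computed from the *true* spot labels with the same
  window formulas the expression benchmark uses, so "recovery" means the
  image pipeline reproduces a ranking it never saw.
- **Deterministic mode** uses largest-remainder type allocation and exact
  per-patch densities; with mixtures on a 4-spots-per-patch lattice chosen as
  multiples of 1/4, window-level nucleus and spot proportions coincide
  exactly, which is why the noiseless tumor ranking is recovered with ρ = 1.

What the synthetic slides do **not** emulate: real H&E texture, nucleus
morphology and segmentation error, spatial autocorrelation of expression
beyond zone structure, inter-annotator disagreement, and the actual geometry
of Visium HD barcoding. Passing tests therefore demonstrate correctness of
the scoring/evaluation machinery and the qualitative behaviors (chance
levels, synergy of the two arms, annotation gains), not performance on real
slides, which additionally depends on the plugged-in encoders.

### Problem sizes used in the test suite

Recovery experiments run on 30–36-patch grids (529–841 windows, ~3,600–5,200
spots, ~18,000–26,000 nuclei); the chance-level reference uses the full
105 × 105 grid (9,604 windows) since it needs no embeddings. These sizes make
every planted signal detectable with wide margins while keeping the suite
fast.

## Known limitations

- The greedy selector is O(k·n) over candidates and exact only for
  axis-aligned equal-size windows.
- UMAP with a fixed seed is single-threaded; on very large patch sets the
  global reduction dominates runtime.
- The synthetic backend's hash-based `embed_images` gives determinism and
  class spread but no semantic relation between pixel content and class;
  semantic behavior enters only through `embed_classes` with planted labels.
- Marker-set spot classification is a hard argmax; mixed spots near zone
  boundaries are assigned a single type, which slightly flattens the
  ground-truth entropy at interfaces.
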