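# spatialfinder

Spatial transcriptomics assays profile gene expression across an intact tissue
section, but sequencing a whole slide can cost thousands of dollars, and much
of a slide is morphologically repetitive. A practical alternative is to
sequence only a handful of small regions of interest (ROIs) chosen from the
routine H&E image — if those regions can be chosen well. `spatialfinder`
ranks candidate ROIs on H&E patch grids by combining frozen vision-language
embeddings with a human-in-the-loop nucleus classifier, and validates the
rankings against benchmarks built from spot-level expression data.

The package is aimed at computational pathology and spatial-omics groups who
want to (i) prioritize ~500 × 500 µm windows for targeted sequencing from
imagery alone, and (ii) quantify how well any such prioritization recovers
what the transcriptome would have said.

## The scores

The slide is cropped to its tissue bounding box, tiled into 224 × 224-px
patches (white/black and low-variance background patches are filtered in a
two-tier cascade), and scanned with an 8 × 8-patch sliding window (stride 1,
roughly 10,000 overlapping windows on a typical capture area). Each window
gets one of two scores, both blends of a visual and a cellular arm that are
min-max normalized over all windows:

**Regional diversity** — for unsupervised discovery of heterogeneous tissue:

    S_diversity = w · Score_visual + (1 − w) · Score_cellular

where `Score_visual` is the median pairwise Euclidean distance between the
window's patch embeddings after a global 30-dimensional UMAP reduction
(n_neighbors = 15, min_dist = 0.1, fixed seed), and `Score_cellular` is the
base-2 Shannon entropy H = −Σᵢ pᵢ log₂ pᵢ of the window's nucleus cell-type
proportions, weighted by cell density as H · ln(1 + N); windows with fewer
than 10 cells score zero.

**Targeted conditional** — for hypothesis-driven searches ("find tumor"):

    S_targeted = w · Score_VLM + (1 − w) · Score_count

where `Score_VLM` is the 0.9-quantile of patch-to-prompt cosine similarity,
clipped at zero and raised to an exponent (default 10) to sharpen contrast,
and `Score_count` = ln(1 + #target-class nuclei) in the window.

Nucleus cell types start from zero-shot text matching (argmax cosine between
each nucleus embedding and class-name text embeddings) and are refined by an
active-learning loop: per cycle, an annotator labels a small batch, an XGBoost
classifier (100 estimators, depth 6, learning rate 0.3, softprob) is retrained
on the cumulative annotations, and all nuclei are relabeled.

Top regions are chosen greedily in descending score order, accepting a window
only if it does not overlap anything already accepted. Rankings are compared
with Spearman's ρ over the common windows (with 95% bootstrap CIs from
resampling the evaluated windows), Overlap@K (percent of shared top-K
anchors) and Set IoU@K (intersection-over-union of the top-K patch
footprints).

Real VLM encoders plug in behind a small backend contract
(`embed_images` / `embed_text` / `dim`); the built-in synthetic backend embeds
planted classes as rows of a seeded orthonormal basis so the entire pipeline
runs offline, including an optional image–text modality gap that makes
zero-shot labeling realistically imperfect.

## Worked example

`examples/03_ground_truth_evaluation.py` simulates a tumor / invasive-margin /
stroma slide (30 × 30 patches, 3,600 expression spots, 18,000 nuclei with
noisy embeddings), builds the expression-side benchmark by classifying every
spot from marker genes and ranking windows by spot-type entropy, scores the
same windows from the image side, and compares:

```
spot classification agrees with planted truth: 99.9%
Spearman rho = 0.955 [0.945, 0.963] over 529 windows
  Overlap@10 = 0.0%   Set IoU@10 = 0.241
  Overlap@50 = 42.0%   Set IoU@50 = 0.794
  Overlap@53 = 47.2%   Set IoU@53 = 0.800
```

ρ = 0.955 says the image-only ranking orders the 529 windows almost exactly
as the expression benchmark does. At the very top of the list exact anchor
matches are rare (adjacent windows trade places) while the spatial footprints
still coincide — that is why Set IoU@10 is well above zero even when
Overlap@10 is 0%.

`examples/04_active_learning.py` shows the annotation loop lifting accuracy
from the 0.798 zero-shot baseline to 0.896 with 300 simulated annotations,
and `examples/05_weight_sweep.py` shows the inverted-U over the blend weight
(pure arms 0.69 / 0.67, blended peak 0.91) on a scenario where visual and
cellular signals mark different regions.

A thin CLI wraps the same functions:

```
spatialfinder simulate --preset margin --size 30 --seed 7 --out bundle/
spatialfinder validate bundle/
spatialfinder score bundle/ --mode diversity --top-k 5 --out model.csv
spatialfinder ground-truth bundle/ --mode diversity --out gt.csv
spatialfinder evaluate model.csv gt.csv --k 10 50
```

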