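"""Window generation, the two score formulas, and greedy ROI selection."""

import math

import numpy as np
import pytest

from spatialfinder.embedding_backend import EmbeddingMatrix
from spatialfinder.patch_grid import PatchGrid
from spatialfinder.roi_scoring import (
    ScoreConfig,
    cell_abundance_score,
    cell_abundance_scores,
    cellular_entropy,
    cellular_entropy_scores,
    diversity_score,
    greedy_nonoverlap_select,
    minmax_normalize,
    rank_windows,
    reduce_embeddings,
    sliding_windows,
    targeted_score,
    text_similarity_score,
    visual_diversity,
    visual_diversity_scores,
    weight_sweep,
    window_geometry,
)


def grid(n, m=None):
    return PatchGrid(n_rows=n, n_cols=m or n)


class TestSlidingWindows:
    @pytest.mark.parametrize(
        "n, stride, expected",
        [(10, 1, 9), (8, 1, 1), (105, 1, 9604), (12, 2, 9)],
    )
    def test_window_counts(self, n, stride, expected):
        anchors = sliding_windows(grid(n), ScoreConfig(stride=stride))
        assert len(anchors) == expected

    def test_single_window_at_origin(self):
        anchors = sliding_windows(grid(8))
        np.testing.assert_array_equal(anchors, [[0, 0]])

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            sliding_windows(grid(7))


class TestVisualDiversity:
    def test_identical_vectors_score_zero(self):
        assert visual_diversity(np.ones((10, 3))) == 0.0

    def test_hand_median(self):
        # distances {5, 10, 5} -> median 5
        pts = np.array([[0.0, 0.0], [3.0, 4.0], [6.0, 8.0]])
        assert visual_diversity(pts) == pytest.approx(5.0)

    def test_degenerate_window_scores_zero(self):
        assert visual_diversity(np.ones((1, 3))) == 0.0
        assert visual_diversity(np.zeros((0, 3))) == 0.0

    def test_matches_brute_force_all_pairs(self, rng):
        """Exact agreement with an O(n^2) loop oracle on random windows."""
        g = grid(12)
        ids = [(r, c) for r in range(12) for c in range(12) if rng.random() < 0.8]
        reduced = EmbeddingMatrix(ids=ids, vectors=rng.normal(size=(len(ids), 5)))
        anchors = sliding_windows(g)
        scores = visual_diversity_scores(anchors, reduced, g)
        pos = {idc: i for i, idc in enumerate(ids)}
        for (ar, ac), score in zip(anchors, scores):
            members = [
                pos[(r, c)]
                for r in range(ar, ar + 8)
                for c in range(ac, ac + 8)
                if (r, c) in pos
            ]
            dists = [
                np.linalg.norm(reduced.vectors[i] - reduced.vectors[j])
                for i in members
                for j in members
                if i < j
            ]
            expected = float(np.median(dists)) if dists else 0.0
            assert score == pytest.approx(expected, abs=1e-12)


class TestCellularEntropy:
    def test_single_type_scores_zero(self):
        assert cellular_entropy([16]) == 0.0

    def test_below_min_cells_scores_zero(self):
        assert cellular_entropy([3, 3, 3]) == 0.0

    def test_two_even_types(self):
        # H = 1 bit, density weight ln(17)
        assert cellular_entropy([8, 8]) == pytest.approx(math.log(17), abs=1e-12)

    def test_entropy_bounded_by_log_types(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 40, size=rng.integers(1, 6))
            n = counts.sum()
            score = cellular_entropy(counts)
            if n >= 10:
                assert 0.0 <= score <= math.log2(len(counts)) * math.log1p(n) + 1e-12

    def test_window_aggregation_and_exclusion(self):
        g = grid(8)
        rc = np.array([[0, 0]] * 8 + [[7, 7]] * 8 + [[3, 3]] * 4)
        labels = np.array(["a"] * 8 + ["b"] * 8 + ["negative control"] * 4, dtype=object)
        anchors = sliding_windows(g)
        full = cellular_entropy_scores(anchors, rc, labels, g)
        assert full[0] == pytest.approx(
            cellular_entropy([8, 8, 4]), abs=1e-12
        )
        excl = cellular_entropy_scores(
            anchors, rc, labels, g, ScoreConfig(entropy_exclude=("negative control",))
        )
        assert excl[0] == pytest.approx(math.log(17), abs=1e-12)


class TestNormalizeAndBlend:
    def test_minmax_examples(self):
        np.testing.assert_allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])
        np.testing.assert_allclose(minmax_normalize([0, 10]), [0, 1])

    def test_minmax_constant_input_all_zero(self):
        np.testing.assert_array_equal(minmax_normalize([3.3, 3.3, 3.3]), [0, 0, 0])

    def test_diversity_blend(self):
        assert diversity_score([0.4], [0.8], w=0.5)[0] == pytest.approx(0.6)
        np.testing.assert_allclose(diversity_score([0.4], [0.8], w=1.0), [0.4])
        np.testing.assert_allclose(diversity_score([0.4], [0.8], w=0.0), [0.8])

    def test_targeted_blend(self):
        assert targeted_score([1.0], [0.0], w=0.5)[0] == pytest.approx(0.5)

    def test_weight_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diversity_score([0.1], [0.2], w=1.5)

    def test_blend_monotone_in_components(self, rng):
        a, b = rng.random(20), rng.random(20)
        base = diversity_score(a, b, w=0.3)
        bumped = diversity_score(a + 0.1, b, w=0.3)
        assert (bumped >= base).all()


class TestTextSimilarity:
    def test_perfect_similarity(self):
        assert text_similarity_score(np.ones(10)) == pytest.approx(1.0)

    def test_exponent_sharpening(self):
        assert text_similarity_score(np.full(10, 0.5)) == pytest.approx(0.5**10)

    def test_negative_similarities_clip_to_zero(self):
        assert text_similarity_score(np.full(10, -0.4)) == 0.0

    def test_empty_window_scores_zero(self):
        assert text_similarity_score(np.array([])) == 0.0


class TestCellAbundance:
    def test_log_count(self):
        assert cell_abundance_score(0) == 0.0
        assert cell_abundance_score(99) == pytest.approx(math.log(100))

    def test_monotone_in_count(self):
        scores = [cell_abundance_score(k) for k in range(50)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_missing_target_class_rejected(self):
        g = grid(8)
        rc = np.array([[0, 0]])
        with pytest.raises(ValueError, match="target class"):
            cell_abundance_scores(
                sliding_windows(g), rc, np.array(["immune"], dtype=object), "tumor", g
            )


class TestGreedySelection:
    def _ranking(self, anchors, scores):
        return rank_windows(np.asarray(anchors), np.asarray(scores, dtype=float))

    def test_abutting_windows_both_selected(self):
        ranking = self._ranking([(0, 0), (0, 8)], [1.0, 0.9])
        sel = greedy_nonoverlap_select(ranking, k=2)
        assert len(sel) == 2

    def test_overlapping_window_rejected(self):
        ranking = self._ranking([(0, 0), (0, 4)], [1.0, 0.9])
        sel = greedy_nonoverlap_select(ranking, k=2)
        assert len(sel) == 1 and tuple(sel.anchors[0]) == (0, 0)

    def test_k_one_returns_top_window(self):
        ranking = self._ranking([(0, 0), (9, 9), (20, 20)], [0.2, 0.9, 0.5])
        sel = greedy_nonoverlap_select(ranking, k=1)
        assert tuple(sel.anchors[0]) == (9, 9)

    def test_both_axes_mode_is_stricter(self):
        ranking = self._ranking([(0, 0), (0, 8)], [1.0, 0.9])
        sel = greedy_nonoverlap_select(ranking, k=2, mode="both_axes")
        assert len(sel) == 1

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            greedy_nonoverlap_select(self._ranking([(0, 0)], [1.0]), k=0)

    def test_any_axis_selection_never_overlaps(self, rng):
        """Rasterized footprints of selected windows are pairwise disjoint."""
        from spatialfinder.evaluation import rasterize_windows

        g = grid(20)
        anchors = sliding_windows(g)
        for _ in range(40):
            ranking = rank_windows(anchors, rng.random(len(anchors)))
            sel = greedy_nonoverlap_select(ranking, k=8)
            total = 0
            cells = set()
            for a in sel.anchors:
                footprint = rasterize_windows([tuple(a)])
                total += len(footprint)
                cells |= footprint
            assert len(cells) == total


class TestWeightSweep:
    def test_pure_baselines_at_grid_ends(self, rng):
        anchors = sliding_windows(grid(10))
        a, b = rng.random(9), rng.random(9)
        sweeps = weight_sweep(anchors, a, b, [0.0, 1.0])
        np.testing.assert_allclose(
            sorted(sweeps[1.0].scores), sorted(minmax_normalize(a))
        )
        np.testing.assert_allclose(
            sorted(sweeps[0.0].scores), sorted(minmax_normalize(b))
        )

    def test_six_point_grid_yields_six_rankings(self, rng):
        anchors = sliding_windows(grid(10))
        sweeps = weight_sweep(
            anchors, rng.random(9), rng.random(9), [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
        )
        assert len(sweeps) == 6

    def test_repeated_calls_identical(self, rng):
        anchors = sliding_windows(grid(10))
        a, b = rng.random(9), rng.random(9)
        r1 = weight_sweep(anchors, a, b, [0.4])[0.4]
        r2 = weight_sweep(anchors, a, b, [0.4])[0.4]
        np.testing.assert_array_equal(r1.anchors, r2.anchors)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            weight_sweep(sliding_windows(grid(10)), rng.random(9), rng.random(9), [])


class TestReduceEmbeddings:
    def test_passthrough_when_already_low_dimensional(self, rng):
        emb = EmbeddingMatrix(ids=list(range(20)), vectors=rng.normal(size=(20, 12)))
        reduced = reduce_embeddings(emb)
        np.testing.assert_array_equal(reduced.vectors, emb.vectors)

    def test_too_few_patches_rejected(self, rng):
        emb = EmbeddingMatrix(ids=list(range(5)), vectors=rng.normal(size=(5, 40)))
        with pytest.raises(ValueError, match="n_neighbors"):
            reduce_embeddings(emb)

    def test_seeded_reduction_reproducible_and_cluster_preserving(self, rng):
        centers = np.zeros((2, 40))
        centers[1, :5] = 8.0
        labels = np.repeat([0, 1], 40)
        x = centers[labels] + rng.normal(scale=0.3, size=(80, 40))
        emb = EmbeddingMatrix(ids=list(range(80)), vectors=x)
        r1 = reduce_embeddings(emb)
        r2 = reduce_embeddings(emb)
        assert r1.vectors.shape == (80, 30)
        np.testing.assert_array_equal(r1.vectors, r2.vectors)
        from scipy.spatial.distance import cdist

        d = cdist(r1.vectors, r1.vectors)
        within = np.concatenate([d[:40, :40].ravel(), d[40:, 40:].ravel()])
        between = d[:40, 40:].ravel()
        assert between.mean() > within.mean()


def test_window_geometry_physical_spans():
    geom = window_geometry(0.274)
    assert round(geom["patch_um"]) == 61
    assert round(geom["window_um"]) == 491
    assert round(geom["capture_area_percent"], 1) == 0.6
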