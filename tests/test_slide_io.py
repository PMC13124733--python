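"""Bundle I/O: crop-bound geometry and round-trip fidelity of every format."""

import json

import numpy as np
import pandas as pd
import pytest

from spatialfinder import slide_io
from spatialfinder.slide_io import (
    CountMatrix,
    CropBounds,
    ScaleFactors,
    SpotTable,
    compute_crop_bounds,
)


class TestCropBounds:
    def test_padding_by_spot_diameter(self, small_spots):
        # in-tissue spots at rows {100, 500}, cols {200, 800}, diameter 50
        sf = ScaleFactors(microns_per_pixel=0.3, spot_diameter_fullres=50)
        crop = compute_crop_bounds(small_spots, sf)
        assert (crop.row_min, crop.row_max) == (50, 551)
        assert (crop.col_min, crop.col_max) == (150, 851)

    def test_clamped_at_zero(self):
        spots = SpotTable(
            pd.DataFrame(
                {"spot_id": ["a"], "in_tissue": [1],
                 "pxl_row_in_fullres": [0], "pxl_col_in_fullres": [0]}
            )
        )
        crop = compute_crop_bounds(spots, ScaleFactors(1.0, 10.0))
        assert (crop.row_min, crop.row_max, crop.col_min, crop.col_max) == (0, 11, 0, 11)

    def test_no_in_tissue_spots_raises(self):
        spots = SpotTable(
            pd.DataFrame(
                {"spot_id": ["a"], "in_tissue": [0],
                 "pxl_row_in_fullres": [5], "pxl_col_in_fullres": [5]}
            )
        )
        with pytest.raises(ValueError, match="in-tissue"):
            compute_crop_bounds(spots, ScaleFactors(1.0, 10.0))

    def test_all_in_tissue_spots_strictly_inside(self, rng):
        for _ in range(20):
            n = rng.integers(1, 40)
            df = pd.DataFrame(
                {
                    "spot_id": [f"s{i}" for i in range(n)],
                    "in_tissue": rng.integers(0, 2, n),
                    "pxl_row_in_fullres": rng.integers(0, 5000, n),
                    "pxl_col_in_fullres": rng.integers(0, 5000, n),
                }
            )
            if not df["in_tissue"].any():
                df.loc[0, "in_tissue"] = 1
            spots = SpotTable(df)
            crop = compute_crop_bounds(spots, ScaleFactors(0.5, float(rng.integers(1, 100))))
            mask = spots.in_tissue
            assert crop.contains(spots.rows[mask], spots.cols[mask]).all()


class TestScaleFactors:
    def test_round_trip(self, tmp_path, scalefactors):
        path = tmp_path / "scalefactors_json.json"
        slide_io.write_scalefactors(scalefactors, path)
        back = slide_io.read_scalefactors(path)
        assert back == scalefactors

    def test_missing_field_named(self, tmp_path):
        path = tmp_path / "sf.json"
        path.write_text(json.dumps({"microns_per_pixel": 0.3}))
        with pytest.raises(ValueError, match="spot_diameter_fullres"):
            slide_io.read_scalefactors(path)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            ScaleFactors(0.0, 50.0)


class TestSpotPositions:
    def test_round_trip(self, tmp_path, small_spots):
        path = tmp_path / "tissue_positions.parquet"
        slide_io.write_spot_positions(small_spots, path)
        back = slide_io.read_spot_positions(path)
        pd.testing.assert_frame_equal(back.df, small_spots.df)

    def test_missing_column_named(self, tmp_path, small_spots):
        path = tmp_path / "p.parquet"
        small_spots.df.drop(columns=["pxl_row_in_fullres"]).to_parquet(path)
        with pytest.raises(ValueError, match="pxl_row_in_fullres"):
            slide_io.read_spot_positions(path)

    def test_barcode_column_accepted(self, tmp_path, small_spots):
        path = tmp_path / "p.parquet"
        small_spots.df.rename(columns={"spot_id": "barcode"}).to_parquet(path)
        back = slide_io.read_spot_positions(path)
        assert list(back.spot_id) == list(small_spots.spot_id)

    def test_duplicate_ids_rejected(self, small_spots):
        df = small_spots.df.copy()
        df["spot_id"] = "same"
        with pytest.raises(ValueError, match="unique"):
            SpotTable(df)


class TestCounts:
    def test_h5_round_trip(self, tmp_path, small_counts):
        path = tmp_path / "filtered_feature_bc_matrix.h5"
        slide_io.write_counts_10x_h5(small_counts, path)
        back = slide_io.read_counts(path)
        assert (back.matrix != small_counts.matrix).nnz == 0
        assert list(back.genes) == list(small_counts.genes)
        assert list(back.spot_ids) == list(small_counts.spot_ids)

    def test_h5_readable_by_scanpy(self, tmp_path, small_counts):
        """The written HDF5 must be a valid 10x matrix for third-party readers."""
        sc = pytest.importorskip("scanpy")
        path = tmp_path / "filtered_feature_bc_matrix.h5"
        slide_io.write_counts_10x_h5(small_counts, path)
        adata = sc.read_10x_h5(path)
        np.testing.assert_array_equal(
            np.asarray(adata.X.todense()), small_counts.matrix.toarray()
        )

    def test_mtx_round_trip(self, tmp_path, small_counts):
        outdir = tmp_path / "counts_mtx"
        slide_io.write_counts_mtx(small_counts, outdir)
        back = slide_io.read_counts(outdir)
        assert (back.matrix != small_counts.matrix).nnz == 0
        assert list(back.genes) == list(small_counts.genes)

    def test_zero_spots_rejected(self):
        with pytest.raises(ValueError, match="0 spots"):
            CountMatrix(np.zeros((0, 3)), [], ["A", "B", "C"])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            CountMatrix(np.zeros((2, 3)), ["a", "b", "c"], ["A", "B", "C"])

    def test_case_insensitive_gene_duplicates_rejected(self):
        with pytest.raises(ValueError, match="upper-casing"):
            CountMatrix(np.zeros((2, 2)), ["a", "b"], ["Epcam", "EPCAM"])

    def test_missing_group_named(self, tmp_path):
        import h5py

        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as fh:
            fh.create_dataset("other", data=[1])
        with pytest.raises(ValueError, match="matrix"):
            slide_io.read_counts(path)


class TestNuclei:
    def test_round_trip_identity(self, tmp_path, small_nuclei):
        path = tmp_path / "nuclei.h5"
        slide_io.write_nuclei(small_nuclei, path)
        back = slide_io.read_nuclei(path)
        np.testing.assert_array_equal(back.nucleus_id, small_nuclei.nucleus_id)
        np.testing.assert_array_equal(back.centroid_row, small_nuclei.centroid_row)
        np.testing.assert_array_equal(back.centroid_col, small_nuclei.centroid_col)
        np.testing.assert_array_equal(back.embedding, small_nuclei.embedding)
        np.testing.assert_array_equal(back.detection_prob, small_nuclei.detection_prob)
        assert list(back.label) == list(small_nuclei.label)

    def test_missing_embedding_named(self, tmp_path):
        import h5py

        path = tmp_path / "nuclei.h5"
        with h5py.File(path, "w") as fh:
            fh.create_group("SegmentationNode")
        with pytest.raises(ValueError, match="embedding"):
            slide_io.read_nuclei(path)

    def test_detection_prob_range_checked(self, rng):
        with pytest.raises(ValueError, match="detection_prob"):
            slide_io.NucleiTable(
                nucleus_id=[0], centroid_row=[1], centroid_col=[1],
                embedding=rng.normal(size=(1, 4)), detection_prob=[1.5],
            )


class TestRoiReport:
    def _ranking(self):
        from spatialfinder.evaluation import RegionRanking

        return RegionRanking(
            anchors=[(0, 0), (3, 9), (8, 1)],
            scores=[0.9, 0.5, 0.1],
            method="diversity",
            components={"score_visual": np.array([0.8, 0.3, 0.2])},
        )

    def test_rows_in_rank_order(self, tmp_path):
        path = tmp_path / "roi.csv"
        slide_io.write_roi_report(self._ranking(), path)
        df = pd.read_csv(path)
        assert list(df["rank"]) == [1, 2, 3]
        assert (df["score"].diff().dropna() <= 0).all()
        assert (tmp_path / "roi.manifest.json").exists()

    def test_round_trip_scores_exact(self, tmp_path):
        path = tmp_path / "roi.csv"
        ranking = self._ranking()
        slide_io.write_roi_report(ranking, path)
        back = slide_io.read_roi_report(path)
        np.testing.assert_array_equal(back.anchors, ranking.anchors)
        np.testing.assert_allclose(back.scores, ranking.scores, rtol=1e-9)
        np.testing.assert_allclose(
            back.components["score_visual"], ranking.components["score_visual"], rtol=1e-9
        )

    def test_empty_ranking_rejected(self, tmp_path):
        from spatialfinder.evaluation import RegionRanking

        empty = RegionRanking(anchors=np.zeros((0, 2)), scores=[])
        with pytest.raises(ValueError, match="empty"):
            slide_io.write_roi_report(empty, tmp_path / "roi.csv")


def test_validate_bundle_on_synthetic_slide(tmp_path):
    from spatialfinder.synthetic_data import make_slide, margin_preset

    slide = make_slide(margin_preset(n=30))
    slide.write_bundle(tmp_path / "bundle")
    summary = slide_io.validate_bundle(tmp_path / "bundle")
    assert summary["n_spots"] == len(slide.spots)
    assert summary["n_nuclei"] == len(slide.nuclei)
    assert summary["embedding_dim"] == slide.nuclei.dim
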