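import numpy as np
import pandas as pd
import pytest

from spatialfinder.slide_io import CountMatrix, NucleiTable, ScaleFactors, SpotTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spots():
    return SpotTable(
        pd.DataFrame(
            {
                "spot_id": ["a", "b", "c"],
                "in_tissue": [1, 1, 0],
                "pxl_row_in_fullres": [100, 500, 900],
                "pxl_col_in_fullres": [200, 800, 50],
            }
        )
    )


@pytest.fixture
def small_counts(rng):
    mat = rng.integers(0, 20, size=(6, 5))
    return CountMatrix(mat, [f"s{i}" for i in range(6)], ["EPCAM", "PTPRC", "COL1A1", "G1", "G2"])


@pytest.fixture
def small_nuclei(rng):
    n, d = 12, 8
    return NucleiTable(
        nucleus_id=np.arange(n),
        centroid_row=rng.integers(0, 448, n),
        centroid_col=rng.integers(0, 448, n),
        embedding=rng.normal(size=(n, d)),
        detection_prob=rng.random(n),
        label=np.array(["tumor", "immune"] * 6, dtype=object),
    )


@pytest.fixture
def scalefactors():
    return ScaleFactors(microns_per_pixel=0.274, spot_diameter_fullres=50.0)
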