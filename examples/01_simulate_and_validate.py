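"""Simulate a slide bundle and validate its on-disk artifacts.

Generates a tumor/margin/stroma slide, writes the standard bundle layout
(scale factors JSON, positions Parquet, 10x-style counts HDF5, nuclei HDF5,
planted-ranking CSVs) and re-reads everything through the validators.
"""

import tempfile
from pathlib import Path

from spatialfinder.slide_io import validate_bundle
from spatialfinder.synthetic_data import make_slide, margin_preset

slide = make_slide(margin_preset(n=30, seed=7))
outdir = Path(tempfile.mkdtemp()) / "bundle"
slide.write_bundle(outdir)

summary = validate_bundle(outdir)
for key, value in summary.items():
    print(f"{key:>20}: {value}")

# n_spots counts the 2x2-per-patch expression spot lattice; crop dimensions
# are in full-resolution pixels (30 patches x 224 px).
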