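"""Convert (synthetic) Vizgen MERFISH-style tables into a sample folder.

Cell centroids are recorded in microns; the provided 3x3 affine maps them
into mosaic pixel space so cells land on the background image.  Counts are
stored raw (per-cell transcript counts).
"""

import os
import tempfile

import numpy as np
import pandas as pd

from spatialprep import AffineMatrix, Overlay, convert_merfish, validate_sample
from spatialprep.fixtures import FixtureConfig, make_merfish_fixture

with tempfile.TemporaryDirectory() as d:
    affine = AffineMatrix([[9.2, 0.0, 420.0], [0.0, 9.2, 310.0], [0.0, 0.0, 1.0]])
    cfg = FixtureConfig(seed=2, n_cells=100, n_genes=30, affine=affine)
    src = make_merfish_fixture(cfg, os.path.join(d, "vizgen"))
    out = convert_merfish(
        os.path.join(src, "cell_by_gene.csv"),
        os.path.join(src, "cell_metadata.csv"),
        os.path.join(src, "micron_to_mosaic_pixel_transform.csv"),
        os.path.join(d, "sample"),
    )
    print("validation findings:", validate_sample(out))

    truth = pd.read_csv(os.path.join(src, "truth_pixels.csv"))
    overlay = Overlay.from_csv(os.path.join(out, "cells.csv"))
    err = np.max(np.abs(overlay.x - truth["x"].to_numpy()))
    print(f"{overlay.n_points} cells; max centroid error vs affine truth: {err:.2e} px")

# The centroid error is at floating-point noise level: the converter applies
# exactly the affine the platform provides.
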