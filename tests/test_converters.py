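import json
import os

import numpy as np
import pandas as pd
import pytest

from spatialprep import (
    AffineMatrix,
    ConversionError,
    FeatureGroupReader,
    FormatError,
    Overlay,
    apply_affine,
    convert_merfish,
    parse_mtx_counts,
    parse_scalefactors,
    parse_tissue_positions,
    read_sample_meta,
    validate_sample,
)
from spatialprep.fixtures import FixtureConfig, make_merfish_fixture, make_visium_fixture


def test_tissue_positions_filters_and_swaps_axes(tmp_path):
    p = tmp_path / "pos.csv"
    p.write_text(
        "AAA-1,1,0,0,100.5,200.5\n"
        "BBB-1,0,0,2,110.0,210.0\n"
        "CCC-1,1,1,1,120.0,220.0\n"
    )
    ovl = parse_tissue_positions(p)
    assert ovl.ids == ["AAA-1", "CCC-1"]  # in_tissue=0 row excluded
    assert ovl.x.tolist() == [200.5, 220.0]  # x = pxl_col
    assert ovl.y.tolist() == [100.5, 120.0]  # y = pxl_row


def test_tissue_positions_dialects_agree(tmp_path):
    body = "AAA-1,1,0,0,10.0,20.0\nBBB-1,1,0,2,30.0,40.0\n"
    (tmp_path / "bare.csv").write_text(body)
    (tmp_path / "headered.csv").write_text(
        "barcode,in_tissue,array_row,array_col,pxl_row_in_fullres,pxl_col_in_fullres\n"
        + body
    )
    a = parse_tissue_positions(tmp_path / "bare.csv")
    b = parse_tissue_positions(tmp_path / "headered.csv")
    assert a.ids == b.ids
    assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)


def test_tissue_positions_wrong_column_count(tmp_path):
    (tmp_path / "bad.csv").write_text("AAA,1,2\n")
    with pytest.raises(FormatError, match="6-column"):
        parse_tissue_positions(tmp_path / "bad.csv")


@pytest.mark.parametrize("diameter,expected", [(55.0, 1.0), (110.0, 0.5)])
def test_scalefactors_microns_per_pixel(tmp_path, diameter, expected):
    p = tmp_path / "scalefactors_json.json"
    p.write_text(json.dumps({"spot_diameter_fullres": diameter}))
    assert parse_scalefactors(p).microns_per_pixel == expected


def test_scalefactors_missing_or_invalid(tmp_path):
    p = tmp_path / "sf.json"
    p.write_text("{}")
    with pytest.raises(FormatError, match="spot_diameter_fullres"):
        parse_scalefactors(p)
    p.write_text(json.dumps({"spot_diameter_fullres": 0}))
    with pytest.raises(FormatError):
        parse_scalefactors(p)


def _write_tiny_mtx(d, gzipped=False):
    import gzip

    os.makedirs(d, exist_ok=True)
    opener = (lambda p: gzip.open(p + ".gz", "wt")) if gzipped else (lambda p: open(p, "w"))
    with opener(os.path.join(d, "matrix.mtx")) as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n3 2 2\n1 1 5\n3 2 7\n")
    with opener(os.path.join(d, "barcodes.tsv")) as fh:
        fh.write("BC1\nBC2\n")
    with opener(os.path.join(d, "features.tsv")) as fh:
        fh.write("E1\tGeneA\tGene Expression\nE2\tGeneB\tGene Expression\nE3\tGeneC\tGene Expression\n")


def test_parse_mtx_hand_fixture(tmp_path):
    _write_tiny_mtx(tmp_path / "m")
    counts, barcodes, genes = parse_mtx_counts(tmp_path / "m")
    assert barcodes == ["BC1", "BC2"]
    assert genes == ["GeneA", "GeneB", "GeneC"]
    dense = np.asarray(counts.todense())
    expected = np.array([[5, 0, 0], [0, 0, 7]])
    assert np.array_equal(dense, expected)


def test_parse_mtx_gzipped_equals_plain(tmp_path):
    _write_tiny_mtx(tmp_path / "plain")
    _write_tiny_mtx(tmp_path / "gz", gzipped=True)
    a = parse_mtx_counts(tmp_path / "plain")
    b = parse_mtx_counts(tmp_path / "gz")
    assert np.array_equal(np.asarray(a[0].todense()), np.asarray(b[0].todense()))
    assert a[1:] == b[1:]


def test_parse_mtx_dimension_mismatch(tmp_path):
    _write_tiny_mtx(tmp_path / "m")
    with open(tmp_path / "m" / "barcodes.tsv", "a") as fh:
        fh.write("BC3\n")
    with pytest.raises(FormatError, match="barcodes"):
        parse_mtx_counts(tmp_path / "m")


def test_parse_mtx_empty_triplets(tmp_path):
    d = tmp_path / "m"
    os.makedirs(d)
    (d / "matrix.mtx").write_text("%%MatrixMarket matrix coordinate integer general\n2 1 0\n")
    (d / "barcodes.tsv").write_text("BC1\n")
    (d / "features.tsv").write_text("E1\tGeneA\nE2\tGeneB\n")
    counts, _, _ = parse_mtx_counts(d)
    assert counts.nnz == 0 and counts.shape == (1, 2)


@pytest.mark.parametrize(
    "matrix,point,expected",
    [
        (np.eye(3), (3.0, 4.0), (3.0, 4.0)),
        (np.diag([2.0, 2.0, 1.0]), (3.0, 4.0), (6.0, 8.0)),
        ([[2, 0, 10], [0, 3, -5], [0, 0, 1]], (1.0, 1.0), (12.0, -2.0)),
    ],
)
def test_apply_affine_examples(matrix, point, expected):
    out = apply_affine(np.array([point]), AffineMatrix(matrix))
    assert out[0].tolist() == list(expected)


def test_affine_rejects_bad_matrices():
    with pytest.raises(ValueError, match="bottom row"):
        AffineMatrix([[1, 0, 0], [0, 1, 0], [0, 0, 2]])
    with pytest.raises(ValueError, match="singular"):
        AffineMatrix([[0, 0, 0], [0, 0, 0], [0, 0, 1]])
    # a 2x3 matrix is promoted
    assert AffineMatrix([[1, 0, 5], [0, 1, 6]]).matrix[2].tolist() == [0, 0, 1]


def test_visium_sample_passes_validation(visium_sample):
    assert validate_sample(visium_sample) == []


def test_visium_feature_values_are_log1p_counts(visium_inputs, visium_sample):
    """Exhaustive: every stored value equals ln(1 + count) of the fixture."""
    truth = pd.read_csv(os.path.join(visium_inputs, "truth_counts.csv")).set_index("barcode")
    overlay = Overlay.from_csv(os.path.join(visium_sample, "spots.csv"))
    store = FeatureGroupReader.open(os.path.join(visium_sample, "genes.bin"))
    assert overlay.ids == list(truth.index)  # counts order preserved
    for gene in store.list_features():
        vec, _ = store.read_feature(gene)
        assert np.array_equal(vec, np.log1p(truth[gene].to_numpy(float)))


def test_visium_overlay_is_55um_circles(visium_sample):
    meta = read_sample_meta(os.path.join(visium_sample, "sample.json"))
    (ovl,) = meta.overlays
    assert ovl.geometry == "circle"
    assert ovl.diameter_um == 55.0
    # scale anchor: 55 um spots at the fixture's 110 px diameter -> 0.5 um/px
    assert meta.microns_per_pixel == pytest.approx(0.5)


def test_visium_excludes_out_of_tissue_rows(visium_inputs, visium_sample):
    pos = pd.read_csv(
        os.path.join(visium_inputs, "tissue_positions_list.csv"), header=None
    )
    out_of_tissue = set(pos[pos[1] == 0][0])
    overlay = Overlay.from_csv(os.path.join(visium_sample, "spots.csv"))
    assert out_of_tissue and not (out_of_tissue & set(overlay.ids))


def test_visium_unknown_barcode_is_conversion_error(tmp_path):
    cfg = FixtureConfig(seed=5, image_size=(1500, 1500), n_spots=10, n_genes=5)
    src = make_visium_fixture(cfg, tmp_path / "in")
    bpath = os.path.join(src, "filtered_feature_bc_matrix", "barcodes.tsv")
    lines = open(bpath).read().splitlines()
    lines[0] = "NOT-A-SPOT-1"
    open(bpath, "w").write("\n".join(lines) + "\n")
    with pytest.raises(ConversionError, match="NOT-A-SPOT"):
        from spatialprep import convert_visium

        convert_visium(src, os.path.join(src, "image.tif"), tmp_path / "out")


def test_merfish_sample_passes_validation(merfish_sample):
    assert validate_sample(merfish_sample) == []


def test_merfish_overlay_matches_affine_truth(merfish_inputs, merfish_sample):
    truth = pd.read_csv(os.path.join(merfish_inputs, "truth_pixels.csv"))
    truth["cell"] = truth["cell"].astype(str)
    truth = truth.set_index("cell")
    overlay = Overlay.from_csv(os.path.join(merfish_sample, "cells.csv"))
    assert np.max(np.abs(overlay.x - truth.loc[overlay.ids, "x"].to_numpy())) < 1e-9
    assert np.max(np.abs(overlay.y - truth.loc[overlay.ids, "y"].to_numpy())) < 1e-9


def test_merfish_counts_stored_raw(merfish_inputs, merfish_sample):
    cbg = pd.read_csv(os.path.join(merfish_inputs, "cell_by_gene.csv"))
    store = FeatureGroupReader.open(os.path.join(merfish_sample, "genes.bin"))
    for gene in store.list_features()[:5]:
        vec, _ = store.read_feature(gene)
        assert np.array_equal(vec, cbg[gene].to_numpy(float))


def test_merfish_identity_affine_is_fixed_point(tmp_path):
    cfg = FixtureConfig(seed=9, n_cells=20, n_genes=5, affine=AffineMatrix(np.eye(3)))
    src = make_merfish_fixture(cfg, tmp_path / "in")
    out = convert_merfish(
        os.path.join(src, "cell_by_gene.csv"),
        os.path.join(src, "cell_metadata.csv"),
        os.path.join(src, "micron_to_mosaic_pixel_transform.csv"),
        tmp_path / "out",
    )
    meta_df = pd.read_csv(os.path.join(src, "cell_metadata.csv"))
    overlay = Overlay.from_csv(os.path.join(out, "cells.csv"))
    assert np.array_equal(overlay.x, meta_df["center_x"].to_numpy(float))
    assert np.array_equal(overlay.y, meta_df["center_y"].to_numpy(float))


def test_merfish_id_mismatch_is_conversion_error(tmp_path):
    cfg = FixtureConfig(seed=9, n_cells=10, n_genes=5)
    src = make_merfish_fixture(cfg, tmp_path / "in")
    meta_path = os.path.join(src, "cell_metadata.csv")
    lines = open(meta_path).read().splitlines()
    del lines[1]
    open(meta_path, "w").write("\n".join(lines) + "\n")
    with pytest.raises(ConversionError, match="mismatch"):
        convert_merfish(
            os.path.join(src, "cell_by_gene.csv"),
            meta_path,
            os.path.join(src, "micron_to_mosaic_pixel_transform.csv"),
            tmp_path / "out",
        )


def test_preprocess_image_defaults_record_quality_90(tmp_path):
    from spatialprep import preprocess_image
    from spatialprep.fixtures import FixtureConfig, make_synthetic_image

    tiff = make_synthetic_image(FixtureConfig(seed=3, image_size=(300, 200)), tmp_path / "i.tif")
    out = preprocess_image(tiff, tmp_path / "sample")
    meta = read_sample_meta(os.path.join(out, "sample.json"))
    assert meta.images[0].compression == "jpeg"
    assert meta.images[0].jpeg_quality == 90
    assert validate_sample(out) == []


def test_preprocess_image_lossless_round_trips(tmp_path):
    import tifffile

    from spatialprep import PyramidReader, preprocess_image
    from spatialprep.fixtures import FixtureConfig, make_synthetic_image

    tiff = make_synthetic_image(FixtureConfig(seed=4, image_size=(310, 170)), tmp_path / "i.tif")
    out = preprocess_image(tiff, tmp_path / "sample", compression="lossless")
    original = tifffile.imread(tiff)
    decoded = PyramidReader.open(os.path.join(out, "image.tif")).read_level(0)
    assert np.array_equal(decoded[0], original)
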