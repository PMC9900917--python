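import numpy as np
import pytest
import tifffile

from spatialprep import (
    CachingRangeReader,
    FileRangeReader,
    PyramidReader,
    build_pyramid,
    downsample_level,
    gaussian_filter_image,
    plan_levels,
    plan_viewport,
)


def halving_oracle(w, h, tile):
    """Independent level plan: halve (ceiling) until max dim fits one tile."""
    dims = [(w, h)]
    while max(dims[-1]) > tile:
        dims.append(((dims[-1][0] + 1) // 2, (dims[-1][1] + 1) // 2))
    return tuple(dims)


@pytest.mark.parametrize(
    "w,h,tile,expected_n",
    [(512, 512, 512, 1), (20000, 20000, 512, 7), (513, 100, 512, 2)],
)
def test_plan_levels_matches_halving_oracle(w, h, tile, expected_n):
    plan = plan_levels(w, h, tile)
    assert plan.levels == halving_oracle(w, h, tile)
    assert plan.n_levels == expected_n


def test_plan_levels_known_dims():
    assert [d[0] for d in plan_levels(20000, 20000, 512).levels] == [
        20000, 10000, 5000, 2500, 1250, 625, 313,
    ]
    assert plan_levels(513, 100, 512).levels == ((513, 100), (257, 50))


def test_plan_levels_rejects_bad_args():
    with pytest.raises(ValueError):
        plan_levels(0, 10, 512)
    with pytest.raises(ValueError):
        plan_levels(10, 10, 8)


@pytest.mark.parametrize(
    "parent,expected",
    [
        ([[0, 0], [0, 0]], [[0]]),
        ([[1, 3], [5, 7]], [[4]]),
    ],
)
def test_downsample_small_examples(parent, expected):
    out = downsample_level(np.array(parent, dtype=np.uint8))
    assert out.tolist() == expected


def test_downsample_matches_block_mean_oracle(rng):
    """Every output pixel is the rounded mean of its <=2x2 source block."""
    for h, w in [(3, 3), (5, 8), (17, 4), (1, 7)]:
        parent = rng.integers(0, 256, size=(h, w)).astype(np.uint8)
        child = downsample_level(parent)
        assert child.shape == ((h + 1) // 2, (w + 1) // 2)
        for r in range(child.shape[0]):
            for c in range(child.shape[1]):
                block = parent[2 * r : 2 * r + 2, 2 * c : 2 * c + 2]
                assert child[r, c] == int(np.floor(block.mean() + 0.5))
    # 3x3 corner cell is the lone source pixel
    p = rng.integers(0, 256, size=(3, 3)).astype(np.uint8)
    assert downsample_level(p)[1, 1] == p[2, 2]


def test_gaussian_radius_zero_is_identity(rng):
    img = rng.integers(0, 256, size=(2, 32, 32)).astype(np.uint8)
    assert np.array_equal(gaussian_filter_image(img, 0), img)


def test_gaussian_constant_image_unchanged():
    img = np.full((1, 40, 40), 137, dtype=np.uint8)
    assert np.array_equal(gaussian_filter_image(img, 4.0), img)


def test_gaussian_impulse_unit_sum_and_symmetric():
    img = np.zeros((129, 129))
    img[64, 64] = 1.0
    out = gaussian_filter_image(img, 4.0)
    assert out.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(out, np.rot90(out), atol=1e-12)


def test_gaussian_negative_radius_rejected():
    with pytest.raises(ValueError):
        gaussian_filter_image(np.zeros((4, 4)), -1)


def test_single_tile_pyramid_round_trip(tmp_path):
    img = np.full((1, 256, 256), 7, dtype=np.uint8)
    spec = build_pyramid(img, ["c"], tmp_path / "p.tif", tile_size=256)
    assert spec.n_levels == 1
    reader = PyramidReader.open(tmp_path / "p.tif")
    assert np.array_equal(reader.read_tile(0, 0, 0), img)


@pytest.mark.parametrize(
    "shape,tile", [((1, 17, 23), 16), ((2, 257, 100), 64), ((4, 300, 517), 128)]
)
def test_lossless_round_trip_bit_exact(rng, tmp_path, shape, tile):
    img = rng.integers(0, 256, size=shape).astype(np.uint8)
    build_pyramid(img, [f"c{i}" for i in range(shape[0])], tmp_path / "p.tif", tile_size=tile)
    reader = PyramidReader.open(tmp_path / "p.tif")
    assert np.array_equal(reader.read_level(0), img)


def test_lossless_uint16_round_trip(rng, tmp_path):
    img = rng.integers(0, 2**16, size=(1, 100, 90)).astype(np.uint16)
    build_pyramid(img, ["c"], tmp_path / "p.tif", tile_size=64)
    assert np.array_equal(PyramidReader.open(tmp_path / "p.tif").read_level(0), img)


def test_overview_levels_consistent_with_downsampling(rng, tmp_path):
    """Level k equals downsample_level applied to level k-1, per channel."""
    img = rng.integers(0, 256, size=(2, 300, 280)).astype(np.uint8)
    build_pyramid(img, ["a", "b"], tmp_path / "p.tif", tile_size=64)
    reader = PyramidReader.open(tmp_path / "p.tif")
    prev = reader.read_level(0)
    for level in range(1, reader.n_levels):
        cur = reader.read_level(level)
        expected = np.stack([downsample_level(prev[c]) for c in range(prev.shape[0])])
        assert np.array_equal(cur, expected)
        prev = cur


def test_independent_tiff_reader_decodes_level0(rng, tmp_path):
    img = rng.integers(0, 256, size=(3, 200, 310)).astype(np.uint8)
    build_pyramid(img, ["r", "g", "b"], tmp_path / "p.tif", tile_size=64)
    assert np.array_equal(tifffile.imread(tmp_path / "p.tif"), img)


def test_jpeg_round_trip_close_and_quality_recorded(rng, tmp_path):
    img = rng.integers(0, 256, size=(3, 1024, 1024)).astype(np.uint8)
    spec = build_pyramid(
        img, ["r", "g", "b"], tmp_path / "p.tif", tile_size=256,
        compression="jpeg", jpeg_quality=90,
    )
    assert spec.jpeg_quality == 90
    reader = PyramidReader.open(tmp_path / "p.tif")
    assert reader.header.description["jpeg_quality"] == 90
    decoded = reader.read_level(0)
    mae = np.abs(decoded.astype(float) - img.astype(float)).mean()
    assert mae <= 5.0


def test_jpeg_rejects_uint16_and_bad_tile_size(rng, tmp_path):
    img16 = rng.integers(0, 2**16, size=(1, 32, 32)).astype(np.uint16)
    with pytest.raises(ValueError, match="uint8"):
        build_pyramid(img16, ["c"], tmp_path / "p.tif", compression="jpeg")
    img8 = img16.astype(np.uint8)
    with pytest.raises(ValueError, match="multiple of 16"):
        build_pyramid(img8, ["c"], tmp_path / "p.tif", tile_size=100)


def test_read_tile_rejects_out_of_grid(rng, tmp_path):
    img = rng.integers(0, 256, size=(1, 128, 128)).astype(np.uint8)
    build_pyramid(img, ["c"], tmp_path / "p.tif", tile_size=64)
    reader = PyramidReader.open(tmp_path / "p.tif")
    with pytest.raises(IndexError):
        reader.read_tile(0, 2, 0)
    with pytest.raises(IndexError):
        reader.read_tile(5, 0, 0)


def viewport_oracle(viewport, level, plan, tile):
    """Brute-force rectangle intersection over the whole tile grid."""
    x, y, vw, vh = viewport
    lw, lh = plan.levels[level]
    f = 2**level
    hits = []
    for r in range((lh + tile - 1) // tile):
        for c in range((lw + tile - 1) // tile):
            tx0, tx1 = c * tile * f, min((c + 1) * tile, lw) * f
            ty0, ty1 = r * tile * f, min((r + 1) * tile, lh) * f
            ix = max(x, tx0) < min(x + vw, tx1)
            iy = max(y, ty0) < min(y + vh, ty1)
            if ix and iy:
                hits.append((r, c))
    return hits


def test_plan_viewport_examples():
    plan = plan_levels(1024, 1024, 256)
    full = plan_viewport((0, 0, 1024, 1024), 0, plan, 256)
    assert full == [(r, c) for r in range(4) for c in range(4)]
    assert plan_viewport((10, 10, 100, 100), 0, plan, 256) == [(0, 0)]
    # viewport spanning a 2x2 tile corner
    assert plan_viewport((200, 200, 112, 112), 0, plan, 256) == [
        (0, 0), (0, 1), (1, 0), (1, 1),
    ]
    assert plan_viewport((2000, 2000, 10, 10), 0, plan, 256) == []


def test_plan_viewport_matches_brute_force_oracle(rng):
    plan = plan_levels(3000, 1700, 128)
    for _ in range(500):
        level = int(rng.integers(0, plan.n_levels))
        x, y = rng.uniform(-200, 3100), rng.uniform(-200, 1800)
        vw, vh = rng.uniform(1, 1500), rng.uniform(1, 1500)
        vp = (x, y, vw, vh)
        assert plan_viewport(vp, level, plan, 128) == viewport_oracle(vp, level, plan, 128)


@pytest.fixture(scope="module")
def big_pyramid(tmp_path_factory):
    rng = np.random.default_rng(7)
    img = rng.integers(0, 256, size=(1, 4096, 4096)).astype(np.uint8)
    path = tmp_path_factory.mktemp("pyr") / "big.tif"
    build_pyramid(img, ["c"], path, tile_size=256)
    return path, img


def test_single_tile_read_fetches_few_bytes(big_pyramid):
    """The lazy-read contract: one tile costs about one tile, not the file."""
    import os

    path, _ = big_pyramid
    file_size = os.path.getsize(path)
    reader = FileRangeReader(path)
    pyr = PyramidReader(reader)
    lvl = pyr.header.levels[0]
    n_tiles = lvl.rows * lvl.cols
    assert n_tiles == 256
    before = reader.total_bytes_fetched
    pyr.read_tile(0, 5, 9)
    tile_bytes = reader.total_bytes_fetched - before
    assert tile_bytes <= int(lvl.lengths[0, 5, 9])
    assert reader.total_bytes_fetched < 0.05 * file_size
    assert reader.total_bytes_fetched < file_size / n_tiles + pyr.header_bytes


def test_full_image_read_fetches_whole_level(big_pyramid):
    import os

    path, img = big_pyramid
    reader = FileRangeReader(path)
    pyr = PyramidReader(reader)
    region, nbytes = pyr.read_region((0, 0, 4096, 4096), 0)
    assert np.array_equal(region, img)
    lvl = pyr.header.levels[0]
    assert nbytes == int(lvl.lengths.sum())
    # level 0 of an incompressible image dominates the file
    assert reader.total_bytes_fetched > 0.7 * os.path.getsize(path)


def test_disjoint_region_reads_are_byte_additive(big_pyramid):
    path, _ = big_pyramid
    pyr = PyramidReader.open(path)
    _, b1 = pyr.read_region((0, 0, 200, 200), 0)
    _, b2 = pyr.read_region((3000, 3000, 60, 60), 0)
    lvl = pyr.header.levels[0]
    assert b1 == int(lvl.lengths[0, 0, 0])
    assert b2 == int(lvl.lengths[0, 11, 11])


def test_cached_rereads_are_free(big_pyramid):
    path, _ = big_pyramid
    reader = CachingRangeReader(FileRangeReader(path))
    pyr = PyramidReader(reader)
    t1 = pyr.read_tile(0, 2, 2)
    before = reader.total_bytes_fetched
    t2 = pyr.read_tile(0, 2, 2)
    assert reader.total_bytes_fetched == before
    assert np.array_equal(t1, t2)
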