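import numpy as np
import pytest

from spatialprep import convert_merfish, convert_visium
from spatialprep.fixtures import FixtureConfig, make_merfish_fixture, make_visium_fixture


@pytest.fixture(scope="session")
def visium_inputs(tmp_path_factory):
    """A Space Ranger-style fixture directory: 50 spots x 20 genes."""
    cfg = FixtureConfig(seed=11, image_size=(2000, 2000), n_spots=50, n_genes=20)
    return make_visium_fixture(cfg, tmp_path_factory.mktemp("visium_in"))


@pytest.fixture(scope="session")
def visium_sample(visium_inputs, tmp_path_factory):
    """The converted Visium sample folder."""
    import os

    out = tmp_path_factory.mktemp("visium_out") / "sample"
    convert_visium(visium_inputs, os.path.join(visium_inputs, "image.tif"), out)
    return str(out)


@pytest.fixture(scope="session")
def merfish_inputs(tmp_path_factory):
    cfg = FixtureConfig(seed=12, image_size=(600, 600), n_cells=100, n_genes=30)
    return make_merfish_fixture(cfg, tmp_path_factory.mktemp("merfish_in"))


@pytest.fixture(scope="session")
def merfish_sample(merfish_inputs, tmp_path_factory):
    import os

    out = tmp_path_factory.mktemp("merfish_out") / "sample"
    convert_merfish(
        os.path.join(merfish_inputs, "cell_by_gene.csv"),
        os.path.join(merfish_inputs, "cell_metadata.csv"),
        os.path.join(merfish_inputs, "micron_to_mosaic_pixel_transform.csv"),
        out,
        image_path=os.path.join(merfish_inputs, "image.tif"),
    )
    return str(out)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
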