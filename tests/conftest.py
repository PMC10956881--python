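import numpy as np
import pytest

from hdsnet.data import index_dataset, split
from hdsnet.synthetic import LesionParams, generate_dataset


@pytest.fixture(scope="session")
def synth_dir(tmp_path_factory):
    """Ten 64×64 synthetic lesion pairs in ISIC layout."""
    d = tmp_path_factory.mktemp("synthdata")
    generate_dataset(10, LesionParams(image_size=(64, 64)), d, seed=7)
    return d


@pytest.fixture(scope="session")
def synth_index(synth_dir):
    return split(index_dataset(synth_dir), ratio=0.8, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
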