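import numpy as np
import pytest

from greenmap import Manifest, SceneSpec, write_scene
from greenmap.taxonomy import CLASS_ORDER


def balanced_layout(rows: int, cols: int) -> list[list[str]]:
    """Grid layout cycling through the eight classes (balanced when
    rows*cols is a multiple of 8)."""
    return [[CLASS_ORDER[(r * cols + c) % 8] for c in range(cols)] for r in range(rows)]


@pytest.fixture(scope="session")
def scene_pair(tmp_path_factory):
    """A small balanced train/test scene pair written to disk (32 px tiles).

    Train: 8x16 = 128 tiles (16 per class); test: 4x8 = 32 tiles. Seeds are
    disjoint so no test tile repeats a train tile.
    """
    root = tmp_path_factory.mktemp("scenes")
    spec_tr = SceneSpec(8, 16, tile_size=32, seed=11, class_layout=balanced_layout(8, 16))
    spec_te = SceneSpec(4, 8, tile_size=32, seed=99, class_layout=balanced_layout(4, 8))
    _, man_tr = write_scene(spec_tr, root / "train")
    _, man_te = write_scene(spec_te, root / "test")
    return Manifest.read_csv(man_tr), Manifest.read_csv(man_te)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
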