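import numpy as np
import pytest

from neurotopo.binning import BinMatrix, MarkerSet, assemble_matrix, build_grid
from neurotopo.geometry import Contour


@pytest.fixture
def unit_square() -> Contour:
    return Contour([(0, 0), (1, 0), (1, 1), (0, 1)], label="sq")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_marker_set(points, subject_id="s1", condition="a", **kw) -> MarkerSet:
    return MarkerSet(subject_id=subject_id, condition=condition,
                     bregma_mm=-3.36, region="LAd", points=np.asarray(points),
                     registered=True, **kw)


@pytest.fixture
def small_matrix() -> BinMatrix:
    """2 conditions x 2 subjects on a 2x2 grid of side 10."""
    grid = build_grid(0, 20, 0, 20, 10)
    sets = [
        make_marker_set([(5, 5), (5, 5)], "a1", "a"),
        make_marker_set([(5, 5), (5, 5), (5, 5), (5, 5)], "a2", "a"),
        make_marker_set([(15, 15)], "b1", "b"),
        make_marker_set([(15, 15), (15, 5)], "b2", "b"),
    ]
    return assemble_matrix(sets, grid)
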