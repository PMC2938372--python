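import numpy as np
import pytest
from hypothesis import settings

from viscocell import Cell, CellParams, World
from viscocell.config import AdhesionRule

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def params40():
    return CellParams(n_points=40)


@pytest.fixture
def params20():
    return CellParams(n_points=20)


@pytest.fixture
def cell40(params40):
    return Cell.build(params40, cid=0)


@pytest.fixture
def rest_cell(params40):
    """Cell at its exact rest geometry with no pressure differential."""
    c = Cell.build(params40, cid=0)
    c.P_in = 0.0
    return c


@pytest.fixture
def rule():
    return AdhesionRule()


def make_world(*cells, **kw):
    w = World(**kw)
    for c in cells:
        w.add_cell(c)
    return w


@pytest.fixture
def two_touching_cells(params20):
    """Two cells with adjacent membranes inside the junction-creation range."""
    gap = 1.0  # < d_a
    a = Cell.build(params20, center=(-(params20.radius + gap / 2), 0.0), cid=0)
    b = Cell.build(params20, center=(params20.radius + gap / 2, 0.0), cid=1)
    return make_world(a, b, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
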