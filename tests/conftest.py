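import numpy as np
import pytest

import florasim as fs
from florasim.fixtures import grid_tissue


@pytest.fixture
def square_cell():
    """Single unit-square cell with a fresh state."""
    mesh = fs.build_initial_tissue(1, 1.0)
    mesh.cells[0].state = fs.CellState(auxin=0.0, pin_endosome=5.0)
    return mesh


@pytest.fixture
def two_cell_mesh():
    """Two unit squares sharing one wall, with states attached."""
    mesh = fs.build_initial_tissue(2, 1.0)
    for cell in mesh.cells.values():
        cell.state = fs.CellState(auxin=1.0, pin_endosome=5.0)
    return mesh


@pytest.fixture
def grid3x3():
    return grid_tissue(3, 3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def states_of(mesh):
    return {cid: c.state for cid, c in mesh.cells.items()}
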