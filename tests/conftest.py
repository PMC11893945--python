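import numpy as np
import pytest

from microdsb.geometry import VialGeometry, place_cells
from microdsb.macro import TransportTables
from microdsb.nuclide import load_nuclide_table
from microdsb.synthetic import anchored_table_path, extended_table_path


@pytest.fixture(scope="session")
def tables():
    return TransportTables.default()


@pytest.fixture(scope="session")
def alpha_table(tables):
    return tables.alpha


@pytest.fixture(scope="session")
def electron_table(tables):
    return tables.electron


@pytest.fixture(scope="session")
def anchored_nuclides():
    return load_nuclide_table(anchored_table_path())


@pytest.fixture(scope="session")
def extended_nuclides():
    return load_nuclide_table(extended_table_path())


@pytest.fixture(scope="session")
def vial():
    return VialGeometry()


@pytest.fixture(scope="session")
def cells(vial):
    return place_cells(vial, 1000, np.random.default_rng(1234))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def mini_geometry():
    """Small vial (radius 200 µm) with 30 cells: analog runs produce usable
    crossing statistics here."""
    vial = VialGeometry(volume_ml=4.0 / 3.0 * np.pi * 200.0**3 / 1e12)
    cells = place_cells(vial, 30, np.random.default_rng(7))
    return vial, cells
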