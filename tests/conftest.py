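import numpy as np
import pytest

from stiffmap.field_model import ElasticityField, Grid2D
from stiffmap.synthetic_data import BoundaryLoad, Phantom, forward_solve


@pytest.fixture
def unit_grid():
    return Grid2D(nx=8, ny=8, t=1.0, h=1.0)


@pytest.fixture
def square_grid_24():
    n = 24
    return Grid2D(nx=n, ny=n, t=1.0 / (n - 1), h=1.0 / (n - 1))


def gaussian_blob_phantom(grid, E_bg=1.0, dE=2.0, nu_bg=0.3, dnu=0.12, s=0.18):
    """Smooth two-blob phantom resolvable at desk-scale grids."""
    Xc, Yc = grid.cell_xy()
    E = E_bg + dE * np.exp(-((Xc - 0.5) ** 2 + (Yc - 0.5) ** 2) / (2 * s**2))
    nu = nu_bg + dnu * np.exp(-((Xc - 0.35) ** 2 + (Yc - 0.6) ** 2) / (2 * s**2))
    return Phantom(elast=ElasticityField(E=E, nu=nu), descriptor="blob")


@pytest.fixture
def homogeneous_uniaxial():
    """Homogeneous plate under uniform load: exact closed-form solution."""
    n = 12
    grid = Grid2D(nx=n, ny=n, t=1.0 / (n - 1), h=1.0 / (n - 1))
    E0, nu0, F = 2.0, 0.0, 1.0
    phantom = Phantom(
        elast=ElasticityField(
            E=np.full(grid.cell_shape, E0), nu=np.full(grid.cell_shape, nu0)
        ),
        descriptor="homogeneous",
    )
    load = BoundaryLoad(profile="uniform_load", F=F)
    u = forward_solve(phantom, load, grid)
    return grid, phantom, load, u, E0, F
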