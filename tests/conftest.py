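"""Shared fixtures: grids and forcing sized for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

from npzdvar.grid import ModelGrid, make_bohai_grid, make_synthetic_forcing


@pytest.fixture(scope="session")
def default_grid() -> ModelGrid:
    """The full 4-arcminute production grid (75 x 60 x 6)."""
    return make_bohai_grid()


@pytest.fixture(scope="session")
def coarse_grid() -> ModelGrid:
    """12-arcminute grid for quicker integration tests."""
    return make_bohai_grid(12.0)


@pytest.fixture(scope="session")
def coarse_forcing(coarse_grid):
    return make_synthetic_forcing(coarse_grid, days=30.0, step_hours=6.0, seed=42)


def rectangle_grid(nx: int, ny: int, layers=(5.0, 7.0), depth: float = 15.0) -> ModelGrid:
    """Fully wet rectangular test grid (no land ring)."""
    lon_edges = np.linspace(117.5, 122.5, nx + 1)
    lat_edges = np.linspace(37.0, 41.0, ny + 1)
    mask = np.ones((ny, nx), dtype=bool)
    return ModelGrid(lon_edges, lat_edges, np.asarray(layers, dtype=float),
                     mask, np.full((ny, nx), depth))


@pytest.fixture()
def grid_5x5() -> ModelGrid:
    """5 x 5 x 2 all-wet grid used by the gradient-check oracle."""
    return rectangle_grid(5, 5, layers=(5.0, 7.0), depth=15.0)


@pytest.fixture()
def grid_10x10() -> ModelGrid:
    return rectangle_grid(10, 10, layers=(5.0,), depth=8.0)
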