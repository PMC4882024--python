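"""Shared fixtures: small synthetic environments reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from stemspat.plot_io import PlotWindow, PointPattern, RasterSurface
from stemspat.synthgen import make_soils, make_terrain, standardized_truth_stack
from stemspat.terrain import classify_habitats, pca_environment, quadrat_topography


@pytest.fixture(scope="session")
def small_window() -> PlotWindow:
    return PlotWindow(200.0, 200.0)


@pytest.fixture(scope="session")
def small_env(small_window):
    """PCA environment stack on a 200 x 200 window (40 x 40 cells)."""
    rng = np.random.default_rng(1234)
    terrain = make_terrain(small_window, smoothness=40.0, n_bumps=25, rng=rng)
    soils = make_soils(terrain, n_random=200, rng=rng)
    return pca_environment(standardized_truth_stack(terrain, soils))


@pytest.fixture(scope="session")
def small_habitat_map(small_window):
    rng = np.random.default_rng(99)
    terrain = make_terrain(small_window, smoothness=40.0, n_bumps=25, rng=rng)
    topo = quadrat_topography(terrain.posts)
    return classify_habitats(topo)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def constant_surface(value: float, window: PlotWindow, cell: float = 5.0,
                     name: str = "const") -> RasterSurface:
    nx = int(round(window.x_extent / cell))
    ny = int(round(window.y_extent / cell))
    return RasterSurface(np.full((ny, nx), value), cell, window.origin, name)


def csr(n: int, window: PlotWindow, rng) -> PointPattern:
    return PointPattern(
        rng.uniform(window.xrange[0], window.xrange[1], n),
        rng.uniform(window.yrange[0], window.yrange[1], n),
        window,
    )
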