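"""Shared fixtures: small grids and the seeded default phantom scenes.

The heavier seeded scenes (default 128x128 phantom pair and the 3-region
tissue scene) are session-scoped so the end-to-end tests share one
generation + decomposition.
"""

from __future__ import annotations

import numpy as np
import pytest

import deglare as dg
from deglare.phantom import PhantomConfig, generate_phantom_pair, generate_tissue_scene

#: seed fixed for the whole suite
SEED = 0


@pytest.fixture(scope="session")
def grid134() -> dg.WavelengthGrid:
    return dg.WavelengthGrid.from_range(500.0, 900.0, 3.0)


@pytest.fixture(scope="session")
def small_grid() -> dg.WavelengthGrid:
    return dg.WavelengthGrid(np.array([500.0, 602.0, 752.0, 900.0]))


def make_cube(data, grid, kind="reflectance"):
    return dg.Hypercube(np.asarray(data, dtype=float), grid, kind=kind)


def make_series(arrays, grid, kind="reflectance"):
    return dg.IlluminationSeries([make_cube(a, grid, kind) for a in arrays])


@pytest.fixture(scope="session")
def default_pair():
    """Default seeded smooth/rough phantom pair (128x128, 134 bands, 3 dirs)."""
    cfg = PhantomConfig(seed=SEED)
    smooth, rough = generate_phantom_pair(cfg)
    return cfg, smooth, rough


@pytest.fixture(scope="session")
def rough_result(default_pair):
    """Decomposition of the default rough phantom (mp=6, min-epsilon-zero)."""
    _, _, rough = default_pair
    return dg.decompose_cube(rough.reflectance, cfg=dg.SolverConfig(poly_order=6))


@pytest.fixture(scope="session")
def tissue_scene():
    """Default seeded 3-region tissue-like scene with rough-mode glare."""
    cfg = PhantomConfig(shape=(96, 96), seed=SEED)
    return generate_tissue_scene(cfg)


@pytest.fixture(scope="session")
def tissue_result(tissue_scene):
    return dg.decompose_cube(
        tissue_scene.reflectance, cfg=dg.SolverConfig(poly_order=6)
    )
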