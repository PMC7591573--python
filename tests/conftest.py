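"""Shared fixtures: grids, lights, phantoms, and the slow shared runs."""

import numpy as np
import pytest

import quasispec as q


@pytest.fixture(scope="session")
def grid():
    return q.WavelengthGrid.default()


@pytest.fixture(scope="session")
def small_grid():
    # 9 points -> 8 intervals: pure composite Simpson, exact for cubics
    return q.WavelengthGrid(np.linspace(450.0, 775.0, 9))


@pytest.fixture(scope="session")
def light(grid):
    return q.default_light(grid)


@pytest.fixture(scope="session")
def tiny_scene():
    """8x8 two-region scene for fast structural tests."""
    return q.two_region_scene(size=8, noise_sigma=0.05, seed=5)


def fast_config(white_level, **kw):
    """Solver config scaled down for unit tests (not the default study run)."""
    defaults = dict(white_level=white_level, budget=150, max_iterations=12)
    defaults.update(kw)
    return q.SolverConfig(**defaults)


@pytest.fixture(scope="session")
def phantom_run():
    """The canonical 24x24 two-region study run with default solver config.

    Shared by the convergence, forward-consistency and determinism checks.
    """
    scene = q.two_region_scene(size=24, noise_sigma=0.05, seed=7)
    model = q.QuasiSpectralModel(
        scene["image"], scene["light"],
        q.SolverConfig(white_level=scene["white_level"]))
    return scene, model.fit(seed=1)
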