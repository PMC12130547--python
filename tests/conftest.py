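"""Shared fixtures: small fast design problems and full-scale study cases.

The "small" fixtures (10 mm aperture, 128-pixel grid, 20 iterations) keep
unit tests fast; the session-scoped "study" fixtures run the full-scale
designs once and are shared by the characterization and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from holobeam import (
    DesignConfig,
    FocusTarget,
    HologramDesign,
    PistonSource,
    make_grid,
)
from holobeam.fixtures import fixture_biplane, fixture_single_focus


@pytest.fixture()
def small_grid():
    return make_grid(128, 128, 100e-6)  # 12.8 mm


@pytest.fixture()
def small_source():
    return PistonSource(diameter=10e-3, frequency=1.5e6, surface_pressure=1.0)


@pytest.fixture(scope="session")
def small_design_result():
    """Fast single-focus design: 10 mm aperture, focus at 15 mm."""
    model = HologramDesign(
        targets=[FocusTarget(0.0, 0.0, 15e-3)],
        source=PistonSource(diameter=10e-3, frequency=1.5e6),
        grid=make_grid(128, 128, 100e-6),
        config=DesignConfig(max_iterations=20),
    )
    return model.fit()


def _fit(cfg):
    return HologramDesign(
        targets=cfg.targets,
        source=cfg.source,
        grid=cfg.grid,
        medium=cfg.medium,
        config=cfg.design,
    ).fit()


@pytest.fixture(scope="session")
def single10_result():
    return _fit(fixture_single_focus(10))


@pytest.fixture(scope="session")
def single20_result():
    return _fit(fixture_single_focus(20))


@pytest.fixture(scope="session")
def single30_result():
    return _fit(fixture_single_focus(30))


@pytest.fixture(scope="session")
def biplane_result():
    return _fit(fixture_biplane())


@pytest.fixture(scope="session")
def biplane_unweighted_result():
    cfg = fixture_biplane()
    cfg.design.weight_exponent = 0.0
    return _fit(cfg)


@pytest.fixture(scope="session")
def single20_table(single20_result):
    """Focus table of the 20 mm design over z = 10-35 mm at 0.2 mm steps."""
    z_list = np.arange(10e-3, 35e-3 + 1e-4, 0.2e-3)
    table, stack = single20_result.characterize(z_list)
    return table
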