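import numpy as np
import pytest

from oticpattern import (
    GrnParameters,
    build_competence,
    build_extrinsic_fgf,
    make_grid,
    preset_scenario,
    simulate,
)
from oticpattern.scenario_engine import PRESET_NAMES


@pytest.fixture(scope="session")
def grid():
    return make_grid(101)


@pytest.fixture(scope="session")
def fgf_e(grid):
    return build_extrinsic_fgf(grid)


@pytest.fixture(scope="session")
def competence(grid):
    return build_competence(grid)


@pytest.fixture(scope="session")
def params():
    return GrnParameters()


@pytest.fixture(scope="session")
def all_results(grid, fgf_e, competence, params):
    """Kymographs for every preset scenario with shipped defaults.

    Session-scoped: the whole suite shares one simulation batch.
    """
    return {
        name: simulate(preset_scenario(name), params, grid, fgf_e, competence)
        for name in PRESET_NAMES
    }


@pytest.fixture(scope="session")
def coarse_setup():
    """Small grid for cohort simulations (positions are independent, so a
    coarser axis only coarsens the extent readout)."""
    g = make_grid(41)
    return g, build_extrinsic_fgf(g), build_competence(g), GrnParameters()


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
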