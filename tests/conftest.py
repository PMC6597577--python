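import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pgpdyn as pg

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> pg.ProcessParameters:
    return pg.default_params()


@pytest.fixture(scope="session")
def grid() -> pg.ActivityGrid:
    return pg.ActivityGrid()


@pytest.fixture(scope="session")
def coarse_grid() -> pg.ActivityGrid:
    """Reduced grid for calibration-loop tests."""
    return pg.ActivityGrid(n_bins=100)


@pytest.fixture(scope="session")
def fast_cfg() -> pg.SolverConfig:
    """Coarser time step for calibration-loop tests."""
    return pg.SolverConfig(dt_max=0.2)


@pytest.fixture
def basal_state(params, grid) -> pg.SystemState:
    """Sensitive-only state at the basal equilibrium profile, 2e4 cells."""
    u1 = 2.0e4 * pg.equilibrium_density(grid, 1, params)
    return pg.SystemState.from_arrays(grid, u1, np.zeros(grid.n_bins))
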