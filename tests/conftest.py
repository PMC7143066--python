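import numpy as np
import pytest

from pdmix import design as dz
from pdmix import io as pio


@pytest.fixture(scope="session")
def study_runs():
    """The packaged 29-run liposome study table."""
    return pio.load_study_runs()


@pytest.fixture(scope="session")
def study_spec():
    return dz.default_study_design(seed=0)


@pytest.fixture(scope="session")
def size_model(study_runs):
    from pdmix import rsm

    model, report = rsm.reduce_model(study_runs, "z_average_nm")
    return model, report


@pytest.fixture(scope="session")
def pdi_model(study_runs):
    from pdmix import rsm

    model, report = rsm.reduce_model(study_runs, "pdi")
    return model, report


@pytest.fixture(scope="session")
def desk_geometry():
    """Truncated serpentine: first 8 obstacles, ~4.9 mm of path."""
    from pdmix.mixing import build_geometry

    return build_geometry().truncated(8)


@pytest.fixture(scope="session")
def frr_sweep(desk_geometry):
    """Mixing simulations at TFR 18 mL/h over FRR in {1, 3, 5, 9}."""
    from pdmix.mixing import simulate_mixing

    return {
        frr: simulate_mixing(desk_geometry, 18.0, float(frr))
        for frr in (1, 3, 5, 9)
    }


@pytest.fixture(scope="session")
def straight_flow():
    """Constant-property creeping flow in an obstacle-free channel."""
    from pdmix.mixing import build_geometry, discretize, solve_flow

    geom = build_geometry(n_obstacles=0, entrance_um=0.0, exit_um=3000.0)
    grid = discretize(geom, cells_across=30)
    return solve_flow(grid, 18.0, 1.0, mu=1.0e-3, rho=1000.0)
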