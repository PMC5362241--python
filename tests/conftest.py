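import pytest
from hypothesis import HealthCheck, settings

import rhozone as rz

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def kp_default() -> rz.KineticParams:
    """Bistable reference kinetics: alpha=1, kappa1=kappa2=0.2, n=4."""
    return rz.KineticParams()


@pytest.fixture(scope="session")
def c_high(kp_default) -> float:
    return float(rz.find_fixed_points(kp_default).high[0])


@pytest.fixture(scope="session")
def saddle_value(kp_default) -> float:
    return float(rz.find_fixed_points(kp_default).saddle[0])


@pytest.fixture(scope="session")
def grid_small() -> rz.Grid:
    """Short domain for fast transport tests."""
    return rz.Grid(length=20.0, n_cells=200)


@pytest.fixture(scope="session")
def grid_default() -> rz.Grid:
    return rz.Grid()


@pytest.fixture(scope="session")
def pe12_record(kp_default, c_high, grid_default):
    """A flow-pinned stationary-zone record (Pe=12, both species advected)."""
    init = rz.make_pulse(grid_default, c_high, 1.0, "rho", K=1.0)
    return rz.simulate(init, kp_default, rz.MechParams(pe=12.0, K=1.0),
                       grid_default, 120.0, 0.5)


@pytest.fixture(scope="session")
def slow_kinetics_zone(grid_default):
    """Converged flow-pinned zone for slow kinetics (alpha=0.02, Pe=8): the
    starting state of the contractility-inhibition experiments."""
    kp = rz.KineticParams(alpha=0.02)
    high = float(rz.find_fixed_points(kp).high[0])
    init = rz.make_pulse(grid_default, high, 1.0, "both", K=1.0)
    rec = rz.simulate(init, kp, rz.MechParams(pe=8.0, K=1.0), grid_default, 300.0, 5.0)
    return rec.frame(rec.n_frames - 1)


@pytest.fixture(scope="session")
def pe15_wide_init_record(kp_default, c_high, grid_default):
    """Pe=15 run started from a broad active zone (half-width 4), which must
    narrow onto the same stationary width as a narrow ignition pulse."""
    init = rz.make_pulse(grid_default, c_high, 4.0, "both", K=1.0)
    return rz.simulate(init, kp_default, rz.MechParams(pe=15.0, K=1.0),
                       grid_default, 120.0, 0.5)
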