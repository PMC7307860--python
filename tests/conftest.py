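import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fruitflux as ff

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> ff.ModelParameters:
    return ff.reference_parameters()


@pytest.fixture(scope="session")
def heavy_w0() -> float:
    return ff.preset_initial_weight("C5_95")


@pytest.fixture(scope="session")
def c5_result(params, heavy_w0) -> ff.SimulationResult:
    """Calibrated heavy-crop-load control day (the reference treatment)."""
    scenario = ff.scenario_preset("C5_95", params)
    return ff.run_day(ff.SimulationConfig(scenario=scenario, params=params,
                                          W0=heavy_w0))


@pytest.fixture(scope="session")
def c30_result(params) -> ff.SimulationResult:
    """Light-crop-load control day (30 leaf-to-fruit, 1995)."""
    scenario = ff.scenario_preset("C30_95", params)
    return ff.run_day(ff.SimulationConfig(scenario=scenario, params=params,
                                          W0=130.0))


@pytest.fixture(scope="session")
def g5_result(params, heavy_w0) -> ff.SimulationResult:
    scenario = ff.scenario_preset("G5_95", params)
    return ff.run_day(ff.SimulationConfig(scenario=scenario, params=params,
                                          W0=heavy_w0))


def quiescent_scenario(psi: float = -0.6) -> ff.ScenarioInputs:
    """All drivers flat and in equilibrium: no gradients, no transpiration,
    no sugar."""
    flat = ff.SinusoidDriver(base_value=psi, extreme_value=psi)
    return ff.ScenarioInputs(
        label="quiescent",
        treatment="synthetic",
        condition="control",
        psi_w_pp=flat,
        c_pp_mass=ff.SinusoidDriver(base_value=0.0, extreme_value=0.0),
        transpiration_per_area=ff.FullDaySinusoid(min_value=0.0, max_value=0.0),
        psi_w_fs=flat,
    )


@pytest.fixture()
def random_boundary():
    """Draw physically valid boundary conditions/geometry, reproducibly."""
    rng = np.random.default_rng(20260920)

    def draw():
        return (
            ff.BoundaryConditions(
                psi_w_pp=rng.uniform(-2.0, -0.2),
                C_pp=rng.uniform(0.01, 0.40) / ff.DEFAULT_CONSTANTS.M_S,
                T_fa=rng.uniform(0.0, 0.3),
                psi_w_fs=rng.uniform(-2.5, -0.3),
                temperature=rng.uniform(283.0, 303.0),
            ),
            ff.geometry_from_weight(rng.uniform(30.0, 200.0)),
        )

    return draw
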