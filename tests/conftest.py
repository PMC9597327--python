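import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phaeosim as ps

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> ps.KineticParameters:
    return ps.KineticParameters().validate()


@pytest.fixture(scope="session")
def panel_scenario():
    return ps.get_scenario("5L_flat_panel_4xf2")


@pytest.fixture(scope="session")
def reference_run(params, panel_scenario):
    """The 5 L flat-panel batch reference simulation (16 days, defaults)."""
    sc = panel_scenario
    return ps.simulate_batch(
        sc.initial_state(params), sc.reactor, sc.schedule, params, sc.duration_days
    )


@pytest.fixture(scope="session")
def conservative_run(params, panel_scenario):
    """Same reference run with zero decay: N + Q X must be conserved."""
    sc = panel_scenario
    p0 = params.replace(K_d=0.0)
    return ps.simulate_batch(
        sc.initial_state(p0), sc.reactor, sc.schedule, p0, sc.duration_days
    )


@pytest.fixture(scope="session")
def nsufficient_scenarios(params, panel_scenario):
    """Initial states for the N-sufficient (N >> K_N throughout: even the
    fully loaded final biomass cannot draw the medium down) and N-limited
    sensitivity scenarios on the 5 L panel."""
    x0 = ps.initial_biomass_from_od(panel_scenario.initial_od550, params)
    n_suff = 2000.0
    n_lim = panel_scenario.medium.nitrogen_N0
    return {
        "N_sufficient": (ps.CultureState(X=x0, N=n_suff, Q=params.Q_max), 16.0),
        "N_limited": (ps.CultureState(X=x0, N=n_lim, Q=params.Q_max), 16.0),
    }


@pytest.fixture(scope="session")
def sensitivity_report(params, panel_scenario, nsufficient_scenarios):
    sc = panel_scenario
    options = ps.SimulationOptions(rtol=1e-8, atol=1e-10, points_per_day=4)
    return ps.sensitivity_one_at_a_time(
        sc.reactor, sc.schedule, params, nsufficient_scenarios, options=options
    )


@pytest.fixture(scope="session")
def harvest_grid(params, panel_scenario):
    """Full 7x9 harvest grid on the N-sufficient 5 L setup (5x f/2 start,
    6x f/2 refresh), 8-day batch then 4 cycles."""
    sc = panel_scenario
    x0 = ps.initial_biomass_from_od(sc.initial_od550, params)
    initial = ps.CultureState(X=x0, N=ps.MediumSpec.from_f2_multiple(5).nitrogen_N0, Q=params.Q_max)
    refresh = ps.MediumSpec.from_f2_multiple(6).nitrogen_N0
    options = ps.SimulationOptions(rtol=1e-8, atol=1e-10, points_per_day=4)
    return ps.harvest_grid_search(
        sc.reactor, sc.schedule, params, initial, refresh, options=options
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
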