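import math

import numpy as np
import pytest

import phaeosim as ps
from phaeosim.core import CultureState, KineticParameters, ReactorConfig
from phaeosim.simulator import (
    HarvestPolicy,
    LightSchedule,
    SimulationOptions,
    biomass_productivity,
    derivatives,
    initial_biomass_from_od,
    overall_productivity,
    predict_states,
    simulate_batch,
    simulate_repeated_batch,
)

P = KineticParameters()
PANEL = ReactorConfig(geometry="flat_panel", incident_intensity_Io=350.0,
                      photoperiod_light_h=12.0, path_length_L=0.05)


class TestLightSchedule:
    def test_twelve_twelve(self):
        s = LightSchedule(light_hours=12.0)
        assert s.is_light(0.0) and s.is_light(0.49)
        assert not s.is_light(0.5) and not s.is_light(0.99)
        assert s.next_switch(0.2) == pytest.approx(0.5)
        assert s.next_switch(0.7) == pytest.approx(1.0)

    def test_continuous_light_and_dark(self):
        assert LightSchedule(light_hours=24.0).is_light(0.93)
        assert not LightSchedule(light_hours=0.0).is_light(0.25)

    def test_bad_hours_rejected(self):
        with pytest.raises(ValueError):
            LightSchedule(light_hours=30.0)


class TestDerivatives:
    def test_hand_computed_light_phase(self):
        """One derivative evaluation against independent arithmetic."""
        X, N, Q = 100.0, 40.0, 0.12
        ka = 2.74 * Q + 0.21
        a = ka * X * 0.05
        iav = 350.0 * (1 - math.exp(-a)) / a
        light = iav**1.9 / (50.0**1.9 + iav**1.9)
        mu = 2.4 * light * (1 - 0.034 / Q) / (1 - 0.034 / 0.12)
        u = 0.59 * (N / (0.010 + N)) * (1 - Q / 0.12)
        dX, dQ, dN = derivatives(CultureState(X=X, N=N, Q=Q), True, PANEL, P)
        assert dX == pytest.approx(mu * X - 0.010 * X, rel=1e-9)
        assert dQ == pytest.approx(u - mu * Q, rel=1e-9)
        assert dN == pytest.approx(-u * X, rel=1e-9)

    def test_dark_depleted_medium(self):
        dX, dQ, dN = derivatives(CultureState(X=500.0, N=0.0, Q=0.08), False, PANEL, P)
        assert dX == pytest.approx(-P.K_d * 500.0, rel=1e-12)
        assert dQ == 0.0 and dN == 0.0

    def test_no_growth_no_decay_is_stationary(self):
        p0 = P.replace(K_d=0.0)
        dX, _, _ = derivatives(CultureState(X=500.0, N=0.0, Q=0.08), False, PANEL, p0)
        assert dX == 0.0

    def test_dark_flags_switch_off_decay_and_uptake(self):
        opts = SimulationOptions(dark_decay=False, dark_uptake=False)
        dX, dQ, dN = derivatives(
            CultureState(X=500.0, N=20.0, Q=0.08), False, PANEL, P, opts
        )
        assert dX == 0.0 and dQ == 0.0 and dN == 0.0

    def test_invalid_state_rejected(self):
        with pytest.raises(ps.simulator.SimulationError):
            s = CultureState(X=1.0, N=1.0, Q=0.08)
            s.X = float("nan")
            derivatives(s, True, PANEL, P)


class TestBatchSimulation:
    def test_exponential_limit_continuous_light(self):
        """With no decay, saturating light and uptake fast enough to pin
        the quota at Q_max, the culture grows exponentially at mu_max."""
        p0 = P.replace(K_d=0.0, U_max=1e4)
        reactor = ReactorConfig(geometry="flat_panel", incident_intensity_Io=1e9,
                                photoperiod_light_h=24.0, path_length_L=0.05)
        init = CultureState(X=1.0, N=1e4, Q=p0.Q_max)
        r = simulate_batch(init, reactor, LightSchedule(light_hours=24.0), p0, 1.0)
        assert r.frame["X_mg_L"].iloc[-1] == pytest.approx(math.exp(p0.mu_max), rel=1e-3)

    def test_light_phase_doubling_time(self):
        """Under 12:12 only the light half-day grows: one day multiplies the
        biomass by exp(mu_max/2)."""
        p0 = P.replace(K_d=0.0, U_max=1e4)
        reactor = ReactorConfig(geometry="flat_panel", incident_intensity_Io=1e9,
                                photoperiod_light_h=12.0, path_length_L=0.05)
        init = CultureState(X=1.0, N=1e4, Q=p0.Q_max)
        r = simulate_batch(init, reactor, LightSchedule(light_hours=12.0), p0, 1.0)
        assert r.frame["X_mg_L"].iloc[-1] == pytest.approx(math.exp(p0.mu_max / 2), rel=1e-3)
        # doubling time inside the light phase is ln 2 / mu_max
        assert math.log(2) / p0.mu_max == pytest.approx(0.289, abs=1e-3)

    def test_nitrogen_conservation_without_decay(self, conservative_run):
        """d(N + QX)/dt = 0 when K_d = 0: the primary correctness oracle."""
        f = conservative_run.frame
        total = f["N_mgN_L"] + f["Q_mgN_mgDCW"] * f["X_mg_L"]
        assert np.max(np.abs(total / total.iloc[0] - 1.0)) < 1e-6

    def test_nitrogen_balance_diagnostic_with_decay(self, reference_run):
        assert reference_run.metadata["nitrogen_balance_rel_residual"] < 1e-5

    def test_quota_stays_within_droop_bounds(self, reference_run):
        q = reference_run.frame["Q_mgN_mgDCW"]
        assert (q >= P.Q_min - 1e-9).all() and (q <= P.Q_max + 1e-9).all()

    def test_state_never_negative(self, reference_run):
        f = reference_run.frame
        assert (f["X_mg_L"] >= 0).all() and (f["N_mgN_L"] >= 0).all()

    def test_depletion_event_refined_against_dense_grid(self, reference_run):
        f = reference_run.frame
        below = f[f["N_mgN_L"] < 0.1]
        t_grid = below["t_days"].iloc[0]
        assert reference_run.n_depletion_time == pytest.approx(t_grid, abs=0.05)
        assert reference_run.n_depletion_state.N == pytest.approx(0.1, abs=1e-6)

    def test_tolerance_halving_changes_day16_biomass_under_0p1pct(
        self, params, panel_scenario
    ):
        sc = panel_scenario
        tight = SimulationOptions(rtol=5e-9, atol=5e-11, points_per_day=2)
        r2 = simulate_batch(sc.initial_state(params), sc.reactor, sc.schedule,
                            params, 16.0, tight)
        loose = SimulationOptions(rtol=1e-8, atol=1e-10, points_per_day=2)
        r1 = simulate_batch(sc.initial_state(params), sc.reactor, sc.schedule,
                            params, 16.0, loose)
        x1 = r1.frame["X_mg_L"].iloc[-1]
        x2 = r2.frame["X_mg_L"].iloc[-1]
        assert abs(x2 / x1 - 1.0) < 1e-3

    def test_initial_quota_outside_bounds_rejected(self, params, panel_scenario):
        sc = panel_scenario
        bad = CultureState(X=10.0, N=49.28, Q=0.5)
        with pytest.raises(ValueError, match="quota"):
            simulate_batch(bad, sc.reactor, sc.schedule, params, 1.0)

    def test_od_inversion(self):
        ka = 2.74 * 0.12 + 0.21
        assert initial_biomass_from_od(0.05, P) == pytest.approx(0.05 / (0.01 * ka), rel=1e-12)

    def test_scheduled_dilution_hook(self, params, panel_scenario):
        """The optional sampling-withdrawal hook dilutes biomass and swaps
        medium at the scheduled instant."""
        sc = panel_scenario
        opts = SimulationOptions(points_per_day=96, scheduled_dilutions=[(1.0, 0.5, 0.0)])
        r = simulate_batch(sc.initial_state(params), sc.reactor, sc.schedule, params, 2.0, opts)
        f = r.frame
        x_before = f.loc[np.isclose(f["t_days"], 1.0), "X_mg_L"].iloc[0]
        x_after = f.loc[f["t_days"] > 1.0, "X_mg_L"].iloc[0]
        # halved, modulo at most one output step of regrowth
        assert x_after < 0.5 * x_before * math.exp(params.mu_max / 96)

    def test_predict_states_matches_dense_run(self, params, panel_scenario, reference_run):
        sc = panel_scenario
        days = [4.0, 8.0, 14.0]
        pred = predict_states(sc.initial_state(params), sc.reactor, sc.schedule, params, days)
        for row, d in zip(pred, days):
            s = reference_run.state_at(d)
            assert row[0] == pytest.approx(s.X, rel=1e-4)
            assert row[1] == pytest.approx(s.N, rel=1e-3, abs=1e-6)
            assert row[2] == pytest.approx(s.Q, rel=1e-4)

    def test_predict_states_requires_future_days(self, params, panel_scenario):
        sc = panel_scenario
        with pytest.raises(ValueError):
            predict_states(sc.initial_state(params), sc.reactor, sc.schedule, params, [0.0])


class TestRepeatedBatch:
    def test_harvest_mixing_rule(self, params, panel_scenario):
        """X <- (1-f)X, N <- (1-f)N + f N_fresh, Q untouched."""
        sc = panel_scenario
        policy = HarvestPolicy(batch_days=8.0, interval=3.0, fraction=0.6,
                               refresh_nitrogen_N0=61.6, n_cycles=1)
        opts = SimulationOptions(points_per_day=96)
        r = simulate_repeated_batch(sc.initial_state(params), sc.reactor, sc.schedule,
                                    params, policy, opts)
        ev = r.harvest_events.iloc[0]
        x_pre = r.frame.loc[np.isclose(r.frame["t_days"], 8.0), "X_mg_L"].iloc[0]
        assert ev["X_removed_mg_L"] == pytest.approx(0.6 * x_pre, rel=1e-9)
        assert ev["N_after"] == pytest.approx(0.4 * ev["N_before"] + 0.6 * 61.6, rel=1e-9)
        # quota is intracellular: no jump across the harvest (continuous up
        # to one output step of refilling on the fresh medium)
        q_pre = r.frame.loc[np.isclose(r.frame["t_days"], 8.0), "Q_mgN_mgDCW"].iloc[0]
        q_post = r.frame.loc[r.frame["t_days"] > 8.0, "Q_mgN_mgDCW"].iloc[0]
        assert q_post == pytest.approx(q_pre, rel=0.06)

    def test_mixing_arithmetic_example(self):
        # X=1000, f=0.6, N=0, fresh=61.6 -> X=400, N=36.96
        f, x, n, nf = 0.6, 1000.0, 0.0, 61.6
        assert (1 - f) * x == pytest.approx(400.0)
        assert (1 - f) * n + f * nf == pytest.approx(36.96)

    def test_vanishing_fraction_recovers_batch(self, params, panel_scenario):
        sc = panel_scenario
        opts = SimulationOptions(rtol=1e-8, atol=1e-10, points_per_day=2)
        policy = HarvestPolicy(batch_days=4.0, interval=2.0, fraction=1e-7,
                               refresh_nitrogen_N0=49.28, n_cycles=2)
        rb = simulate_repeated_batch(sc.initial_state(params), sc.reactor, sc.schedule,
                                     params, policy, opts)
        b = simulate_batch(sc.initial_state(params), sc.reactor, sc.schedule,
                           params, 8.0, opts)
        assert rb.frame["X_mg_L"].iloc[-1] == pytest.approx(
            b.frame["X_mg_L"].iloc[-1], rel=1e-5
        )

    def test_invalid_policy_rejected(self):
        with pytest.raises(ValueError):
            HarvestPolicy(fraction=1.0)
        with pytest.raises(ValueError):
            HarvestPolicy(interval=0.0)


class TestProductivity:
    def test_batch_definition_is_dcw_over_time(self, reference_run):
        prod = biomass_productivity(reference_run)
        f = reference_run.frame
        x8 = f.loc[np.isclose(f["t_days"], 8.0), "X_mg_L"].iloc[0]
        assert prod.loc[8.0] == pytest.approx(x8 / 8.0, rel=1e-12)
        assert 0.0 not in prod.index  # t=0 undefined, excluded

    def test_simple_division(self):
        assert 960.0 / 8.0 == 120.0  # the batch definition at DCW=960, t=8

    def test_zero_growth_trajectory_zero_overall(self, params):
        p0 = params.replace(K_d=0.0)
        reactor = ReactorConfig(geometry="flat_panel", incident_intensity_Io=350.0,
                                photoperiod_light_h=0.0, path_length_L=0.05)
        init = CultureState(X=100.0, N=0.0, Q=0.08)
        opts = SimulationOptions(dark_uptake=False, points_per_day=4)
        r = simulate_batch(init, reactor, LightSchedule(light_hours=0.0), p0, 4.0, opts)
        overall = biomass_productivity(r, mode="overall")
        assert np.allclose(overall.to_numpy(), 0.0, atol=1e-9)

    def test_overall_includes_harvest_ledger(self, params, panel_scenario):
        sc = panel_scenario
        policy = HarvestPolicy(batch_days=8.0, interval=3.0, fraction=0.6,
                               refresh_nitrogen_N0=73.92, n_cycles=2)
        opts = SimulationOptions(points_per_day=2)
        r = simulate_repeated_batch(sc.initial_state(params), sc.reactor, sc.schedule,
                                    params, policy, opts)
        expected = (
            r.harvested_biomass_per_litre
            + r.frame["X_mg_L"].iloc[-1]
            - r.initial.X
        ) / r.frame["t_days"].iloc[-1]
        assert overall_productivity(r) == pytest.approx(expected, rel=1e-12)
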