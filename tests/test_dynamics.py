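import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from abscopal._fastsim import ArmSchedule, batch_simulate
from abscopal.dynamics import (
    InitialConditionSpec,
    apply_radiation_impulse,
    extravasation_probability,
    immunotherapy_signal,
    initial_state,
    logistic_backsolve,
    rhs,
    simulate,
)
from abscopal.parameters import (
    ImmunotherapyProtocol,
    ModelParameters,
    RadiationProtocol,
    SystemState,
    TumorSiteState,
)


class TestImmunotherapySignal:
    def test_zero_before_first_injection(self):
        proto = ImmunotherapyProtocol(injection_times=[12.0, 15.0, 18.0])
        assert immunotherapy_signal(5.0, proto, e=8.495, clr=0.967) == 0.0

    def test_amplitude_at_injection_instant(self):
        proto = ImmunotherapyProtocol(injection_times=[12.0])
        assert immunotherapy_signal(12.0, proto, e=8.495, clr=0.967) == 8.495

    def test_single_bolus_decay(self):
        proto = ImmunotherapyProtocol(injection_times=[12.0])
        want = 8.495 * math.exp(-0.967)
        assert immunotherapy_signal(13.0, proto, e=8.495, clr=0.967) == \
            pytest.approx(want, rel=1e-12)

    @given(st.lists(st.floats(0.0, 30.0), min_size=1, max_size=5),
           st.floats(15.0, 40.0))
    def test_closed_form_matches_clearance_ode(self, times, t_eval):
        """The closed form must agree with direct numerical integration of
        the first-order clearance dynamics (du/dt = -clr*u, bolus jumps +e)."""
        e, clr = 8.495, 0.967
        times = sorted(times)
        proto = ImmunotherapyProtocol(injection_times=times)
        u = 0.0
        t_now = 0.0
        for tb in [t for t in times if t <= t_eval]:
            if tb > t_now:
                sol = solve_ivp(lambda t, y: [-clr * y[0]], (t_now, tb), [u],
                                rtol=1e-12, atol=1e-14)
                u = sol.y[0, -1]
                t_now = tb
            u += e
        if t_eval > t_now:
            sol = solve_ivp(lambda t, y: [-clr * y[0]], (t_now, t_eval), [u],
                            rtol=1e-12, atol=1e-14)
            u = sol.y[0, -1]
        assert immunotherapy_signal(t_eval, proto, e, clr) == \
            pytest.approx(u, abs=1e-8, rel=1e-8)


class TestExtravasation:
    def _state(self, v1, v2):
        return SystemState(t=0.0, site1=TumorSiteState(C=v1),
                           site2=TumorSiteState(C=v2))

    def test_symmetry(self):
        assert extravasation_probability(self._state(10.0, 10.0)) == (0.5, 0.5)

    def test_proportionality(self):
        assert extravasation_probability(self._state(30.0, 10.0)) == (0.75, 0.25)

    def test_both_empty_convention(self):
        assert extravasation_probability(self._state(0.0, 0.0)) == (0.5, 0.5)

    @given(st.floats(0.0, 1e4), st.floats(0.0, 1e4))
    def test_normalization(self, v1, v2):
        p1, p2 = extravasation_probability(self._state(v1, v2))
        assert p1 + p2 == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= p1 <= 1.0


class TestRHS:
    def test_extinction_fixed_point(self, params):
        state = SystemState(t=0.0, site1=TumorSiteState(), site2=TumorSiteState())
        assert np.all(rhs(state, params, u=0.0) == 0.0)

    def test_carrying_capacity_equilibrium(self, params):
        p = params.replace(a=0.0, w=0.0)
        state = SystemState(t=0.0, site1=TumorSiteState(C=1423.1),
                            site2=TumorSiteState())
        dy = rhs(state, p, u=0.0)
        assert dy[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_viable_derivative(self):
        # dC/dt = 0.195*100*(1 - 100/1423.1) - 0.0177*100*1 = 16.3597...
        p = ModelParameters(r=0.195, K=1423.1, a=0.0177)
        state = SystemState(t=0.0, site1=TumorSiteState(C=100.0, E=1.0),
                            site2=TumorSiteState())
        dy = rhs(state, p, u=0.0)
        assert dy[0] == pytest.approx(
            0.195 * 100 * (1 - 100 / 1423.1) - 0.0177 * 100, rel=1e-12)

    def test_negative_state_rejected(self, params):
        state = SystemState(t=0.0, site1=TumorSiteState(C=1.0),
                            site2=TumorSiteState())
        state.site1.C = -1.0  # bypass constructor check
        with pytest.raises(ValueError):
            rhs(state, params, u=0.0)


class TestRadiationImpulse:
    def test_identity_at_sf_one(self):
        s = TumorSiteState(C=50.0, Dv=3.0, I=1.0, E=2.0)
        out = apply_radiation_impulse(s, sf=1.0, ai=0.5)
        assert (out.C, out.Dv, out.I, out.E) == (50.0, 3.0, 1.0, 2.0)

    def test_20gy_table_arithmetic(self):
        s = TumorSiteState(C=100.0)
        out = apply_radiation_impulse(s, sf=0.265, ai=0.194)
        assert out.C == pytest.approx(26.5)
        assert out.I == pytest.approx(73.5 * 0.194)
        assert out.Dv == pytest.approx(73.5 * 0.806)
        assert out.volume == pytest.approx(100.0, abs=1e-12)

    def test_full_kill_all_immunogenic(self):
        s = TumorSiteState(C=40.0, Dv=1.0, I=2.0)
        out = apply_radiation_impulse(s, sf=0.0, ai=1.0)
        assert out.C == 0.0
        assert out.I == 42.0
        assert out.Dv == 1.0

    @given(st.floats(0, 1e3), st.floats(0, 1e3), st.floats(0, 1e3),
           st.floats(0, 1), st.floats(0, 1))
    def test_volume_conserved_exactly(self, c, dv, i, sf, ai):
        s = TumorSiteState(C=c, Dv=dv, I=i)
        out = apply_radiation_impulse(s, sf=sf, ai=ai)
        # one multiply-and-add per compartment: conservation to float rounding
        assert out.volume == pytest.approx(s.volume, rel=1e-14, abs=1e-12)
        assert out.E == s.E

    @pytest.mark.parametrize("sf,ai", [(-0.1, 0.5), (1.1, 0.5), (0.5, 2.0)])
    def test_fraction_validation(self, sf, ai):
        with pytest.raises(ValueError):
            apply_radiation_impulse(TumorSiteState(C=1.0), sf, ai)


class TestInitialState:
    def test_palpable_at_capacity_rejected(self, params):
        with pytest.raises(ValueError):
            logistic_backsolve(params.K, 12.0, params.r, params.K)

    def test_zero_interval_identity(self, params):
        assert logistic_backsolve(32.0, 0.0, params.r, params.K) == \
            pytest.approx(32.0, rel=1e-12)

    def test_backsolve_roundtrip_through_logistic_ode(self, params):
        v0 = logistic_backsolve(32.0, 12.0, params.r, params.K)
        sol = solve_ivp(lambda t, y: [params.r * y[0] * (1 - y[0] / params.K)],
                        (0.0, 12.0), [v0], rtol=1e-11, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(32.0, rel=1e-6)

    def test_initial_state_anchors(self, params):
        spec = InitialConditionSpec()
        (d1, s1), (d2, s2) = initial_state(spec, params)
        assert (d1, d2) == (0.0, 2.0)
        assert s1.Dv == s1.I == s1.E == 0.0
        assert 0 < s2.C < s1.C < 32.0


class TestSimulate:
    def test_exponential_growth_limit(self, params, table):
        """With no immune terms and far-from-capacity growth, the viable
        compartment grows exponentially at rate r."""
        p = params.replace(a=0.0, w=0.0, K=1e12)
        ic = InitialConditionSpec(palpable_volumes=(32.0, 21.0))
        res = simulate(p, table, None, None, ic=ic, horizon=32.0,
                       output_grid=np.array([0.0, 10.0, 32.0]))
        c0 = res.trajectories["site1"]["C"][0]
        for t, c in zip(res.times[1:], res.trajectories["site1"]["C"][1:]):
            assert c == pytest.approx(c0 * math.exp(p.r * t), rel=1e-6)

    def test_post_irradiation_decay_limit(self, params, table):
        """With growth and immune terms off, both dying compartments decay
        as exp(-d t) from their post-impulse values."""
        p = params.replace(r=1e-12, a=0.0, w=0.0)
        rt = RadiationProtocol(events=[(12.0, 20.0)])
        res = simulate(p, table, rt, None, horizon=32.0,
                       output_grid=np.array([12.0, 20.0, 32.0]))
        post = res.events[0]["post"]
        for t_idx, t in [(1, 20.0), (2, 32.0)]:
            decay = math.exp(-p.d * (t - 12.0))
            assert res.trajectories["site1"]["Dv"][t_idx] == \
                pytest.approx(post.Dv * decay, rel=1e-6)
            assert res.trajectories["site1"]["I"][t_idx] == \
                pytest.approx(post.I * decay, rel=1e-6)

    def test_volume_continuous_across_impulse(self, params, table):
        rt = RadiationProtocol(events=[(12.0, 20.0)])
        res = simulate(params, table, rt, None, horizon=14.0)
        ev = res.events[0]
        assert ev["post"].volume == pytest.approx(ev["pre"].volume, rel=1e-14)
        assert ev["post"].C == pytest.approx(ev["pre"].C * 0.265, rel=1e-12)
        # the grid shows no volume jump at the event beyond solver tolerance
        i = np.searchsorted(res.times, 12.0)
        v = res.trajectories["site1"]["V"]
        assert abs(v[i] - v[i - 1]) < 1.5 * abs(v[i + 1] - v[i]) + 1e-6

    def test_adaptive_agrees_with_fixed_step_oracle(self, params, table):
        """Adaptive RK45 at 1e-8 tolerance vs classical RK4 at 1e-3 day."""
        rt = RadiationProtocol(events=[(12.0, 20.0)])
        it = ImmunotherapyProtocol(injection_times=[12.0, 15.0, 18.0])
        res = simulate(params, table, rt, it, horizon=32.0,
                       output_grid=np.array([32.0]))
        sched = [ArmSchedule(impulses=[(12.0, *table.lookup(20.0))],
                             injections=[12.0, 15.0, 18.0])]
        si = initial_state(InitialConditionSpec(), params)
        out = batch_simulate(params, sched, si, 32.0, [32.0], step=1e-3)
        for site, cols in ((1, slice(0, 3)), (2, slice(4, 7))):
            v_fixed = out[0, 0, cols].sum()
            assert res.volume(site, 32.0) == pytest.approx(v_fixed, rel=1e-4)

    def test_non_negativity_on_grid(self, params, table):
        rt = RadiationProtocol.daily(12.0, 5, 6.0)
        it = ImmunotherapyProtocol(injection_times=[12.0, 14.0, 16.0])
        res = simulate(params, table, rt, it, horizon=32.0)
        for site in ("site1", "site2"):
            for name, series in res.trajectories[site].items():
                assert np.all(series >= 0.0), (site, name)

    def test_volume_identity_on_grid(self, params, table):
        res = simulate(params, table, None, None, horizon=20.0)
        for site in ("site1", "site2"):
            tr = res.trajectories[site]
            np.testing.assert_allclose(tr["V"], tr["C"] + tr["Dv"] + tr["I"],
                                       rtol=0, atol=1e-12)

    def test_event_after_horizon_rejected(self, params, table):
        rt = RadiationProtocol(events=[(40.0, 20.0)])
        with pytest.raises(ValueError, match="horizon"):
            simulate(params, table, rt, None, horizon=32.0)

    def test_unknown_dose_needs_model(self, params, table):
        rt = RadiationProtocol(events=[(12.0, 10.0)])
        with pytest.raises(KeyError, match="10"):
            simulate(params, table, rt, None, horizon=32.0)

    def test_tidy_export(self, params, table):
        res = simulate(params, table, None, None, horizon=14.0,
                       output_grid=np.array([0.0, 7.0, 14.0]))
        df = res.to_frame()
        assert set(df.columns) == {"time_day", "site", "compartment", "value"}
        assert len(df) == 3 * 2 * 5  # times x sites x compartments

    def test_secondary_site_dormant_before_implantation(self, params, table):
        res = simulate(params, table, None, None, horizon=10.0,
                       output_grid=np.array([0.0, 1.0, 1.9, 2.0, 5.0]))
        v2 = res.trajectories["site2"]["V"]
        assert np.all(v2[:3] == 0.0)
        assert v2[3] > 0.0 and v2[4] > v2[3]
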