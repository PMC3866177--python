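"""Core model: transition equations, integration, prevalence summaries."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

import obesim as ob

ZERO_CHILD = dict(n_child=1.0, ow_child=0.0, ob_child=0.0)


def params(**overrides) -> ob.BehaviorParams:
    """All rates zero, unit transition times, overridable per field."""
    base = dict(
        beta_aa=0.0, beta_cc=0.0, beta_ac=0.0, gamma_a=0.0, gamma_c=0.0,
        rho_awl=0.0, rho_cwl=0.0, eps_awl=0.0, eps_cwl=0.0,
        p_sa=1.0, p_sc=1.0, p_oa=1.0, p_oc=1.0,
    )
    base.update(overrides)
    return ob.BehaviorParams(**base)


def simplex3(draw, st_floats):
    a, b = sorted([draw(st_floats), draw(st_floats)])
    return a, b - a, 1.0 - b


@st.composite
def states(draw):
    unit = st.floats(0.0, 1.0, allow_nan=False)
    na, sa, oa = simplex3(draw, unit)
    nc, sc, oc = simplex3(draw, unit)
    return ob.PopulationState(na, sa, oa, nc, sc, oc)


@st.composite
def random_params(draw):
    rate = st.floats(0.0, 0.01)
    prop = st.floats(0.0, 1.0)
    time = st.floats(10.0, 300.0)
    return params(
        beta_aa=draw(rate), beta_cc=draw(rate), beta_ac=draw(rate),
        gamma_a=draw(rate), gamma_c=draw(rate),
        rho_awl=draw(prop), rho_cwl=draw(prop),
        eps_awl=draw(prop), eps_cwl=draw(prop),
        p_sa=draw(time), p_sc=draw(time), p_oa=draw(time), p_oc=draw(time),
    )


class TestStateValidation:
    def test_rejects_broken_simplex(self):
        with pytest.raises(ValueError, match="adult stocks sum"):
            ob.PopulationState(0.5, 0.5, 0.5, **ZERO_CHILD)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            ob.PopulationState(1.2, -0.1, -0.1, **ZERO_CHILD)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            ob.PopulationState(float("nan"), 0.5, 0.5, **ZERO_CHILD)

    @pytest.mark.parametrize("field,value,match", [
        ("p_sa", 0.0, "p_sa"),
        ("beta_aa", -0.1, "beta_aa"),
        ("rho_awl", 1.5, "rho_awl"),
    ])
    def test_param_constraints_name_the_field(self, field, value, match):
        with pytest.raises(ValueError, match=match):
            params(**{field: value})


class TestDerivatives:
    def test_all_normal_weight_is_stationary(self):
        """No overweight/obese contacts: nothing to transmit, progress or recover."""
        state = ob.PopulationState(1.0, 0.0, 0.0, 1.0, 0.0, 0.0)
        d = ob.derivatives(state, params(beta_aa=0.01, beta_cc=0.01, beta_ac=0.01,
                                         gamma_a=0.01, rho_awl=0.5, eps_awl=0.5))
        assert np.all(d.to_array() == 0.0)

    def test_adult_transmission_hand_value(self):
        """beta_aa*N_A*(S_A+O_A) = 0.0015*0.3*0.7 moves mass N_A -> S_A only."""
        state = ob.PopulationState(0.3, 0.35, 0.35, **ZERO_CHILD)
        d = ob.derivatives(state, params(beta_aa=0.0015))
        assert d.n_adult == pytest.approx(-0.000315, abs=1e-15)
        assert d.ow_adult == pytest.approx(+0.000315, abs=1e-15)
        assert d.ob_adult == 0.0
        assert d.n_child == d.ow_child == d.ob_child == 0.0

    def test_child_sees_both_peer_and_adult_exposure(self):
        """Child infection flow is [beta_cc*(S_C+O_C) + beta_ac*(S_A+O_A)]*N_C."""
        state = ob.PopulationState(0.5, 0.3, 0.2, 0.6, 0.25, 0.15)
        d = ob.derivatives(state, params(beta_cc=0.002, beta_ac=0.003))
        expected = (0.002 * 0.4 + 0.003 * 0.5) * 0.6
        assert d.n_child == pytest.approx(-expected)
        assert d.ow_child == pytest.approx(expected)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(state=states(), p=random_params())
    def test_closed_groups_conserve_mass(self, state, p):
        d = ob.derivatives(state, p).to_array()
        assert abs(d[:3].sum()) < 1e-15
        assert abs(d[3:].sum()) < 1e-15

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(state=states(), p=random_params(), child_shift=st.floats(0.0, 1.0))
    def test_adult_equations_never_reference_child_stocks(self, state, p, child_shift):
        """Structural: the adult derivative is unchanged by any child stocks."""
        nc, sc, oc = simplex_from_shift(child_shift)
        other = dataclasses.replace(state, n_child=nc, ow_child=sc, ob_child=oc)
        d1 = ob.derivatives(state, p).to_array()[:3]
        d2 = ob.derivatives(other, p).to_array()[:3]
        assert np.array_equal(d1, d2)


def simplex_from_shift(u: float):
    s = 0.5 * u
    return 1.0 - 2 * s, s, s


class TestIntegrate:
    def test_zero_dynamics_is_constant(self):
        initial = ob.PopulationState(0.4, 0.3, 0.3, 0.5, 0.3, 0.2)
        traj = ob.integrate(initial, params(),
                            ob.SimulationConfig(dt=0.5, horizon=20, record_every=0.5))
        assert np.all(traj.states == traj.states[0])
        assert traj.times[0] == 0.0 and traj.times[-1] == 20.0

    def test_linear_subsystem_matches_matrix_exponential(self):
        """With beta = gamma = 0 the system is linear; compare against expm."""
        p = params(rho_awl=0.3, eps_awl=0.2, rho_cwl=0.25, eps_cwl=0.15,
                   p_sa=60.0, p_oa=120.0, p_sc=50.0, p_oc=100.0)
        initial = ob.PopulationState(0.3, 0.35, 0.35, 0.6, 0.2, 0.2)
        horizon = 520.0
        traj = ob.integrate(initial, p,
                            ob.SimulationConfig(dt=0.25, horizon=horizon,
                                                integrator="rk4", record_every=1.0))
        a_s, a_o = p.rho_awl / p.p_sa, p.eps_awl / p.p_oa
        c_s, c_o = p.rho_cwl / p.p_sc, p.eps_cwl / p.p_oc
        block = lambda rs, ro: np.array(  # noqa: E731
            [[0.0, rs, 0.0], [0.0, -rs, ro], [0.0, 0.0, -ro]])
        A = np.zeros((6, 6))
        A[:3, :3] = block(a_s, a_o)
        A[3:, 3:] = block(c_s, c_o)
        exact = expm(A * horizon) @ initial.to_array()
        assert np.allclose(traj.states[-1], exact, atol=1e-6)

    def test_step_halving_converges(self, cfg):
        f = lambda dt: ob.integrate(  # noqa: E731
            cfg.initial_state, cfg.params,
            ob.SimulationConfig(dt=dt, horizon=520.0, record_every=520.0))
        p1 = ob.prevalence(f(0.25).final_state, ob.Group.CHILD)
        p2 = ob.prevalence(f(0.125).final_state, ob.Group.CHILD)
        assert abs(p1 - p2) < 1e-4 * 100  # within 1e-4 as a fraction

    def test_euler_and_rk4_agree(self, cfg):
        out = {}
        for method in ("euler", "rk4"):
            traj = ob.integrate(
                cfg.initial_state, cfg.params,
                ob.SimulationConfig(dt=0.25, horizon=520.0, integrator=method,
                                    record_every=520.0))
            out[method] = ob.prevalence(traj.final_state, ob.Group.CHILD) / 100.0
        assert abs(out["euler"] - out["rk4"]) < 1e-4

    def test_rk4_handles_time_varying_schedule(self, cfg):
        factors = ob.ImpactFactors(psi_a=0.5, psi_c=0.25)
        totals = ob.total_impacts(ob.InterventionImpacts(eta_na=0.5), factors)
        schedule = ob.intervention_schedule(cfg.params, totals, factors, 520.0)
        euler = ob.integrate(cfg.initial_state, schedule,
                             ob.SimulationConfig(dt=0.25, horizon=520.0, record_every=520.0))
        rk4 = ob.integrate(cfg.initial_state, schedule,
                           ob.SimulationConfig(dt=0.25, horizon=520.0, integrator="rk4",
                                               record_every=520.0))
        assert np.allclose(euler.states[-1], rk4.states[-1], atol=1e-4)

    def test_oversized_step_raises(self):
        """A recovery outflow exceeding the stock in one step must error, not clip."""
        p = params(rho_awl=1.0, p_sa=0.1)  # outflow rate 10/week
        initial = ob.PopulationState(0.3, 0.5, 0.2, **ZERO_CHILD)
        with pytest.raises(ValueError, match="reduce dt"):
            ob.integrate(initial, p, ob.SimulationConfig(dt=1.0, horizon=10, record_every=1.0))

    def test_monotone_in_transmission_rates(self, cfg):
        """Raising any beta weakly raises childhood prevalence at every time."""
        final = {}
        for field in ("beta_aa", "beta_cc", "beta_ac"):
            prevs = []
            for scale in (0.5, 1.0, 1.5):
                p = dataclasses.replace(cfg.params, **{field: getattr(cfg.params, field) * scale})
                traj = ob.integrate(cfg.initial_state, p,
                                    ob.SimulationConfig(dt=0.25, horizon=260, record_every=26))
                prevs.append(traj.prevalence_series(ob.Group.CHILD))
            lo, mid, hi = prevs
            assert np.all(lo <= mid + 1e-12) and np.all(mid <= hi + 1e-12), field
            final[field] = prevs

    def test_conservation_along_default_run(self, baseline_traj):
        sums_a = baseline_traj.states[:, :3].sum(axis=1)
        sums_c = baseline_traj.states[:, 3:].sum(axis=1)
        assert np.max(np.abs(sums_a - 1.0)) < 1e-8
        assert np.max(np.abs(sums_c - 1.0)) < 1e-8


class TestSummaries:
    @pytest.mark.parametrize("state,group,expected", [
        (ob.PopulationState(0.2, 0.4, 0.4, 1.0, 0.0, 0.0), "child", 0.0),
        (ob.PopulationState(0.2, 0.4, 0.4, 0.5, 0.25, 0.25), "child", 50.0),
        (ob.PopulationState(0.2, 0.4, 0.4, 0.34, 0.33, 0.33), "child", 66.0),
        (ob.PopulationState(0.2, 0.4, 0.4, 0.34, 0.33, 0.33), "adult", 80.0),
    ])
    def test_prevalence(self, state, group, expected):
        assert ob.prevalence(state, group) == pytest.approx(expected)

    def test_growth_factor_constant_trajectory_is_one(self):
        initial = ob.PopulationState(0.4, 0.3, 0.3, 0.67, 0.17, 0.16)
        traj = ob.integrate(initial, params(),
                            ob.SimulationConfig(dt=1.0, horizon=10, record_every=1.0))
        assert ob.growth_factor(traj, "child") == pytest.approx(1.0)

    def test_growth_factor_doubling(self):
        times = np.array([0.0, 10.0])
        states = np.array([
            [0.4, 0.3, 0.3, 0.67, 0.17, 0.16],
            [0.4, 0.3, 0.3, 0.34, 0.33, 0.33],
        ])
        traj = ob.Trajectory(times, states)
        assert ob.growth_factor(traj, "child") == pytest.approx(0.66 / 0.33)

    def test_growth_factor_undefined_from_zero(self):
        traj = ob.integrate(ob.PopulationState(0.4, 0.3, 0.3, 1.0, 0.0, 0.0),
                            params(), ob.SimulationConfig(dt=1.0, horizon=5, record_every=1.0))
        with pytest.raises(ValueError, match="initial prevalence"):
            ob.growth_factor(traj, "child")

    def test_trajectory_dataframe_schema(self, baseline_traj):
        df = baseline_traj.to_dataframe()
        assert list(df.columns) == [
            "time_weeks", "n_adult", "ow_adult", "ob_adult",
            "n_child", "ow_child", "ob_child",
            "adult_prevalence_pct", "child_prevalence_pct",
        ]
        assert len(df) == 521


class TestSimulationConfig:
    def test_rejects_horizon_not_multiple_of_dt(self):
        with pytest.raises(ValueError, match="multiple of dt"):
            ob.SimulationConfig(dt=0.3, horizon=1.0)

    def test_rejects_record_every_not_multiple_of_dt(self):
        with pytest.raises(ValueError, match="record_every"):
            ob.SimulationConfig(dt=0.25, horizon=10, record_every=0.3)
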