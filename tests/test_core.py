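"""Unit tests for the shared chemostat core: kinetics, state containers, and
the integration contract."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from crisprdyn import (
    ChemostatEnv,
    IntegrationError,
    PhageParams,
    PhageState,
    StateVector,
    Trajectory,
    simulate_phage,
)
from crisprdyn.analytics import bacterial_equilibrium, resource_equilibrium
from crisprdyn.core import integrate, monod_growth, resource_flux


class TestMonodGrowth:
    def test_zero_resource(self):
        assert monod_growth(1.0, 0.25, 0.0) == 0.0

    def test_half_saturation(self):
        # by definition of the Monod constant, growth is V/2 at R = k
        assert monod_growth(1.0, 0.25, 0.25) == pytest.approx(0.5, rel=1e-12)

    def test_hand_arithmetic(self):
        # 1.0 * 0.0625 / (0.25 + 0.0625) = 0.0625/0.3125 = 0.2
        assert monod_growth(1.0, 0.25, 0.0625) == pytest.approx(0.2, rel=1e-12)

    def test_bounded_by_V(self):
        assert monod_growth(1.3, 0.25, 1e9) < 1.3

    @given(
        st.floats(0.0, 100.0),
        st.floats(0.0, 100.0),
        st.floats(0.1, 5.0),
        st.floats(0.01, 10.0),
    )
    def test_monotone_in_R(self, R1, R2, V, k):
        lo, hi = sorted((R1, R2))
        assert monod_growth(V, k, lo) <= monod_growth(V, k, hi)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            monod_growth(1.0, 0.25, -1.0)
        with pytest.raises(ValueError):
            monod_growth(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            monod_growth(-1.0, 0.25, 1.0)


class TestResourceFlux:
    def test_no_bacteria_at_reservoir(self, env):
        assert resource_flux(env, env.A, []) == 0.0

    def test_no_bacteria_empty_vessel(self, env):
        assert resource_flux(env, 0.0, []) == pytest.approx(
            env.w * env.A, rel=1e-12
        )

    def test_steady_state_balance(self, env):
        # at the single-population equilibrium inflow exactly balances uptake
        R_star = resource_equilibrium(1.0, env.k, env.w)
        N_star = bacterial_equilibrium(env, 1.0)
        psi = monod_growth(1.0, env.k, R_star)
        flux = resource_flux(env, R_star, [(psi, N_star)])
        assert abs(flux) < 1e-12 * env.w * env.A


class TestChemostatEnv:
    def test_defaults(self, env):
        assert (env.A, env.w, env.k, env.e) == (50.0, 0.2, 0.25, 5e-7)

    @pytest.mark.parametrize(
        "kwargs",
        [{"A": 0.0}, {"w": -0.1}, {"k": 0.0}, {"e": -1e-7},
         {"refuge_density": -1.0}, {"phage_extinction_threshold": -1.0}],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            ChemostatEnv(**kwargs)

    def test_adsorbable_density(self, env):
        assert env.adsorbable_density(50.0) == 0.0
        assert env.adsorbable_density(env.refuge_density) == 0.0
        assert env.adsorbable_density(1e4) == pytest.approx(
            1e4 - env.refuge_density
        )


class TestStateVector:
    def test_labels_and_getitem(self):
        s = StateVector(("N", "P"), np.array([1.0, 2.0]), R=3.0, t=4.0)
        assert s["N"] == 1.0 and s["P"] == 2.0 and s["R"] == 3.0

    def test_roundtrip(self):
        s = StateVector(("N", "P"), np.array([1.0, 2.0]), R=3.0)
        s2 = StateVector.from_array(s.labels, s.as_array(), t=1.0)
        assert np.array_equal(s2.as_array(), s.as_array())

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            StateVector(("N",), np.array([-1.0]), R=0.0)
        with pytest.raises(ValueError):
            StateVector(("N",), np.array([1.0]), R=-0.1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            StateVector(("N", "P"), np.array([1.0]), R=0.0)


class TestTrajectory:
    def _traj(self):
        times = np.array([0.0, 1.0, 2.0])
        states = np.array([[1.0, 10.0], [2.0, 10.0], [3.0, 10.0]])
        return Trajectory(("N",), times, states, events=[(1.0, "phage_extinct")])

    def test_columns_and_getitem(self):
        tr = self._traj()
        assert tr.columns == ("N", "R")
        assert np.array_equal(tr["N"], [1.0, 2.0, 3.0])
        assert np.array_equal(tr["R"], [10.0, 10.0, 10.0])

    def test_final(self):
        assert self._traj().final["N"] == 3.0

    def test_event_flags_in_dataframe(self):
        df = self._traj().to_dataframe()
        assert list(df.columns) == ["t", "R", "N", "event_phage_extinct"]
        assert list(df["event_phage_extinct"]) == [0, 1, 1]

    def test_csv_has_header(self, tmp_path):
        path = tmp_path / "ts.csv"
        self._traj().to_csv(path)
        first = path.read_text().splitlines()[0]
        assert first.split(",")[:3] == ["t", "R", "N"]


def _single_population_run(env, t_end=300.0, **kwargs):
    p = PhageParams(mu=0.0, m=0.0)
    return simulate_phage(p, env, PhageState(N=1e6, R=env.A), t_end, **kwargs)


class TestIntegrate:
    def test_single_population_reaches_closed_form(self, env):
        traj = _single_population_run(env)
        N_star = bacterial_equilibrium(env, 1.0)
        assert traj.final["N"] == pytest.approx(N_star, rel=1e-6)
        assert traj.final["R"] == pytest.approx(
            resource_equilibrium(1.0, env.k, env.w), rel=1e-4
        )

    def test_empty_vessel_returns_to_reservoir(self, env):
        # R relaxes to A as A - (A - R0) e^(-w t); by t = 120 hr the
        # deficit is e^(-24) ~ 4e-11 of the initial gap
        p = PhageParams()
        traj = simulate_phage(p, env, PhageState(R=1.0), 120.0)
        assert traj.final["R"] == pytest.approx(env.A, rel=1e-6)

    def test_phage_below_threshold_extinct_at_start(self, env):
        p = PhageParams()
        traj = simulate_phage(
            p, env, PhageState(N=1e6, P=0.05, R=env.A), 10.0
        )
        assert traj.event_times("phage_extinct") == [0.0]
        assert np.all(traj["P"] == 0.0)

    def test_phage_extinction_event_mid_run(self, env):
        # no adsorption: the phage inoculum only washes out and is lost
        p = PhageParams(delta_N=0.0, delta_C=0.0, delta_MAX=0.0,
                        delta_MIN=0.0, mu=0.0, m=0.0)
        traj = simulate_phage(
            p, env, PhageState(N=1e6, P=1e3, R=env.A), 100.0
        )
        t_events = traj.event_times("phage_extinct")
        assert len(t_events) == 1 and t_events[0] > 0.0
        after = traj.times >= t_events[0]
        assert np.all(traj["P"][after] == 0.0)

    def test_times_strictly_increasing_and_initial_preserved(self, env):
        traj = _single_population_run(env, t_end=10.0)
        assert np.all(np.diff(traj.times) > 0)
        assert traj.times[0] == 0.0
        assert traj.states[0][0] == 1e6
        assert traj.states[0][-1] == env.A

    def test_tolerance_refinement(self, env):
        base = _single_population_run(env, t_end=100.0)
        fine = _single_population_run(
            env, t_end=100.0, rtol=5e-9, atol=5e-11
        )
        scale = np.maximum(np.abs(base.states[-1]), 1.0)
        rel = np.max(np.abs(base.states[-1] - fine.states[-1]) / scale)
        assert rel < 1e-3

    def test_solver_modes_agree(self, env):
        lsoda = _single_population_run(env, t_end=100.0, method="lsoda")
        dopri = _single_population_run(env, t_end=100.0, method="dopri5")
        scale = np.maximum(np.abs(lsoda.states[-1]), 1.0)
        rel = np.max(np.abs(lsoda.states[-1] - dopri.states[-1]) / scale)
        assert rel < 5e-3

    def test_resource_balance_at_steady_state(self, env):
        # |w(A - R) - e*sum(psi_i X_i)| < 1e-6 * w * A once converged
        traj = _single_population_run(env)
        fin = traj.final
        psi = monod_growth(1.0, env.k, fin["R"])
        residual = resource_flux(env, fin["R"], [(psi, fin["N"])])
        assert abs(residual) < 1e-6 * env.w * env.A

    def test_washout_when_w_exceeds_all_V(self):
        env = ChemostatEnv(w=1.0)
        p = PhageParams(V_N=0.5, V_NR=0.4, V_C=0.45, V_CR=0.4, mu=0.0)
        t_end = 50.0 / env.w
        traj = simulate_phage(
            p, env,
            PhageState(N=1e6, N_R=1e5, C=1e5, C_R=1e5, R=10.0),
            t_end,
        )
        fin = traj.final
        for lab in ("N", "N_R", "C", "C_R"):
            assert fin[lab] < 0.01 * 1e5
        assert fin["R"] == pytest.approx(env.A, rel=0.01)

    def test_nonnegativity_random_draws(self, env):
        rng = np.random.default_rng(20251002)
        for _ in range(5):
            p = PhageParams(
                V_N=rng.uniform(0.5, 1.5),
                V_C=rng.uniform(0.5, 1.2),
                V_CR=rng.uniform(0.5, 1.1),
                delta_N=10 ** rng.uniform(-10, -8),
                delta_C=10 ** rng.uniform(-10, -8),
                x=rng.uniform(0.0, 1.0),
                m=rng.uniform(0.01, 0.3),
                beta_N=rng.uniform(20, 200),
                beta_C=rng.uniform(20, 200),
                beta_CR=rng.uniform(20, 200),
            )
            traj = simulate_phage(
                p, env,
                PhageState(N=1e7, C=1e6, C_R=1e5, P=1e6, R=env.A),
                60.0,
            )
            assert np.all(traj.states >= 0.0)

    def test_argument_validation(self, env):
        initial = PhageState(N=1e6, R=env.A)
        p = PhageParams()
        with pytest.raises(ValueError):
            simulate_phage(p, env, initial, t_end=0.0)
        with pytest.raises(ValueError):
            simulate_phage(p, env, initial, 10.0, report_dt=-1.0)
        with pytest.raises(ValueError):
            simulate_phage(p, env, initial, 10.0, method="rk4")

    def test_integration_error_carries_partial(self):
        assert issubclass(IntegrationError, RuntimeError)
        err = IntegrationError(
            "boom",
            Trajectory(("N",), np.array([0.0]), np.array([[1.0, 2.0]])),
        )
        assert err.partial.final["N"] == 1.0
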