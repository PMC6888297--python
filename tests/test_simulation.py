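"""Integration, steady states, stability tagging, long-time behaviour."""

import numpy as np
import pytest

from ampktoggle import integrate, standard_protocol, steady_states
from ampktoggle.model import ModelParameters, ModelState
from ampktoggle.simulation import (
    DegenerateModelError,
    Trajectory,
    integrate_to_steady,
    jacobian,
    physiological_steady_state,
)

RATE_FIELDS = (
    "kaA", "kiA", "kiAU", "kiAM", "kamtor", "kiM", "kiMA", "kiMU",
    "kaUA", "kiU", "kiUM", "kaG0", "kaGU", "kiG", "kiGM",
)


class TestIntegrate:
    def test_control_stays_at_rest_for_24_hours(self, params, extended,
                                                rest_state):
        prot = standard_protocol([], [], 1440)
        traj = integrate(prot, params, extended, initial_state=rest_state)
        drift = np.abs(traj.states - rest_state.to_array()).max()
        assert drift < 1e-6

    def test_states_respect_box_bounds(self, params, extended, rest_state):
        prot = standard_protocol(["ampk_hyper"], [], 360)
        traj = integrate(prot, params, extended, initial_state=rest_state)
        assert traj.states.min() >= 0.0
        assert traj.states.max() <= 1.0 + 1e-6

    def test_stage_boundary_is_single_grid_point(self, params, extended,
                                                 rest_state):
        prot = standard_protocol(["rapamycin"], ["si_ulk1"], 150)
        traj = integrate(prot, params, extended, initial_state=rest_state)
        assert np.all(np.diff(traj.times) > 0)
        assert traj.times[0] == 0.0 and traj.times[-1] == 150.0
        assert 30.0 in traj.times

    def test_state_continuous_where_clamp_inactive(self, params, extended,
                                                   rest_state):
        # compound_c changes only a rate constant: no clamp, state smooth
        prot = standard_protocol(["starvation"], ["compound_c"], 90)
        traj = integrate(prot, params, extended, initial_state=rest_state)
        i = int(np.where(traj.times == 30.0)[0][0])
        step = np.abs(traj.states[i] - traj.states[i - 1]).max()
        assert step < 0.02  # one quiet grid-minute, no jump

    def test_clamp_applies_at_onset_for_reduced_totals(self, params,
                                                       extended, rest_state):
        prot = standard_protocol(["rapamycin"], ["si_ulk1"], 150)
        traj = integrate(prot, params, extended, initial_state=rest_state)
        i = int(np.where(traj.times == 30.0)[0][0])
        assert traj.states[i, 1] <= 0.01  # M clamped to the new MT

    def test_tolerance_robustness(self, params, extended, rest_state):
        prot = standard_protocol(["rapamycin"], [], 120)
        a = integrate(prot, params, extended, initial_state=rest_state,
                      rtol=1e-8, atol=1e-10)
        b = integrate(prot, params, extended, initial_state=rest_state,
                      rtol=5e-9, atol=5e-11)
        assert np.abs(a.states[-1] - b.states[-1]).max() < 1e-5

    def test_trajectory_csv_round_trip(self, tmp_path, params, extended,
                                       rest_state):
        prot = standard_protocol(["rapamycin"], [], 60)
        traj = integrate(prot, params, extended, initial_state=rest_state)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        clone = Trajectory.from_csv(path)
        assert np.allclose(clone.states, traj.states)
        assert np.array_equal(clone.times, traj.times)


class TestSteadyStates:
    def test_unique_resting_state_at_physiological_stress(self, params,
                                                          extended):
        found = steady_states(params, extended, n_starts=64, seed=1)
        stable_resting = [
            s for s, ok in found if ok and s.M > 0.5 and s.A < 0.1
        ]
        assert len(stable_resting) == 1
        assert len(found) == 1  # S = 1 is monostable at the defaults

    def test_all_returned_states_are_roots(self, params, extended):
        from ampktoggle.model import rhs_vector

        for st, _ in steady_states(params, extended, n_starts=32, seed=0):
            assert np.max(np.abs(
                rhs_vector(st.to_array(), params, extended)
            )) < 1e-9

    def test_bistable_value_has_two_stable_one_saddle(self, params,
                                                      extended):
        p = params.replace(S=1.4)
        found = steady_states(p, extended, n_starts=64, seed=1)
        stability = sorted(ok for _, ok in found)
        assert stability == [False, True, True]

    def test_degenerate_all_zero_rates_reported(self):
        p = ModelParameters(**{f: 0.0 for f in RATE_FIELDS})
        with pytest.raises(DegenerateModelError):
            steady_states(p)

    def test_n_starts_validated(self, params):
        with pytest.raises(ValueError):
            steady_states(params, n_starts=0)

    def test_physiological_state_has_active_mtor(self, rest_state):
        assert rest_state.M > 0.5
        assert rest_state.A < 0.1
        assert rest_state.U < 0.05 and rest_state.G < 0.05


class TestLongTime:
    def test_random_interior_starts_reach_listed_stable_states(
        self, params, extended, rng
    ):
        found = steady_states(params, extended, n_starts=64, seed=1)
        stable = np.array([s.to_array() for s, ok in found if ok])
        for _ in range(15):
            y0 = rng.random(4)
            y = integrate_to_steady(params, extended, y0)
            dist = np.abs(stable - y).max(axis=1).min()
            assert dist < 1e-4

    def test_jacobian_matches_analytic_sign_structure(self, params,
                                                      extended, rest_state):
        J = jacobian(rest_state.to_array(), params, extended)
        # at rest: mTOR inhibits AMPK (dA/dM < 0), AMPK activates ULK1
        assert J[0, 1] < 0
        assert J[2, 0] > 0
        # every species inactivates itself at rest
        assert np.all(np.diag(J) < 0)
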