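"""Qualitative calls, the scenario suite, variant comparison, orderings."""

import numpy as np
import pytest

from ampktoggle import (
    Thresholds,
    classify,
    compare_variants,
    evaluate_matrix,
    event_ordering,
    integrate,
    scenario_suite,
    standard_protocol,
)
from ampktoggle.perturbations import get_treatment
from ampktoggle.phenotypes import ScenarioSpec, _exp
from ampktoggle.simulation import Trajectory


def flat_trajectory(level, duration=120):
    t = np.arange(0.0, duration + 1)
    return Trajectory(times=t, states=np.full((t.size, 4), level))


class TestClassify:
    def test_all_low_for_zero_trajectory(self):
        call = classify(flat_trajectory(0.0))
        assert all(call[s] == "LOW" for s in "AMUG")

    def test_all_high_at_totals(self):
        call = classify(flat_trajectory(1.0))
        assert all(call[s] == "HIGH" for s in "AMUG")

    def test_boundary_final_exactly_at_theta_high_is_high(self):
        call = classify(flat_trajectory(0.5))
        assert call["A"] == "HIGH"

    def test_transient_requires_high_peak_and_low_final(self):
        t = np.arange(0.0, 121.0)
        x = np.where(t < 40, t / 40.0, np.maximum(1.0 - (t - 40) / 40.0, 0.0))
        states = np.column_stack([x, np.zeros_like(x),
                                  np.zeros_like(x), np.zeros_like(x)])
        call = classify(Trajectory(times=t, states=states))
        assert call["A"] == "TRANSIENT"

    def test_partial_when_final_lands_between_thresholds(self):
        t = np.arange(0.0, 121.0)
        x = np.where(t < 40, t / 40.0, np.maximum(1.0 - (t - 40) / 100.0, 0.35))
        states = np.column_stack([x] + [np.zeros_like(x)] * 3)
        call = classify(Trajectory(times=t, states=states))
        assert call["A"] == "PARTIAL"

    def test_resampling_invariance(self, params, extended, rest_state):
        prot = standard_protocol(["rapamycin"], [], 120)
        fine = integrate(prot, params, extended, initial_state=rest_state,
                         grid_dt=0.5)
        coarse = integrate(prot, params, extended, initial_state=rest_state,
                           grid_dt=1.0)
        assert classify(fine).levels == classify(coarse).levels

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            Thresholds(theta_high=0.2, theta_low=0.3)


class TestSuite:
    def test_suite_covers_more_than_fifteen_mutants(self):
        assert len(scenario_suite()) >= 16

    def test_all_scenario_protocols_resolve(self, params):
        for spec in scenario_suite():
            prot = spec.protocol()
            assert prot.duration > 0
            prot.params_per_stage(params)  # resolves every treatment name

    def test_control_expectation_is_mtor_on_everything_else_off(self):
        control = [s for s in scenario_suite() if s.id == "control"][0]
        assert control.expected["A"] == {"LOW"}
        assert control.expected["M"] == {"HIGH"}
        assert control.expected["U"] == {"LOW"}
        assert control.expected["G"] == {"LOW"}

    def test_scenario_ids_unique(self):
        ids = [s.id for s in scenario_suite()]
        assert len(ids) == len(set(ids))


class TestMatrix:
    def test_extended_variant_matches_every_scenario(self, params, extended):
        report = evaluate_matrix(params=params, variant=extended)
        assert report.total >= 16
        assert report.matched == report.total

    def test_template_variant_fails_on_ampk_in_silencing_scenarios(
        self, params, template
    ):
        report = evaluate_matrix(params=params, variant=template)
        misses = {r["scenario"]: r["diffs"] for r in report.rows
                  if not r["match"]}
        for scenario in ("si_ulk1", "si_tsc12", "mtor_hyper"):
            assert scenario in misses
            assert "A:" in misses[scenario]

    def test_all_wildcard_suite_always_matches(self, params, extended):
        suite = [
            ScenarioSpec("free", [], [], 60.0, _exp()),
            ScenarioSpec("free2", ["rapamycin"], [], 60.0, _exp()),
        ]
        report = evaluate_matrix(suite, params, extended)
        assert report.matched == 2

    def test_score_deterministic(self, params, extended):
        a = evaluate_matrix(params=params, variant=extended)
        b = evaluate_matrix(params=params, variant=extended)
        assert [r["match"] for r in a.rows] == [r["match"] for r in b.rows]
        assert a.matched == b.matched

    def test_empty_suite_rejected(self, params):
        with pytest.raises(ValueError):
            evaluate_matrix([], params)


class TestCompareVariants:
    def test_si_ulk1_contrast_is_the_new_edge_signature(self, params):
        out = compare_variants("si_ulk1", params)
        assert out["extended"]["finals"]["A"] < 0.25
        assert out["template"]["finals"]["A"] > 0.5
        assert out["ampk_final_difference"] > 0.25

    def test_control_contrast_at_shipped_defaults(self, params):
        # extended rests quietly; the template's AMPK-P surges even
        # untreated (its baseline is not stable without the new edge)
        out = compare_variants("control", params)
        assert out["extended"]["levels"]["A"] == "LOW"
        assert out["template"]["peaks"]["A"] >= 0.5

    def test_identical_variants_give_zero_difference(self, params, extended,
                                                     rest_state):
        prot = standard_protocol(["si_ulk1"], [], 360)
        a = integrate(prot, params, extended, initial_state=rest_state)
        b = integrate(prot, params, extended, initial_state=rest_state)
        assert np.array_equal(a.states, b.states)

    def test_unknown_scenario(self, params):
        with pytest.raises(KeyError):
            compare_variants("nonexistent", params)

    @pytest.mark.parametrize(
        "switch",
        ["mtor_inhibits_ampk", "ampk_activates_ulk1", "ulk1_inhibits_ampk",
         "mtor_inhibits_ulk1", "ulk1_inhibits_mtor", "ampk_inhibits_mtor",
         "mtor_inhibits_atg", "ulk1_activates_atg"],
    )
    def test_only_the_mtor_ampk_edge_ablation_releases_ampk_under_si_ulk1(
        self, params, rest_state, switch
    ):
        """Cutting mTOR ┤ AMPK is necessary and sufficient for the AMPK-P
        surge under ULK1 silencing; no other single-edge cut produces it."""
        from ampktoggle.model import ModelVariant

        variant = ModelVariant(**{switch: False})
        prot = standard_protocol(["si_ulk1"], [], 360)
        traj = integrate(prot, params, variant, initial_state=rest_state)
        final_a = traj.series("A")[-1]
        if switch == "mtor_inhibits_ampk":
            assert final_a > 0.5
        else:
            assert final_a < 0.25


class TestEventOrdering:
    def test_rapamycin_mtor_fall_precedes_ampk_then_ulk1(
        self, params, extended, rest_state
    ):
        prot = standard_protocol(["rapamycin"], [], 120)
        traj = integrate(prot, params, extended, initial_state=rest_state)
        ev = event_ordering(traj, baseline=rest_state)
        assert ev.fall["M"] is not None and ev.rise["A"] is not None
        assert ev.rise["U"] is not None
        assert ev.fall["M"] < ev.rise["A"] < ev.rise["U"]
        assert traj.series("G")[-1] >= 0.5

    def test_control_has_no_crossings(self, params, extended, rest_state):
        prot = standard_protocol([], [], 120)
        traj = integrate(prot, params, extended, initial_state=rest_state)
        ev = event_ordering(traj, baseline=rest_state)
        assert ev.rise["A"] is None and ev.rise["U"] is None
        assert ev.fall["M"] is None

    def test_silencing_ulk1_blocks_its_induction_but_not_ampk(
        self, params, extended, rest_state
    ):
        prot = standard_protocol(["rapamycin"], ["si_ulk1"], 150)
        traj = integrate(prot, params, extended, initial_state=rest_state)
        ev = event_ordering(traj, baseline=rest_state)
        assert ev.rise["A"] is not None
        assert ev.rise["U"] is None
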