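"""Engine correctness: decision tree, transitions, traces, comparison.

The key check is an independent oracle: a brute-force enumeration over all
state paths (written from the sequential-risk definition, not the engine)
whose expected occupancy, cost and QALY totals the cohort trace must match
to 1e-9.
"""
import numpy as np
import pytest
from hypothesis import given, settings as hsettings
from hypothesis import strategies as st

from dogcea.model import (
    ARMS,
    ALL_CATEGORIES,
    CeResult,
    ModelState,
    build_transition_row,
    classify_quadrant,
    compare_arms,
    decision_tree_split,
    discount_factor,
    run_trace,
)
from dogcea.params import CostCategory
from conftest import make_ps, profile, random_ps


class TestDiscounting:
    @pytest.mark.parametrize("rate,cycle,expected", [
        (0.03, 0, 1.0),
        (0.0, 7, 1.0),
        (0.03, 2, 1.0 / 1.03**2),
    ])
    def test_values(self, rate, cycle, expected):
        assert discount_factor(rate, cycle) == pytest.approx(expected, abs=1e-9)

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(0.03, -1)


class TestDecisionTree:
    def test_certain_pass(self):
        ps = make_ps(p_minor=1, p_major=1, p_exam=1)
        split = decision_tree_split(ps.transitions)
        assert split[ModelState.CERTIFIED] == 1.0

    def test_product_of_probabilities(self):
        ps = make_ps(p_minor=0.8, p_major=0.75, p_exam=0.9)
        split = decision_tree_split(ps.transitions)
        assert split[ModelState.CERTIFIED] == pytest.approx(0.54)
        assert split[ModelState.NOT_CERTIFIED] == pytest.approx(0.46)

    def test_zero_first_factor(self):
        ps = make_ps(p_minor=0.0, p_major=0.5, p_exam=0.9)
        assert decision_tree_split(ps.transitions)[ModelState.CERTIFIED] == 0.0


class TestTransitionRows:
    def test_absorbing_states(self):
        ps = make_ps()
        for state in (ModelState.OWNER_DEAD, ModelState.DOG_DEAD):
            row = build_transition_row(state, 30, 3, ps.transitions, 10)
            assert row == {state: 1.0}

    def test_sequential_risk_factorisation(self):
        ps = make_ps(q_owner=0.01, q_dog=0.05, p_decert=0.02)
        row = build_transition_row(ModelState.CERTIFIED, 30, 3,
                                   ps.transitions, 10)
        assert row[ModelState.OWNER_DEAD] == pytest.approx(0.01)
        assert row[ModelState.DOG_DEAD] == pytest.approx(0.0495)
        assert row[ModelState.NOT_CERTIFIED] == pytest.approx(0.018810)
        assert row[ModelState.CERTIFIED] == pytest.approx(0.921690)
        assert sum(row.values()) == pytest.approx(1.0, abs=1e-12)

    def test_forced_retirement_at_retirement_age(self):
        ps = make_ps(q_owner=0.01, q_dog=0.05)
        # the dog attains the retirement age in the next cycle
        row = build_transition_row(ModelState.CERTIFIED, 30, 9,
                                   ps.transitions, 10)
        assert ModelState.RETIRED in row
        assert row[ModelState.RETIRED] == pytest.approx(0.99 * 0.95)
        assert ModelState.CERTIFIED not in row

    @given(q_owner=st.floats(0, 1), q_dog=st.floats(0, 1),
           p_decert=st.floats(0, 1),
           state=st.sampled_from(list(ModelState)),
           dog_age=st.integers(2, 12))
    @hsettings(max_examples=200, deadline=None)
    def test_rows_always_sum_to_one(self, q_owner, q_dog, p_decert, state,
                                    dog_age):
        ps = make_ps(q_owner=q_owner, q_dog=q_dog, p_decert=p_decert)
        row = build_transition_row(state, 30, dog_age, ps.transitions, 10)
        assert sum(row.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(0.0 <= p <= 1.0 for p in row.values())


def enumerate_paths(ps, arm):
    """Independent oracle: expectation over explicit state paths.

    Re-derives the model from first principles — year-0 decision split with
    death risks, then sequential conditional risks each cycle — by walking
    every path through the state space with its probability, accruing
    discounted state costs and QALY weights along the way.
    """
    s = ps.settings
    t = ps.transitions
    H = s.horizon_years
    occupancy = np.zeros((H, len(ModelState)))
    costs = np.zeros(H)
    qalys = np.zeros(H)

    def state_cost(state, cycle, cycle0_arm=None):
        if state is ModelState.OWNER_DEAD:
            return 0.0
        prof = {
            ModelState.CERTIFIED: "certified",
            ModelState.RETIRED: "retired_or_decert",
            ModelState.NOT_CERTIFIED: "companion",
            ModelState.DOG_DEAD: "dog_dead",
        }[state]
        if state is ModelState.CERTIFIED and cycle < s.benefit_start_cycle:
            prof = "companion"
        total = sum(ps.profiles[prof].cost_point(c)
                    for c in ALL_CATEGORIES if c is not CostCategory.DOG)
        if state is ModelState.CERTIFIED:
            total += ps.dog_costs.certified.total_for_cycle(cycle)
        elif state in (ModelState.RETIRED, ModelState.NOT_CERTIFIED):
            if cycle == 0 and cycle0_arm == "certified_track":
                total += ps.dog_costs.certified.total_for_cycle(0)
            else:
                total += ps.dog_costs.companion.total_for_cycle(cycle)
        return total

    def state_qaly(state, cycle):
        if state is ModelState.OWNER_DEAD:
            return 0.0
        prof = {
            ModelState.CERTIFIED: "certified",
            ModelState.RETIRED: "retired_or_decert",
            ModelState.NOT_CERTIFIED: "companion",
            ModelState.DOG_DEAD: "dog_dead",
        }[state]
        if state is ModelState.CERTIFIED and cycle < s.benefit_start_cycle:
            prof = "companion"
        return ps.profiles[prof].qaly_weight.point_value

    def successors(state, cycle):
        """[(next_state, prob)] for the transition out of `cycle`."""
        owner_age = s.owner_start_age + cycle
        dog_age = s.dog_start_age + cycle
        if state in (ModelState.OWNER_DEAD, ModelState.DOG_DEAD):
            return [(state, 1.0)]
        q_o = t.owner_mortality[owner_age]
        q_d = t.dog_mortality[dog_age]
        out = [(ModelState.OWNER_DEAD, q_o),
               (ModelState.DOG_DEAD, (1 - q_o) * q_d)]
        live = (1 - q_o) * (1 - q_d)
        if cycle == 0:
            p = (t.p_pass_minor * t.p_pass_major * t.p_pass_exam
                 if arm == "certified_track" else 0.0)
            out += [(ModelState.CERTIFIED, live * p),
                    (ModelState.NOT_CERTIFIED, live * (1 - p))]
        elif state is ModelState.CERTIFIED:
            if dog_age + 1 >= s.dog_retirement_age:
                out.append((ModelState.RETIRED, live))
            else:
                out += [(ModelState.NOT_CERTIFIED, live * t.p_annual_decert),
                        (ModelState.CERTIFIED, live * (1 - t.p_annual_decert))]
        else:
            out.append((state, live))
        return [(n, p) for n, p in out if p > 0]

    def walk(state, cycle, prob):
        occupancy[cycle, state] += prob
        df = (1 + s.discount_rate) ** (-cycle)
        costs[cycle] += prob * df * state_cost(state, cycle, cycle0_arm=arm)
        qalys[cycle] += prob * df * state_qaly(state, cycle)
        if cycle == H - 1:
            return
        for nxt, p in successors(state, cycle):
            walk(nxt, cycle + 1, prob * p)

    walk(ModelState.NOT_CERTIFIED, 0, 1.0)
    return occupancy, costs, qalys


class TestTraceOracle:
    @pytest.mark.parametrize("arm", ARMS)
    @pytest.mark.parametrize("kwargs", [
        dict(horizon=3, q_owner=0.1, q_dog=0.05, p_decert=0.1, discount=0.0),
        dict(horizon=3, q_owner=0.02, q_dog=0.3, p_minor=0.8, p_major=0.75,
             p_exam=0.9, p_decert=0.25, discount=0.03),
        dict(horizon=4, q_owner=0.05, q_dog=0.1, p_decert=0.0, discount=0.05,
             dog_start=8, retire=10),  # retirement inside the horizon
    ])
    def test_trace_matches_path_enumeration(self, arm, kwargs):
        ps = make_ps(**kwargs)
        trace = run_trace(ps, arm)
        occ, costs, qalys = enumerate_paths(ps, arm)
        np.testing.assert_allclose(trace.occupancy, occ, atol=1e-9)
        np.testing.assert_allclose(trace.cycle_costs.sum(axis=1), costs,
                                   atol=1e-9)
        np.testing.assert_allclose(trace.cycle_qalys, qalys, atol=1e-9)


class TestTraceProperties:
    def test_no_exit_scenario_keeps_cohort_certified(self):
        ps = make_ps(horizon=10, q_owner=0.0, q_dog=0.0, p_minor=1, p_major=1,
                     p_exam=1, p_decert=0.0, retire=30)
        trace = run_trace(ps, "certified_track")
        assert np.all(trace.occupancy[1:, ModelState.CERTIFIED] == 1.0)

    def test_undiscounted_companion_qalys_are_weight_times_horizon(
            self, physical_ps):
        from dataclasses import replace

        ps = replace(physical_ps,
                     settings=replace(physical_ps.settings, discount_rate=0.0),
                     transitions=replace(
                         physical_ps.transitions,
                         owner_mortality={a: 0.0 for a in
                                          physical_ps.transitions.owner_mortality},
                         dog_mortality={a: 0.0 for a in
                                        physical_ps.transitions.dog_mortality}))
        trace = run_trace(ps, "companion_track")
        assert trace.total_qalys == pytest.approx(10 * 0.226, abs=1e-9)

    def test_occupancy_conservation_randomised(self):
        rng = np.random.default_rng(20190912)
        for _ in range(150):
            ps = random_ps(rng)
            for arm in ARMS:
                trace = run_trace(ps, arm)
                np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0,
                                           atol=1e-12)
                assert trace.occupancy.min() >= 0.0
                assert trace.occupancy.max() <= 1.0 + 1e-12
                dead = trace.occupancy[:, ModelState.OWNER_DEAD]
                assert np.all(np.diff(dead) >= -1e-15)

    def test_owner_dead_accrues_nothing(self):
        ps = make_ps(horizon=5, q_owner=1.0, q_dog=0.0)
        trace = run_trace(ps, "companion_track")
        # whole cohort dead from cycle 1: no cost, no QALYs
        assert trace.occupancy[1:, ModelState.OWNER_DEAD].min() == 1.0
        assert trace.cycle_costs[1:].sum() == 0.0
        assert trace.cycle_qalys[1:].sum() == 0.0

    def test_discounting_monotone(self, physical_ps):
        from dataclasses import replace

        totals = []
        for rate in (0.0, 0.03, 0.05, 0.10):
            ps = replace(physical_ps,
                         settings=replace(physical_ps.settings,
                                          discount_rate=rate))
            trace = run_trace(ps, "certified_track")
            totals.append((trace.total_cost, trace.total_qalys))
        costs, qalys = zip(*totals)
        assert all(a >= b for a, b in zip(costs, costs[1:]))
        assert all(a >= b for a, b in zip(qalys, qalys[1:]))

    def test_failed_certification_equals_companion_except_tests(self):
        ps = make_ps(horizon=6, p_minor=0.0, p_major=0.0, p_exam=0.0,
                     q_owner=0.05, q_dog=0.1, discount=0.03)
        cert = run_trace(ps, "certified_track")
        comp = run_trace(ps, "companion_track")
        np.testing.assert_allclose(cert.occupancy, comp.occupancy, atol=1e-12)
        np.testing.assert_allclose(cert.cycle_qalys, comp.cycle_qalys,
                                   atol=1e-12)
        # only the year-1 dog-cost difference (the suitability tests) remains
        diff = cert.cycle_costs - comp.cycle_costs
        expected_year1 = (ps.dog_costs.certified.totals["year1"]
                          - ps.dog_costs.companion.totals["year1"])
        assert diff[0].sum() == pytest.approx(expected_year1)
        np.testing.assert_allclose(diff[1:], 0.0, atol=1e-12)


class TestComparison:
    def test_tabulated_dominant_result(self):
        ce = CeResult.from_totals(1_191_121, 1_197_080, 2.79, 2.51)
        assert ce.delta_cost == pytest.approx(-5_959)
        assert ce.delta_qaly == pytest.approx(0.28)
        assert ce.dominance == "dominant"
        assert ce.icer is None
        assert ce.icer_label == "Dominant"

    def test_tradeoff_icer(self):
        ce = CeResult.from_totals(1_000, 0, 0.05, 0.0)
        assert ce.icer == pytest.approx(20_000)
        assert ce.dominance == "tradeoff_ne"

    def test_no_difference(self):
        ce = CeResult.from_totals(10.0, 10.0, 1.0, 1.0)
        assert ce.icer is None
        assert ce.dominance == "no_difference"

    def test_zero_qaly_delta_classified_by_cost(self):
        assert CeResult.from_totals(5.0, 0.0, 1.0, 1.0).dominance == "dominated"
        assert CeResult.from_totals(0.0, 5.0, 1.0, 1.0).dominance == "dominant"

    @given(dc=st.floats(-1e6, 1e6), de=st.floats(-10, 10))
    @hsettings(max_examples=100, deadline=None)
    def test_quadrants_consistent_with_signs(self, dc, de):
        quad = classify_quadrant(dc, de)
        if dc < 0 and de > 0:
            assert quad == "dominant"
        if dc > 0 and de < 0:
            assert quad == "dominated"

    def test_compare_arms_on_fixture(self, physical_ps):
        cert = run_trace(physical_ps, "certified_track")
        comp = run_trace(physical_ps, "companion_track")
        ce = compare_arms(cert, comp)
        assert ce.delta_cost == pytest.approx(cert.total_cost - comp.total_cost)
        assert ce.delta_qaly == pytest.approx(cert.total_qalys - comp.total_qalys)
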