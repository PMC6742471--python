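"""Decision tree + Markov cohort engine and the Model/Results interface.

The model follows a cohort of dog owners for ``horizon_years`` one-year
cycles.  Cycle 0 is a decision-tree year: on the certified track the owner
and dog sit the minor and major suitability tests and the final exam while
still living with (and paying for) an ordinary companion dog; the fraction
passing all three moves into the certified state at cycle 1, the remainder
to the not-certified state.  From cycle 1 the cohort evolves through five
states — certified dog, dog retired, dog not certified, dog dead, owner
dead — under annual owner and dog mortality, forced retirement at the dog's
retirement age, and an annual decertification risk.  Costs and QALYs accrue
per cycle, discounted at the annual rate, with no half-cycle correction.

Competing risks within a cycle are ordered owner death → dog death →
retirement → decertification and applied as sequential conditional risks,
so every transition row sums to one by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .params import (
    STATE_CATEGORIES,
    CostCategory,
    EconomicSettings,
    ParameterSet,
    ParameterError,
    TransitionInputs,
    apply_perspective,
    load_parameter_set,
)

ARMS = ("certified_track", "companion_track")


class ModelState(IntEnum):
    """Markov states; DOG_DEAD and OWNER_DEAD are absorbing."""

    CERTIFIED = 0
    RETIRED = 1
    NOT_CERTIFIED = 2
    DOG_DEAD = 3
    OWNER_DEAD = 4


STATE_NAMES = {
    ModelState.CERTIFIED: "certified_dog",
    ModelState.RETIRED: "dog_retired",
    ModelState.NOT_CERTIFIED: "dog_not_certified",
    ModelState.DOG_DEAD: "dog_dead",
    ModelState.OWNER_DEAD: "owner_dead",
}

#: which cost/QALY profile each live state draws on
_PROFILE_FOR_STATE = {
    ModelState.CERTIFIED: "certified",
    ModelState.RETIRED: "retired_or_decert",
    ModelState.NOT_CERTIFIED: "companion",
    ModelState.DOG_DEAD: "dog_dead",
}

ALL_CATEGORIES = tuple(CostCategory)


def discount_factor(rate: float, cycle_index: int) -> float:
    """Present-value factor ``(1 + rate)^(-cycle)``; cycle 0 is undiscounted."""
    if cycle_index < 0:
        raise ValueError(f"cycle_index must be >= 0, got {cycle_index}")
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    return (1.0 + rate) ** (-cycle_index)


def decision_tree_split(t: TransitionInputs) -> dict[ModelState, float]:
    """Certification outcome of the year-0 decision tree.

    The certified fraction is the product of the minor-test, major-test and
    final-exam pass probabilities; everyone else keeps an uncertified dog.
    """
    p_cert = t.p_pass_minor * t.p_pass_major * t.p_pass_exam
    return {
        ModelState.CERTIFIED: p_cert,
        ModelState.NOT_CERTIFIED: 1.0 - p_cert,
    }


def _mortality(table: Mapping[int, float], age: int, label: str) -> float:
    try:
        return table[age]
    except KeyError:
        raise ParameterError(f"{label} mortality table has no entry for age {age}")


def build_transition_row(
    state: ModelState,
    owner_age: int,
    dog_age: int,
    t: TransitionInputs,
    retirement_age: int,
) -> dict[ModelState, float]:
    """One row of the cycle transition matrix.

    ``owner_age`` and ``dog_age`` are the ages during the cycle being left;
    annual death probabilities are looked up at those ages.  A certified dog
    retires at the transition into the cycle in which it attains
    ``retirement_age`` (i.e. when ``dog_age + 1 >= retirement_age``), so no
    cycle is spent certified at or beyond the retirement age.
    """
    if state in (ModelState.OWNER_DEAD, ModelState.DOG_DEAD):
        return {state: 1.0}
    q_owner = _mortality(t.owner_mortality, owner_age, "owner")
    q_dog = _mortality(t.dog_mortality, dog_age, "dog")
    row = {
        ModelState.OWNER_DEAD: q_owner,
        ModelState.DOG_DEAD: (1.0 - q_owner) * q_dog,
    }
    survive = (1.0 - q_owner) * (1.0 - q_dog)
    if state is ModelState.CERTIFIED:
        if dog_age + 1 >= retirement_age:
            row[ModelState.RETIRED] = survive
        else:
            row[ModelState.NOT_CERTIFIED] = survive * t.p_annual_decert
            row[ModelState.CERTIFIED] = survive * (1.0 - t.p_annual_decert)
    else:  # RETIRED and NOT_CERTIFIED only face the death risks
        row[state] = survive
    return row


@dataclass
class CohortTrace:
    """Cycle-by-state occupancy with discounted cost and QALY accrual."""

    arm: str
    occupancy: np.ndarray  # (horizon, 5) probabilities
    cycle_costs: np.ndarray  # (horizon, 5) discounted USD by CostCategory
    cycle_qalys: np.ndarray  # (horizon,) discounted QALYs

    @property
    def total_cost(self) -> float:
        return float(self.cycle_costs.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.cycle_qalys.sum())

    def cost_by_category(self) -> dict[CostCategory, float]:
        return {
            cat: float(self.cycle_costs[:, i].sum())
            for i, cat in enumerate(ALL_CATEGORIES)
        }

    def to_frame(self) -> pd.DataFrame:
        data = {
            f"occ_{STATE_NAMES[s]}": self.occupancy[:, s] for s in ModelState
        }
        for i, cat in enumerate(ALL_CATEGORIES):
            data[f"cost_{cat.value}"] = self.cycle_costs[:, i]
        data["qalys"] = self.cycle_qalys
        frame = pd.DataFrame(data)
        frame.insert(0, "cycle", np.arange(len(frame)))
        return frame


def _cycles_since_retirement(s: EconomicSettings, cycle: int) -> int:
    """Cycles elapsed since the forced-retirement cycle (0 before it)."""
    retirement_cycle = s.dog_retirement_age - s.dog_start_age
    return max(cycle - retirement_cycle, 0)


def _state_cost_vector(ps: ParameterSet, state: ModelState, cycle: int) -> np.ndarray:
    """Annual (undiscounted) cost by category for one state at one cycle."""
    s = ps.settings
    costs = np.zeros(len(ALL_CATEGORIES))
    if state is ModelState.OWNER_DEAD:
        return costs
    profile_name = _PROFILE_FOR_STATE[state]
    if state is ModelState.CERTIFIED and cycle < s.benefit_start_cycle:
        profile_name = "companion"
    prof = ps.profiles[profile_name]
    mult = 1.0
    if state is ModelState.RETIRED and s.retired_cost_growth != 1.0:
        # exponential trend per cycle since the earliest retirement cycle
        mult = s.retired_cost_growth ** _cycles_since_retirement(s, cycle)
    for i, cat in enumerate(ALL_CATEGORIES):
        if cat is CostCategory.DOG:
            continue
        costs[i] = prof.cost_point(cat) * mult
        if s.include_unrelated_costs:
            costs[i] += ps.unrelated_addon.get(profile_name, {}).get(cat, 0.0)
    # dog upkeep: certified schedule only while certified; a dead dog costs
    # nothing; retired / uncertified dogs cost the same as a companion dog
    dog_idx = ALL_CATEGORIES.index(CostCategory.DOG)
    if state is ModelState.CERTIFIED:
        costs[dog_idx] = ps.dog_costs.certified.total_for_cycle(cycle)
    elif state in (ModelState.RETIRED, ModelState.NOT_CERTIFIED):
        costs[dog_idx] = ps.dog_costs.companion.total_for_cycle(cycle)
    return costs


def _state_qaly_weight(ps: ParameterSet, state: ModelState, cycle: int) -> float:
    s = ps.settings
    if state is ModelState.OWNER_DEAD:
        return 0.0
    profile_name = _PROFILE_FOR_STATE[state]
    if state is ModelState.CERTIFIED and cycle < s.benefit_start_cycle:
        profile_name = "companion"
    w = ps.profiles[profile_name].qaly_weight.point_value
    if state is ModelState.RETIRED and s.retired_qaly_decay != 1.0:
        w *= s.retired_qaly_decay ** _cycles_since_retirement(s, cycle)
    return w


def run_trace(ps: ParameterSet, arm: str) -> CohortTrace:
    """Run one arm of the model and return its cohort trace.

    Cycle 0 is the decision-tree year: the whole cohort lives with an
    ordinary companion dog (companion state costs and QALY weight); the
    certified track additionally pays the suitability-test component of the
    year-1 dog-cost schedule.  The cycle-0 → cycle-1 transition combines the
    death risks with the certification split (certified fraction zero on the
    companion track).
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; choose from {ARMS}")
    s = ps.settings
    t = ps.transitions
    horizon = s.horizon_years
    occupancy = np.zeros((horizon, len(ModelState)))
    cycle_costs = np.zeros((horizon, len(ALL_CATEGORIES)))
    cycle_qalys = np.zeros(horizon)

    occupancy[0, ModelState.NOT_CERTIFIED] = 1.0
    # cycle-0 accrual: companion profile, track-specific year-1 dog cost
    base = _state_cost_vector(ps, ModelState.NOT_CERTIFIED, 0)
    if arm == "certified_track":
        dog_idx = ALL_CATEGORIES.index(CostCategory.DOG)
        base = base.copy()
        base[dog_idx] = ps.dog_costs.certified.total_for_cycle(0)
    cycle_costs[0] = base
    cycle_qalys[0] = _state_qaly_weight(ps, ModelState.NOT_CERTIFIED, 0)

    for cycle in range(1, horizon):
        owner_age = s.owner_start_age + cycle - 1
        dog_age = s.dog_start_age + cycle - 1
        prev = occupancy[cycle - 1]
        nxt = np.zeros(len(ModelState))
        if cycle == 1:
            # decision-tree split combined with year-0 death risks
            q_o = _mortality(t.owner_mortality, owner_age, "owner")
            q_d = _mortality(t.dog_mortality, dog_age, "dog")
            survive = (1.0 - q_o) * (1.0 - q_d)
            split = decision_tree_split(t)
            p_cert = split[ModelState.CERTIFIED] if arm == "certified_track" else 0.0
            nxt[ModelState.OWNER_DEAD] = q_o
            nxt[ModelState.DOG_DEAD] = (1.0 - q_o) * q_d
            nxt[ModelState.CERTIFIED] = survive * p_cert
            nxt[ModelState.NOT_CERTIFIED] = survive * (1.0 - p_cert)
        else:
            for state in ModelState:
                mass = prev[state]
                if mass == 0.0:
                    continue
                row = build_transition_row(
                    state, owner_age, dog_age, t, s.dog_retirement_age
                )
                for dest, p in row.items():
                    nxt[dest] += mass * p
        occupancy[cycle] = nxt

        df = discount_factor(s.discount_rate, cycle)
        for state in ModelState:
            mass = nxt[state]
            if mass == 0.0:
                continue
            cycle_costs[cycle] += (
                mass * df * _state_cost_vector(ps, state, cycle)
            )
            cycle_qalys[cycle] += mass * df * _state_qaly_weight(ps, state, cycle)

    return CohortTrace(
        arm=arm, occupancy=occupancy, cycle_costs=cycle_costs, cycle_qalys=cycle_qalys
    )


# ---------------------------------------------------------------------------
# cost-effectiveness comparison
# ---------------------------------------------------------------------------

DOMINANT = "dominant"
DOMINATED = "dominated"
TRADEOFF_NE = "tradeoff_ne"
TRADEOFF_SW = "tradeoff_sw"
NO_DIFFERENCE = "no_difference"


def classify_quadrant(delta_cost: float, delta_qaly: float) -> str:
    """Cost-effectiveness plane quadrant of an (ΔC, ΔE) pair.

    South-east (cheaper, more effective) is dominant; north-west is
    dominated; the two trade-off quadrants need an ICER and a threshold.
    Zero-QALY differences are classified by cost sign alone.
    """
    if delta_qaly > 0:
        return DOMINANT if delta_cost < 0 else TRADEOFF_NE
    if delta_qaly < 0:
        return DOMINATED if delta_cost > 0 else TRADEOFF_SW
    if delta_cost < 0:
        return DOMINANT
    if delta_cost > 0:
        return DOMINATED
    return NO_DIFFERENCE


@dataclass
class CeResult:
    """Deterministic comparison of the two arms."""

    cost_by_arm: dict[str, float]
    qaly_by_arm: dict[str, float]
    delta_cost: float
    delta_qaly: float
    dominance: str
    icer: float | None

    @property
    def icer_label(self) -> str:
        if self.icer is not None:
            return f"{self.icer:,.0f}"
        if self.dominance == DOMINANT:
            return "Dominant"
        if self.dominance == DOMINATED:
            return "Dominated"
        if self.dominance == NO_DIFFERENCE:
            return "No difference"
        return "Undefined"

    @classmethod
    def from_totals(
        cls,
        cost_certified: float,
        cost_companion: float,
        qaly_certified: float,
        qaly_companion: float,
    ) -> "CeResult":
        delta_cost = cost_certified - cost_companion
        delta_qaly = qaly_certified - qaly_companion
        quadrant = classify_quadrant(delta_cost, delta_qaly)
        # an ICER is only a meaningful ratio in the trade-off quadrants
        icer = (
            delta_cost / delta_qaly
            if quadrant in (TRADEOFF_NE, TRADEOFF_SW)
            else None
        )
        return cls(
            cost_by_arm={
                "certified_track": cost_certified,
                "companion_track": cost_companion,
            },
            qaly_by_arm={
                "certified_track": qaly_certified,
                "companion_track": qaly_companion,
            },
            delta_cost=delta_cost,
            delta_qaly=delta_qaly,
            dominance=quadrant,
            icer=icer,
        )


def compare_arms(cert: CohortTrace, comp: CohortTrace) -> CeResult:
    """Incremental cost-effectiveness of the certified vs companion arm."""
    return CeResult.from_totals(
        cert.total_cost, comp.total_cost, cert.total_qalys, comp.total_qalys
    )


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------


class DecisionModel:
    """Cost-effectiveness model of a certified assistance dog.

    Parameters
    ----------
    params : ParameterSet
        Validated model inputs for one dog type (see
        :func:`dogcea.params.load_example_parameters` for the packaged
        base case).

    ``fit()`` runs both arms deterministically and returns a
    :class:`CEResults`; ``fit_psa()`` and ``fit_scenarios()`` run the
    probabilistic and one-way sensitivity analyses.
    """

    def __init__(self, params: ParameterSet):
        params.validate()
        self.params = params

    @classmethod
    def from_bundle(
        cls, path: str | Path, dog_type: str, perspective: str | None = None
    ) -> "DecisionModel":
        ps = load_parameter_set(path, dog_type)
        if perspective is not None and perspective != ps.settings.perspective:
            ps = apply_perspective(ps, perspective)
        return cls(ps)

    def run_trace(self, arm: str) -> CohortTrace:
        return run_trace(self.params, arm)

    def fit(self) -> "CEResults":
        cert = self.run_trace("certified_track")
        comp = self.run_trace("companion_track")
        return CEResults(self, cert, comp, compare_arms(cert, comp))

    def fit_psa(self, n_draws: int = 10_000, seed: int | None = None):
        from .psa import run_psa

        return run_psa(self.params, n_draws, seed)

    def fit_scenarios(self, specs=None):
        from .dsa import builtin_scenarios, run_dsa

        return run_dsa(self.params, specs if specs is not None else builtin_scenarios())


@dataclass
class CEResults:
    """Deterministic base-case results: traces, totals and the ICER."""

    model: DecisionModel
    trace_certified: CohortTrace
    trace_companion: CohortTrace
    ce: CeResult = field(repr=False)

    @property
    def delta_cost(self) -> float:
        return self.ce.delta_cost

    @property
    def delta_qaly(self) -> float:
        return self.ce.delta_qaly

    def trace(self, arm: str) -> CohortTrace:
        return self.trace_certified if arm == "certified_track" else self.trace_companion

    def cost_decomposition(self) -> pd.DataFrame:
        """Discounted 10-year cost per category per arm plus the difference."""
        cert = self.trace_certified.cost_by_category()
        comp = self.trace_companion.cost_by_category()
        rows = []
        for cat in ALL_CATEGORIES:
            rows.append(
                {
                    "category": cat.value,
                    "certified": cert[cat],
                    "companion": comp[cat],
                    "difference": cert[cat] - comp[cat],
                }
            )
        total = {
            "category": "total",
            "certified": sum(cert.values()),
            "companion": sum(comp.values()),
            "difference": sum(cert.values()) - sum(comp.values()),
        }
        rows.append(total)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        ce = self.ce
        s = self.model.params.settings
        lines = [
            f"Cost-effectiveness summary — {self.model.params.dog_type} "
            f"({s.perspective} perspective, {s.horizon_years}-year horizon, "
            f"{s.discount_rate:.0%} discount)",
            "-" * 78,
            f"{'Arm':<22}{'Cost (USD)':>16}{'QALYs':>10}",
            f"{'Certified dog':<22}{ce.cost_by_arm['certified_track']:>16,.0f}"
            f"{ce.qaly_by_arm['certified_track']:>10.2f}",
            f"{'Companion dog':<22}{ce.cost_by_arm['companion_track']:>16,.0f}"
            f"{ce.qaly_by_arm['companion_track']:>10.2f}",
            "-" * 78,
            f"Incremental cost: {ce.delta_cost:>12,.0f} USD",
            f"Incremental QALYs: {ce.delta_qaly:>10.2f}",
            f"ICER: {ce.icer_label} "
            + ("" if ce.icer is None else "USD per QALY gained"),
        ]
        return "\n".join(lines)
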