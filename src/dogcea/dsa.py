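"""Deterministic one-way sensitivity analysis.

Eleven named scenarios probe the structural assumptions of the model:
discount rates of 0% and 5%, short and long dog life spans (anchored on
cumulative dog mortality of 30% resp. 10% by dog age 11), retirement ages
of 8 and 12, an exponential cost increase / utility decrease while the dog
is retired, inclusion of care unrelated to the certified dog ("all
costs"), purchasing a fully trained dog outright (17,569 USD, no training
year), a narrow health-care payer perspective and a societal perspective
without productivity losses.

Each scenario is a declarative transform of a :class:`ParameterSet`; the
base set is never modified.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import CeResult, compare_arms, run_trace
from .params import (
    DistributionSpec,
    DogCostSchedule,
    DogCostTrack,
    ParameterError,
    ParameterSet,
    apply_perspective,
    clone,
)

logger = logging.getLogger(__name__)

#: dog age by which the cumulative-mortality anchors are expressed
ANCHOR_AGE = 11

#: default exponential trend rates for the retired-dog scenario (per cycle);
#: these rates are modelling assumptions, not study estimates
DEFAULT_RETIRED_COST_GROWTH = 1.05
DEFAULT_RETIRED_QALY_DECAY = 0.95

FULLY_TRAINED_PURCHASE_USD = 17_569.0


@dataclass(frozen=True)
class ScenarioSpec:
    """A named one-way scenario: setting overrides + structural switches.

    ``overrides`` maps dotted settings paths (e.g. ``settings.discount_rate``)
    to values; ``switches`` holds the structural transforms
    (``dog_cum_mortality_at_11``, ``fully_trained_purchase``,
    ``perspective``, ``include_unrelated_costs``, ``retired_trend``).
    """

    scenario_id: int
    name: str
    overrides: Mapping[str, float] = field(default_factory=dict)
    switches: Mapping[str, object] = field(default_factory=dict)


_SETTINGS_OVERRIDES = {
    "settings.discount_rate": "discount_rate",
    "settings.dog_retirement_age": "dog_retirement_age",
    "settings.retired_cost_growth": "retired_cost_growth",
    "settings.retired_qaly_decay": "retired_qaly_decay",
}
_KNOWN_SWITCHES = {
    "dog_cum_mortality_at_11",
    "fully_trained_purchase",
    "perspective",
    "include_unrelated_costs",
    "retired_trend",
}


def builtin_scenarios(
    retired_cost_growth: float = DEFAULT_RETIRED_COST_GROWTH,
    retired_qaly_decay: float = DEFAULT_RETIRED_QALY_DECAY,
) -> list[ScenarioSpec]:
    """The eleven standard one-way scenarios, in reporting order."""
    return [
        ScenarioSpec(1, "Discount rate (cost and QALYs): 0%",
                     overrides={"settings.discount_rate": 0.0}),
        ScenarioSpec(2, "Discount rate (cost and QALYs): 5%",
                     overrides={"settings.discount_rate": 0.05}),
        ScenarioSpec(3, "Short life span of the dog",
                     switches={"dog_cum_mortality_at_11": 0.30}),
        ScenarioSpec(4, "Long life-span of the dog",
                     switches={"dog_cum_mortality_at_11": 0.10}),
        ScenarioSpec(5, "Dog retires at the age of 8",
                     overrides={"settings.dog_retirement_age": 8}),
        ScenarioSpec(6, "Dog retires at the age of 12",
                     overrides={"settings.dog_retirement_age": 12}),
        ScenarioSpec(7, "Cost increase and HRQoL decrease for owners with a "
                        "retired dog",
                     switches={"retired_trend": (retired_cost_growth,
                                                 retired_qaly_decay)}),
        ScenarioSpec(8, "Analysis including related and unrelated costs "
                        "(all costs)",
                     switches={"include_unrelated_costs": True}),
        ScenarioSpec(9, "Purchasing a fully trained dog (17,569 USD)",
                     switches={"fully_trained_purchase":
                               FULLY_TRAINED_PURCHASE_USD}),
        ScenarioSpec(10, "Health-care perspective",
                     switches={"perspective": "healthcare"}),
        ScenarioSpec(11, "Societal perspective without productivity losses",
                     switches={"perspective": "societal_no_productivity"}),
    ]


def calibrate_dog_mortality(
    dog_mortality: Mapping[int, float],
    start_age: int,
    target_cum: float,
    anchor_age: int = ANCHOR_AGE,
    tol: float = 1e-10,
) -> dict[int, float]:
    """Scale annual dog death probabilities to hit a cumulative anchor.

    Finds (by bisection) the single multiplier ``m`` such that
    ``1 - prod(1 - m*q_a)`` over dog ages ``start_age .. anchor_age-1``
    equals ``target_cum``, and returns the scaled table.
    """
    if not (0.0 < target_cum < 1.0):
        raise ParameterError(f"cumulative mortality target {target_cum} not in (0,1)")
    ages = range(start_age, anchor_age)
    base = np.array([dog_mortality[a] for a in ages], dtype=float)
    if np.all(base == 0):
        raise ParameterError("cannot calibrate an all-zero dog mortality table")

    def cum(m: float) -> float:
        return 1.0 - float(np.prod(1.0 - np.clip(m * base, 0.0, 1.0)))

    hi = 1.0
    while cum(hi) < target_cum and hi < 1e9:
        hi *= 2.0
    m = brentq(lambda m: cum(m) - target_cum, 0.0, hi, xtol=tol)
    return {a: float(np.clip(m * q, 0.0, 1.0)) for a, q in dog_mortality.items()}


def _fully_trained_schedule(
    schedule: DogCostSchedule, purchase_total: float
) -> DogCostSchedule:
    """Replace the certified track's start-up years with a turnkey purchase.

    Year 1 becomes the fully trained dog's purchase price plus ordinary
    upkeep; year 2 loses the training and cape costs and reverts to the
    maintenance-year pattern.
    """
    cert = schedule.certified
    upkeep = cert.components["year1"]["annual_upkeep"]
    year1 = {
        "purchase": DistributionSpec.point(purchase_total),
        "annual_upkeep": upkeep,
    }
    components = {
        "year1": year1,
        "year2": dict(cert.components["subsequent"]),
        "subsequent": dict(cert.components["subsequent"]),
    }
    totals = {
        block: sum(s.point_value for s in comps.values())
        for block, comps in components.items()
    }
    new_cert = DogCostTrack(components=components, totals=totals)
    return DogCostSchedule(certified=new_cert, companion=schedule.companion)


def apply_scenario(ps: ParameterSet, spec: ScenarioSpec) -> ParameterSet:
    """Return a new ParameterSet with the scenario's overrides applied."""
    out = clone(ps)
    settings_kwargs = {}
    for path, value in spec.overrides.items():
        if path not in _SETTINGS_OVERRIDES:
            raise ParameterError(f"scenario {spec.scenario_id}: unknown override "
                                 f"path {path!r}")
        settings_kwargs[_SETTINGS_OVERRIDES[path]] = value
    if settings_kwargs:
        out = replace(out, settings=replace(out.settings, **settings_kwargs))

    for switch, value in spec.switches.items():
        if switch not in _KNOWN_SWITCHES:
            raise ParameterError(f"scenario {spec.scenario_id}: unknown switch "
                                 f"{switch!r}")
        if switch == "dog_cum_mortality_at_11":
            scaled = calibrate_dog_mortality(
                out.transitions.dog_mortality,
                out.settings.dog_start_age,
                float(value),
            )
            out = replace(out, transitions=replace(out.transitions,
                                                   dog_mortality=scaled))
        elif switch == "fully_trained_purchase":
            out = replace(out, dog_costs=_fully_trained_schedule(out.dog_costs,
                                                                 float(value)))
        elif switch == "perspective":
            out = apply_perspective(out, str(value))
        elif switch == "include_unrelated_costs":
            out = replace(out, settings=replace(out.settings,
                                                include_unrelated_costs=bool(value)))
        elif switch == "retired_trend":
            g, d = value
            logger.warning(
                "Retired-dog trend rates are assumptions: cost growth %s, "
                "QALY decay %s per cycle", g, d,
            )
            out = replace(out, settings=replace(out.settings,
                                                retired_cost_growth=float(g),
                                                retired_qaly_decay=float(d)))
    out.validate()
    return out


@dataclass
class ScenarioResult:
    scenario_id: int
    name: str
    ce: CeResult

    @property
    def incremental_cost(self) -> float:
        return self.ce.delta_cost

    @property
    def incremental_qaly(self) -> float:
        return self.ce.delta_qaly

    @property
    def icer_label(self) -> str:
        return self.ce.icer_label


@dataclass
class ScenarioResults:
    """Results object for the one-way sensitivity analysis."""

    results: list[ScenarioResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "scenario": r.scenario_id,
                    "name": r.name,
                    "incremental_cost": r.incremental_cost,
                    "incremental_qaly": r.incremental_qaly,
                    "icer": r.icer_label,
                }
                for r in self.results
            ]
        )

    def summary(self) -> str:
        frame = self.to_frame()
        lines = ["One-way sensitivity analysis", "-" * 78]
        for _, row in frame.iterrows():
            lines.append(
                f"{row['scenario']:>2}  {row['name'][:48]:<48}"
                f"{row['incremental_cost']:>10,.0f}  "
                f"{row['incremental_qaly']:>5.2f}  {row['icer']}"
            )
        return "\n".join(lines)


def run_dsa(ps: ParameterSet, specs: list[ScenarioSpec]) -> ScenarioResults:
    """Run the deterministic engine under each scenario, in order."""
    if not specs:
        raise ValueError("run_dsa requires at least one scenario")
    results = []
    for spec in specs:
        scen_ps = apply_scenario(ps, spec)
        cert = run_trace(scen_ps, "certified_track")
        comp = run_trace(scen_ps, "companion_track")
        results.append(ScenarioResult(spec.scenario_id, spec.name,
                                      compare_arms(cert, comp)))
    return ScenarioResults(results=results)
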