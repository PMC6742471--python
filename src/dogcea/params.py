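"""Model inputs for the assistance-dog cost-effectiveness model.

The model compares a certified assistance dog (physical service dog or
diabetes alert dog) against a regular companion dog over a 10-year horizon.
Everything the engine consumes — per-state annual costs and utility (QALY)
weights, the dog-cost schedule, transition probabilities, mortality tables
and economic settings — is collected in a :class:`ParameterSet`, loadable
from a plain-text parameter bundle and shipped as packaged fixtures.

Costs are annual, per owner, in 2017 USD (SEK inputs are converted at the
configured exchange rate).  Utility weights are EQ-5D index values on the
UK tariff scale, which ranges from -0.594 (worse than death) to 1.
"""
from __future__ import annotations

import configparser
import copy
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UK_TARIFF_MIN = -0.594
UK_TARIFF_MAX = 1.0

#: printed yearly dog-cost totals round component sums to the nearest USD,
#: so totals are only guaranteed to match component sums within 1 USD
TOTAL_ROUNDING_TOL = 1.0


class ParameterError(ValueError):
    """A parameter file could not be parsed or violates a model invariant."""


class CostCategory(str, Enum):
    """The five cost categories whose sum is the societal total cost."""

    HEALTHCARE = "healthcare"
    MUNICIPAL = "municipal"
    INFORMAL_CARE = "informal_care"
    PRODUCTIVITY_LOSS = "productivity_loss"
    DOG = "dog"


#: categories carried on state profiles (dog costs follow their own schedule)
STATE_CATEGORIES = (
    CostCategory.HEALTHCARE,
    CostCategory.MUNICIPAL,
    CostCategory.INFORMAL_CARE,
    CostCategory.PRODUCTIVITY_LOSS,
)

DOG_TYPES = ("physical_service", "diabetes_alert")
PERSPECTIVES = ("societal", "healthcare", "societal_no_productivity")
PROFILE_STATES = ("companion", "certified", "retired_or_decert", "dog_dead")


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution and base-case value for one input parameter.

    ``family`` is ``"gamma"`` for costs, ``"beta"`` for utility weights and
    ``"point"`` for parameters that are not sampled in the probabilistic
    sensitivity analysis.  ``alfa``/``beta`` follow the (shape, scale)
    convention for gamma and the standard two-shape convention for beta.
    Base-case runs always use ``point_value``.
    """

    family: str
    point_value: float
    alfa: float | None = None
    beta: float | None = None

    def validate(self, name: str = "parameter") -> None:
        if self.family not in ("gamma", "beta", "point"):
            raise ParameterError(f"{name}: unknown family {self.family!r}")
        if self.family in ("gamma", "beta"):
            if self.alfa is None or self.beta is None:
                raise ParameterError(f"{name}: {self.family} requires alfa and beta")
            if not (self.alfa > 0 and self.beta > 0):
                raise ParameterError(
                    f"{name}: alfa and beta must be positive, got "
                    f"({self.alfa}, {self.beta})"
                )
        if self.family == "gamma" and self.point_value < 0:
            raise ParameterError(f"{name}: gamma point value must be >= 0")
        if self.family == "beta" and not (
            UK_TARIFF_MIN <= self.point_value <= UK_TARIFF_MAX
        ):
            raise ParameterError(
                f"{name}: utility point value {self.point_value} outside "
                f"tariff range [{UK_TARIFF_MIN}, {UK_TARIFF_MAX}]"
            )

    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls(family="point", point_value=float(value))


@dataclass(frozen=True)
class StateProfile:
    """Annual per-category costs and the utility weight of one model state."""

    annual_cost: Mapping[CostCategory, DistributionSpec]
    qaly_weight: DistributionSpec

    def validate(self, name: str = "profile") -> None:
        for cat in STATE_CATEGORIES:
            if cat not in self.annual_cost:
                raise ParameterError(f"{name}: missing cost category {cat.value}")
            self.annual_cost[cat].validate(f"{name}.{cat.value}")
        self.qaly_weight.validate(f"{name}.qaly_weight")
        if not (UK_TARIFF_MIN <= self.qaly_weight.point_value <= UK_TARIFF_MAX):
            raise ParameterError(f"{name}: QALY weight outside tariff range")

    def cost_point(self, cat: CostCategory) -> float:
        return self.annual_cost[cat].point_value


#: components allowed on the certified track only
CERTIFIED_ONLY_COMPONENTS = (
    "suitability_tests",
    "training",
    "capes",
    "maintenance_test",
    "health_declaration",
)
DOG_COST_BLOCKS = ("year1", "year2", "subsequent")


@dataclass(frozen=True)
class DogCostTrack:
    """Dog-cost schedule for one track (certified or companion).

    ``components`` maps block -> component -> DistributionSpec; ``totals``
    carries the yearly totals actually charged by the engine (the printed
    totals, which match component sums within 1 USD of rounding).
    """

    components: Mapping[str, Mapping[str, DistributionSpec]]
    totals: Mapping[str, float]

    def total_for_cycle(self, cycle: int) -> float:
        if cycle == 0:
            return self.totals["year1"]
        if cycle == 1:
            return self.totals["year2"]
        return self.totals["subsequent"]

    def validate(self, name: str, certified: bool) -> None:
        for block in DOG_COST_BLOCKS:
            if block not in self.totals:
                raise ParameterError(f"{name}: missing dog-cost block {block}")
            comp_sum = sum(
                spec.point_value for spec in self.components.get(block, {}).values()
            )
            if abs(comp_sum - self.totals[block]) > TOTAL_ROUNDING_TOL:
                raise ParameterError(
                    f"{name}.{block}: components sum to {comp_sum:.0f} but "
                    f"total is {self.totals[block]:.0f} (tolerance 1 USD)"
                )
            if not certified:
                bad = set(self.components.get(block, {})) & set(
                    CERTIFIED_ONLY_COMPONENTS
                )
                if bad:
                    raise ParameterError(
                        f"{name}.{block}: companion track carries "
                        f"certification components {sorted(bad)}"
                    )


@dataclass(frozen=True)
class DogCostSchedule:
    certified: DogCostTrack
    companion: DogCostTrack

    def validate(self) -> None:
        self.certified.validate("dog_costs.certified", certified=True)
        self.companion.validate("dog_costs.companion", certified=False)

    def track(self, name: str) -> DogCostTrack:
        return self.certified if name == "certified" else self.companion


@dataclass(frozen=True)
class TransitionInputs:
    """Decision-tree pass probabilities, decertification risk and mortality."""

    p_pass_minor: float
    p_pass_major: float
    p_pass_exam: float
    p_annual_decert: float
    owner_mortality: Mapping[int, float]
    dog_mortality: Mapping[int, float]

    def validate(self, settings: "EconomicSettings | None" = None) -> None:
        for attr in ("p_pass_minor", "p_pass_major", "p_pass_exam", "p_annual_decert"):
            p = getattr(self, attr)
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"transitions.{attr}={p} outside [0, 1]")
        for label, table in (
            ("owner_mortality", self.owner_mortality),
            ("dog_mortality", self.dog_mortality),
        ):
            for age, q in table.items():
                if not (0.0 <= q <= 1.0):
                    raise ParameterError(f"{label}[{age}]={q} outside [0, 1]")
        if settings is not None:
            for age in range(
                settings.owner_start_age,
                settings.owner_start_age + settings.horizon_years + 1,
            ):
                if age not in self.owner_mortality:
                    raise ParameterError(f"owner_mortality missing age {age}")
            for age in range(
                settings.dog_start_age, settings.dog_retirement_age + 2
            ):
                if age not in self.dog_mortality:
                    raise ParameterError(f"dog_mortality missing dog age {age}")


@dataclass(frozen=True)
class EconomicSettings:
    """Run settings: horizon, discounting, ages, perspective, PSA options."""

    discount_rate: float = 0.03
    horizon_years: int = 10
    cycle_length: float = 1.0
    owner_start_age: int = 44
    dog_start_age: int = 2
    dog_retirement_age: int = 10
    perspective: str = "societal"
    sek_per_usd: float = 8.538
    threshold_grid: tuple[float, ...] = tuple(np.arange(0.0, 150_000.0 + 1, 2_500.0))
    rng_seed: int = 2019
    psa_anchor: str = "moment_matched"
    benefit_start_cycle: int = 1
    include_unrelated_costs: bool = False
    retired_cost_growth: float = 1.0
    retired_qaly_decay: float = 1.0

    def validate(self) -> None:
        if self.discount_rate < 0:
            raise ParameterError("discount_rate must be >= 0")
        if self.horizon_years < 1:
            raise ParameterError("horizon_years must be >= 1")
        if self.dog_retirement_age <= self.dog_start_age:
            raise ParameterError("dog_retirement_age must exceed dog_start_age")
        if self.perspective not in PERSPECTIVES:
            raise ParameterError(f"unknown perspective {self.perspective!r}")
        if self.psa_anchor not in ("moment_matched", "printed_params"):
            raise ParameterError(f"unknown psa_anchor {self.psa_anchor!r}")
        grid = np.asarray(self.threshold_grid, dtype=float)
        if grid.size and not np.all(np.diff(grid) > 0):
            raise ParameterError("threshold_grid must be strictly increasing")


@dataclass(frozen=True)
class ParameterSet:
    """Complete model input for one dog type."""

    dog_type: str
    profiles: Mapping[str, StateProfile]
    dog_costs: DogCostSchedule
    transitions: TransitionInputs
    settings: EconomicSettings
    unrelated_addon: Mapping[str, Mapping[CostCategory, float]] = field(
        default_factory=dict
    )

    def validate(self) -> None:
        if self.dog_type not in DOG_TYPES:
            raise ParameterError(f"unknown dog_type {self.dog_type!r}")
        for state in PROFILE_STATES:
            if state not in self.profiles:
                raise ParameterError(f"missing state profile {state!r}")
            self.profiles[state].validate(f"profiles.{state}")
        dd, comp = self.profiles["dog_dead"], self.profiles["companion"]
        for cat in STATE_CATEGORIES:
            if dd.cost_point(cat) != comp.cost_point(cat):
                raise ParameterError(
                    "dog_dead profile must equal the companion baseline "
                    f"(category {cat.value} differs)"
                )
        if dd.qaly_weight.point_value != comp.qaly_weight.point_value:
            raise ParameterError("dog_dead QALY weight must equal companion baseline")
        self.dog_costs.validate()
        self.settings.validate()
        self.transitions.validate(self.settings)

    def profile(self, state: str) -> StateProfile:
        return self.profiles[state]


def convert_currency(amount_sek: float, rate: float) -> float:
    """Convert SEK to USD at ``rate`` SEK per USD."""
    if rate <= 0:
        raise ParameterError(f"exchange rate must be positive, got {rate}")
    return amount_sek / rate


def derive_retired_profile(
    companion: StateProfile, certified: StateProfile
) -> StateProfile:
    """Mid-point profile for the retired / lost-certification state.

    Each cost category and the utility weight is the arithmetic mean of the
    companion and certified values; costs are truncated to whole USD (the
    convention used for the tabulated retired-state cells, e.g. a mean of
    4,135.5 is reported as 4,135).
    """
    companion.validate("companion")
    certified.validate("certified")
    costs: dict[CostCategory, DistributionSpec] = {}
    for cat in STATE_CATEGORIES:
        mid = (companion.cost_point(cat) + certified.cost_point(cat)) / 2.0
        costs[cat] = DistributionSpec.point(math.floor(mid))
    q_mid = (
        companion.qaly_weight.point_value + certified.qaly_weight.point_value
    ) / 2.0
    return StateProfile(annual_cost=costs, qaly_weight=DistributionSpec.point(q_mid))


def _zeroed(spec: DistributionSpec) -> DistributionSpec:
    return DistributionSpec.point(0.0)


def apply_perspective(ps: ParameterSet, perspective: str) -> ParameterSet:
    """Return a copy of ``ps`` restricted to the costing perspective.

    * ``societal`` — all five categories (unchanged);
    * ``societal_no_productivity`` — productivity losses zeroed;
    * ``healthcare`` — only health-care and dog (intervention) costs kept.
    """
    if perspective not in PERSPECTIVES:
        raise ParameterError(f"unknown perspective {perspective!r}")
    if perspective == "societal":
        dropped: tuple[CostCategory, ...] = ()
    elif perspective == "societal_no_productivity":
        dropped = (CostCategory.PRODUCTIVITY_LOSS,)
    else:  # healthcare payer view keeps healthcare + intervention (dog) costs
        dropped = (
            CostCategory.MUNICIPAL,
            CostCategory.INFORMAL_CARE,
            CostCategory.PRODUCTIVITY_LOSS,
        )
    profiles = {}
    for state, prof in ps.profiles.items():
        costs = {
            cat: (_zeroed(spec) if cat in dropped else spec)
            for cat, spec in prof.annual_cost.items()
        }
        profiles[state] = StateProfile(annual_cost=costs, qaly_weight=prof.qaly_weight)
    addon = {
        state: {cat: (0.0 if cat in dropped else v) for cat, v in cats.items()}
        for state, cats in ps.unrelated_addon.items()
    }
    return replace(
        ps,
        profiles=profiles,
        unrelated_addon=addon,
        settings=replace(ps.settings, perspective=perspective),
    )


# ---------------------------------------------------------------------------
# bundle IO
# ---------------------------------------------------------------------------

_COST_ROWS = (
    "healthcare",
    "municipal",
    "informal_care",
    "productivity_loss",
    "qaly_weight",
)


def _read_spec(row: pd.Series, col: str, family: str, name: str) -> DistributionSpec:
    value = row[col]
    if pd.isna(value):
        raise ParameterError(f"{name}: missing value in column {col!r}")
    alfa, beta = row.get(f"alfa_{col}"), row.get(f"beta_{col}")
    if pd.isna(alfa) or pd.isna(beta):
        return DistributionSpec.point(float(value))
    spec = DistributionSpec(
        family=family, point_value=float(value), alfa=float(alfa), beta=float(beta)
    )
    spec.validate(name)
    return spec


def _read_cost_table(path: Path) -> dict[str, StateProfile]:
    try:
        table = pd.read_csv(path).set_index("category")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParameterError(f"could not parse {path.name}: {exc}") from exc
    missing = [r for r in _COST_ROWS if r not in table.index]
    if missing:
        raise ParameterError(f"{path.name}: missing rows {missing}")
    profiles: dict[str, StateProfile] = {}
    has_retired = (
        "retired" in table.columns
        and not table.loc[list(_COST_ROWS), "retired"].isna().all()
    )
    for state, col in (
        ("companion", "companion"),
        ("certified", "certified"),
        ("retired_or_decert", "retired"),
    ):
        if state == "retired_or_decert" and not has_retired:
            continue
        costs = {}
        for cat in STATE_CATEGORIES:
            row = table.loc[cat.value]
            costs[cat] = _read_spec(row, col, "gamma", f"{path.name}:{cat.value}")
        qrow = table.loc["qaly_weight"]
        qaly = _read_spec(qrow, col, "beta", f"{path.name}:qaly_weight")
        profiles[state] = StateProfile(annual_cost=costs, qaly_weight=qaly)
    if "retired_or_decert" not in profiles:
        profiles["retired_or_decert"] = derive_retired_profile(
            profiles["companion"], profiles["certified"]
        )
    profiles["dog_dead"] = profiles["companion"]
    return profiles


def _read_dog_costs(path: Path) -> DogCostSchedule:
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise ParameterError(f"could not parse {path.name}: {exc}") from exc
    tracks: dict[str, DogCostTrack] = {}
    for track_name, sub in table.groupby("track"):
        components: dict[str, dict[str, DistributionSpec]] = {}
        totals: dict[str, float] = {}
        for _, row in sub.iterrows():
            block, comp = row["block"], row["component"]
            if block not in DOG_COST_BLOCKS:
                raise ParameterError(f"{path.name}: unknown block {block!r}")
            if comp == "total":
                totals[block] = float(row["value"])
                continue
            if pd.isna(row.get("alfa")) or pd.isna(row.get("beta")):
                spec = DistributionSpec.point(float(row["value"]))
            else:
                spec = DistributionSpec(
                    family="gamma",
                    point_value=float(row["value"]),
                    alfa=float(row["alfa"]),
                    beta=float(row["beta"]),
                )
            components.setdefault(block, {})[comp] = spec
        tracks[str(track_name)] = DogCostTrack(components=components, totals=totals)
    for needed in ("certified", "companion"):
        if needed not in tracks:
            raise ParameterError(f"{path.name}: missing track {needed!r}")
    return DogCostSchedule(certified=tracks["certified"], companion=tracks["companion"])


def _read_lifetable(path: Path, age_col: str) -> dict[int, float]:
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise ParameterError(f"could not parse {path.name}: {exc}") from exc
    if age_col not in table.columns or "q_annual" not in table.columns:
        raise ParameterError(f"{path.name}: expected columns {age_col}, q_annual")
    return {int(a): float(q) for a, q in zip(table[age_col], table["q_annual"])}


_SETTING_PARSERS = {
    "discount_rate": float,
    "horizon_years": int,
    "owner_start_age": int,
    "dog_start_age": int,
    "dog_retirement_age": int,
    "perspective": str,
    "sek_per_usd": float,
    "rng_seed": int,
    "psa_anchor": str,
    "benefit_start_cycle": int,
    "include_unrelated_costs": lambda s: s.strip().lower() in ("1", "true", "yes"),
    "retired_cost_growth": float,
    "retired_qaly_decay": float,
    "cycle_length": float,
}

_ASSUMED_TRANSITIONS = ("p_pass_minor", "p_pass_major", "p_pass_exam", "p_annual_decert")


def _read_cfg(path: Path, section: str) -> dict[str, str]:
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read or section not in parser:
        raise ParameterError(f"{path.name}: missing [{section}] section")
    return dict(parser[section])


def load_parameter_set(path: str | Path, dog_type: str) -> ParameterSet:
    """Load and validate a parameter bundle directory for one dog type.

    The bundle contains ``costs_<dogtype>.csv``, ``dog_costs.csv``,
    ``transitions.cfg``, ``settings.cfg``, ``owner_lifetable.csv``,
    ``dog_lifetable.csv`` and optionally ``unrelated_costs.csv``.
    """
    path = Path(path)
    if dog_type not in DOG_TYPES:
        raise ParameterError(f"unknown dog_type {dog_type!r}; choose from {DOG_TYPES}")
    profiles = _read_cost_table(path / f"costs_{dog_type}.csv")
    dog_costs = _read_dog_costs(path / "dog_costs.csv")

    raw_settings = _read_cfg(path / "settings.cfg", "settings")
    kwargs = {}
    for key, value in raw_settings.items():
        if key in ("threshold_max", "threshold_step"):
            continue
        if key not in _SETTING_PARSERS:
            raise ParameterError(f"settings.cfg: unknown key {key!r}")
        kwargs[key] = _SETTING_PARSERS[key](value)
    if "threshold_max" in raw_settings:
        step = float(raw_settings.get("threshold_step", 2500))
        kwargs["threshold_grid"] = tuple(
            np.arange(0.0, float(raw_settings["threshold_max"]) + 1, step)
        )
    settings = EconomicSettings(**kwargs)

    raw_trans = _read_cfg(path / "transitions.cfg", "transitions")
    tkwargs = {}
    for key in _ASSUMED_TRANSITIONS:
        if key not in raw_trans:
            raise ParameterError(f"transitions.cfg: missing key {key!r}")
        tkwargs[key] = float(raw_trans[key])
    logger.warning(
        "Test-pass/decertification probabilities are assumptions, not study "
        "estimates: minor=%(p_pass_minor)s major=%(p_pass_major)s "
        "exam=%(p_pass_exam)s annual_decert=%(p_annual_decert)s",
        tkwargs,
    )
    transitions = TransitionInputs(
        owner_mortality=_read_lifetable(path / "owner_lifetable.csv", "age"),
        dog_mortality=_read_lifetable(path / "dog_lifetable.csv", "dog_age"),
        **tkwargs,
    )

    addon: dict[str, dict[CostCategory, float]] = {}
    addon_path = path / "unrelated_costs.csv"
    if addon_path.exists():
        table = pd.read_csv(addon_path)
        for _, row in table.iterrows():
            addon.setdefault(str(row["state"]), {})[
                CostCategory(row["category"])
            ] = float(row["annual_value"])

    ps = ParameterSet(
        dog_type=dog_type,
        profiles=profiles,
        dog_costs=dog_costs,
        transitions=transitions,
        settings=settings,
        unrelated_addon=addon,
    )
    ps.validate()
    return ps


def write_parameter_set(ps: ParameterSet, path: str | Path) -> Path:
    """Write ``ps`` as a parameter bundle directory (inverse of load)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for cat in list(STATE_CATEGORIES) + ["qaly_weight"]:
        row: dict[str, object] = {
            "category": cat.value if isinstance(cat, CostCategory) else cat
        }
        for state, col in (
            ("companion", "companion"),
            ("certified", "certified"),
            ("retired_or_decert", "retired"),
        ):
            prof = ps.profiles[state]
            spec = (
                prof.qaly_weight
                if cat == "qaly_weight"
                else prof.annual_cost[cat]  # type: ignore[index]
            )
            row[col] = spec.point_value
            row[f"alfa_{col}"] = spec.alfa
            row[f"beta_{col}"] = spec.beta
        rows.append(row)
    pd.DataFrame(rows).to_csv(path / f"costs_{ps.dog_type}.csv", index=False)

    drows = []
    for track_name in ("companion", "certified"):
        track = ps.dog_costs.track(track_name)
        for block in DOG_COST_BLOCKS:
            for comp, spec in track.components.get(block, {}).items():
                drows.append(
                    {
                        "track": track_name,
                        "block": block,
                        "component": comp,
                        "value": spec.point_value,
                        "alfa": spec.alfa,
                        "beta": spec.beta,
                    }
                )
            drows.append(
                {
                    "track": track_name,
                    "block": block,
                    "component": "total",
                    "value": track.totals[block],
                    "alfa": None,
                    "beta": None,
                }
            )
    pd.DataFrame(drows).to_csv(path / "dog_costs.csv", index=False)

    s = ps.settings
    parser = configparser.ConfigParser()
    parser["settings"] = {
        "discount_rate": repr(s.discount_rate),
        "horizon_years": str(s.horizon_years),
        "owner_start_age": str(s.owner_start_age),
        "dog_start_age": str(s.dog_start_age),
        "dog_retirement_age": str(s.dog_retirement_age),
        "perspective": s.perspective,
        "sek_per_usd": repr(s.sek_per_usd),
        "rng_seed": str(s.rng_seed),
        "psa_anchor": s.psa_anchor,
        "benefit_start_cycle": str(s.benefit_start_cycle),
        "include_unrelated_costs": str(s.include_unrelated_costs).lower(),
        "retired_cost_growth": repr(s.retired_cost_growth),
        "retired_qaly_decay": repr(s.retired_qaly_decay),
        "threshold_max": repr(float(max(s.threshold_grid))),
        "threshold_step": repr(float(s.threshold_grid[1] - s.threshold_grid[0]))
        if len(s.threshold_grid) > 1
        else "2500",
    }
    with open(path / "settings.cfg", "w") as fh:
        parser.write(fh)

    t = ps.transitions
    parser = configparser.ConfigParser()
    parser["transitions"] = {k: repr(getattr(t, k)) for k in _ASSUMED_TRANSITIONS}
    with open(path / "transitions.cfg", "w") as fh:
        parser.write(fh)

    pd.DataFrame(
        sorted(t.owner_mortality.items()), columns=["age", "q_annual"]
    ).to_csv(path / "owner_lifetable.csv", index=False)
    pd.DataFrame(
        sorted(t.dog_mortality.items()), columns=["dog_age", "q_annual"]
    ).to_csv(path / "dog_lifetable.csv", index=False)

    if ps.unrelated_addon:
        arows = [
            {"state": state, "category": cat.value, "annual_value": v}
            for state, cats in ps.unrelated_addon.items()
            for cat, v in cats.items()
        ]
        pd.DataFrame(arows).to_csv(path / "unrelated_costs.csv", index=False)
    return path


def fixture_bundle_path() -> Path:
    """Path of the packaged base-case parameter bundle."""
    return Path(__file__).parent / "fixtures" / "base_case"


def load_example_parameters(dog_type: str = "physical_service") -> ParameterSet:
    """Load the packaged base-case parameter set for ``dog_type``."""
    return load_parameter_set(fixture_bundle_path(), dog_type)


def load_reference_headline() -> pd.DataFrame:
    """Reference base-case per-arm totals (10-year discounted cost and QALYs)."""
    return pd.read_csv(
        Path(__file__).parent / "fixtures" / "reference_results" / "headline.csv"
    )


def load_reference_breakdown() -> pd.DataFrame:
    """Reference 10-year cost decomposition by category and arm."""
    return pd.read_csv(
        Path(__file__).parent / "fixtures" / "reference_results" / "cost_breakdown.csv"
    )


def clone(ps: ParameterSet) -> ParameterSet:
    """Deep copy of a parameter set (scenario transforms mutate copies)."""
    return copy.deepcopy(ps)
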