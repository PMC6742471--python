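import numpy as np
import pytest

from dogcea.params import (
    STATE_CATEGORIES,
    CostCategory,
    DistributionSpec,
    DogCostSchedule,
    DogCostTrack,
    EconomicSettings,
    ParameterSet,
    StateProfile,
    derive_retired_profile,
    load_example_parameters,
    TransitionInputs,
)


@pytest.fixture(scope="session")
def physical_ps():
    return load_example_parameters("physical_service")


@pytest.fixture(scope="session")
def diabetes_ps():
    return load_example_parameters("diabetes_alert")


def profile(healthcare=0.0, municipal=0.0, informal=0.0, productivity=0.0,
            qaly=0.5):
    return StateProfile(
        annual_cost={
            CostCategory.HEALTHCARE: DistributionSpec.point(healthcare),
            CostCategory.MUNICIPAL: DistributionSpec.point(municipal),
            CostCategory.INFORMAL_CARE: DistributionSpec.point(informal),
            CostCategory.PRODUCTIVITY_LOSS: DistributionSpec.point(productivity),
        },
        qaly_weight=DistributionSpec.point(qaly),
    )


def simple_dog_costs(companion=(200.0, 100.0, 100.0),
                     certified=(250.0, 300.0, 150.0)):
    def track(totals, cert):
        comps = {}
        y1, y2, sub = totals
        comps["year1"] = {"purchase": DistributionSpec.point(y1 - 100),
                          "annual_upkeep": DistributionSpec.point(100.0)}
        if cert:
            comps["year2"] = {"annual_upkeep": DistributionSpec.point(100.0),
                              "training": DistributionSpec.point(y2 - 100)}
            comps["subsequent"] = {"annual_upkeep": DistributionSpec.point(100.0),
                                   "maintenance_test":
                                       DistributionSpec.point(sub - 100)}
        else:
            comps["year2"] = {"annual_upkeep": DistributionSpec.point(y2)}
            comps["subsequent"] = {"annual_upkeep": DistributionSpec.point(sub)}
        return DogCostTrack(components=comps,
                            totals={"year1": y1, "year2": y2, "subsequent": sub})

    return DogCostSchedule(certified=track(certified, True),
                           companion=track(companion, False))


def make_ps(
    horizon=3,
    q_owner=0.1,
    q_dog=0.05,
    p_minor=1.0,
    p_major=1.0,
    p_exam=1.0,
    p_decert=0.1,
    discount=0.0,
    owner_start=30,
    dog_start=2,
    retire=10,
    companion_profile=None,
    certified_profile=None,
    dog_costs=None,
    **settings_kwargs,
):
    """Small fully synthetic parameter set for engine tests."""
    companion_profile = companion_profile or profile(healthcare=1000.0, qaly=0.5)
    certified_profile = certified_profile or profile(healthcare=800.0, qaly=0.7)
    retired = derive_retired_profile(companion_profile, certified_profile)
    settings = EconomicSettings(
        discount_rate=discount,
        horizon_years=horizon,
        owner_start_age=owner_start,
        dog_start_age=dog_start,
        dog_retirement_age=retire,
        **settings_kwargs,
    )
    transitions = TransitionInputs(
        p_pass_minor=p_minor,
        p_pass_major=p_major,
        p_pass_exam=p_exam,
        p_annual_decert=p_decert,
        owner_mortality={a: q_owner for a in range(owner_start,
                                                   owner_start + horizon + 2)},
        dog_mortality={a: q_dog
                       for a in range(dog_start,
                                      max(retire + 3, dog_start + horizon + 2))},
    )
    ps = ParameterSet(
        dog_type="physical_service",
        profiles={
            "companion": companion_profile,
            "certified": certified_profile,
            "retired_or_decert": retired,
            "dog_dead": companion_profile,
        },
        dog_costs=dog_costs or simple_dog_costs(),
        transitions=transitions,
        settings=settings,
    )
    ps.validate()
    return ps


def random_ps(rng: np.random.Generator):
    """Randomised valid parameter set for property tests."""
    horizon = int(rng.integers(2, 12))
    comp = profile(healthcare=float(rng.uniform(0, 5000)),
                   municipal=float(rng.uniform(0, 5000)),
                   qaly=float(rng.uniform(0.05, 0.95)))
    cert = profile(healthcare=float(rng.uniform(0, 5000)),
                   informal=float(rng.uniform(0, 5000)),
                   qaly=float(rng.uniform(0.05, 0.95)))
    return make_ps(
        horizon=horizon,
        q_owner=float(rng.uniform(0, 1)),
        q_dog=float(rng.uniform(0, 1)),
        p_minor=float(rng.uniform(0, 1)),
        p_major=float(rng.uniform(0, 1)),
        p_exam=float(rng.uniform(0, 1)),
        p_decert=float(rng.uniform(0, 1)),
        discount=float(rng.uniform(0, 0.1)),
        retire=int(rng.integers(4, 14)),
        companion_profile=comp,
        certified_profile=cert,
    )
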