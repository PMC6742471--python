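"""Probabilistic sensitivity analysis (PSA).

Each draw resamples every cost parameter from its gamma distribution and
every utility weight from its beta distribution, reruns both arms of the
deterministic engine, and records the incremental cost and QALY pair.  The
cloud of draws is summarised on the cost-effectiveness plane and as a
cost-effectiveness acceptability curve (CEAC): the probability, at each
willingness-to-pay threshold λ, that the net monetary benefit
λ·ΔE − ΔC of the certified dog is positive.

Anchoring.  The tabulated (alfa, beta) pairs are mutually inconsistent with
the tabulated means under either gamma convention, so by default each
distribution is rescaled to keep its printed shape but have mean equal to
the base-case point value (``psa_anchor = "moment_matched"``); set
``psa_anchor = "printed_params"`` to sample the raw printed distributions.

Draw order is parameter-major and fixed (documented in
:func:`sample_parameter_set`), so a seed fully determines a run.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import (
    DOMINANT,
    DOMINATED,
    TRADEOFF_NE,
    TRADEOFF_SW,
    classify_quadrant,
    compare_arms,
    run_trace,
)
from .params import (
    DOG_COST_BLOCKS,
    STATE_CATEGORIES,
    DistributionSpec,
    DogCostSchedule,
    DogCostTrack,
    ParameterError,
    ParameterSet,
    StateProfile,
)

#: states sampled, in draw order; dog_dead shares the companion draw
_SAMPLED_STATES = ("companion", "certified", "retired_or_decert")


def _draw_spec(
    spec: DistributionSpec, rng: np.random.Generator, anchor: str, name: str
) -> float:
    """One Monte-Carlo draw from a parameter's distribution."""
    if spec.family == "point":
        return spec.point_value
    spec.validate(name)
    if spec.family == "gamma":
        shape = spec.alfa
        scale = spec.beta
        if anchor == "moment_matched":
            # keep the printed shape (hence CV), centre the mean on the base case
            scale = spec.point_value / shape if shape > 0 else 0.0
        return float(rng.gamma(shape, scale))
    # beta
    a, b = spec.alfa, spec.beta
    if anchor == "moment_matched":
        m = spec.point_value
        if not (0.0 < m < 1.0):
            raise ParameterError(
                f"{name}: moment-matched beta needs mean in (0, 1), got {m}"
            )
        b = a * (1.0 - m) / m
    return float(rng.beta(a, b))


def _sample_profile(
    prof: StateProfile, rng: np.random.Generator, anchor: str, label: str
) -> StateProfile:
    costs = {}
    for cat in STATE_CATEGORIES:
        draw = _draw_spec(prof.annual_cost[cat], rng, anchor, f"{label}.{cat.value}")
        costs[cat] = replace(prof.annual_cost[cat], point_value=draw)
    qdraw = _draw_spec(prof.qaly_weight, rng, anchor, f"{label}.qaly_weight")
    return StateProfile(
        annual_cost=costs, qaly_weight=replace(prof.qaly_weight, point_value=qdraw)
    )


def _sample_dog_costs(
    schedule: DogCostSchedule, rng: np.random.Generator, anchor: str
) -> DogCostSchedule:
    # each distinct dog-cost component (purchase, annual upkeep, ...) is drawn
    # once per PSA iteration and shared across tracks and years when its spec
    # is identical; block totals are recomputed from the sampled components
    shared: dict[tuple, float] = {}
    tracks = {}
    for track_name in ("companion", "certified"):  # fixed draw order
        track = schedule.track(track_name)
        components: dict[str, dict[str, DistributionSpec]] = {}
        totals: dict[str, float] = {}
        for block in DOG_COST_BLOCKS:
            comps = {}
            for comp, spec in track.components.get(block, {}).items():
                key = (comp, spec.family, spec.alfa, spec.beta, spec.point_value)
                if key not in shared:
                    shared[key] = _draw_spec(spec, rng, anchor, f"dog_costs.{comp}")
                comps[comp] = replace(spec, point_value=shared[key])
            components[block] = comps
            totals[block] = sum(s.point_value for s in comps.values())
        tracks[track_name] = DogCostTrack(components=components, totals=totals)
    return DogCostSchedule(certified=tracks["certified"], companion=tracks["companion"])


def sample_parameter_set(
    ps: ParameterSet, rng: np.random.Generator
) -> ParameterSet:
    """Resample one PSA iterate of ``ps`` from a shared random stream.

    Draw order (parameter-major, fixed): for each of the companion,
    certified and retired profiles — the four cost categories then the
    utility weight — followed by the distinct dog-cost components
    (companion track first).  The dog-dead profile reuses the companion
    draw, preserving the baseline-reversion invariant.
    """
    anchor = ps.settings.psa_anchor
    profiles = {}
    for state in _SAMPLED_STATES:
        profiles[state] = _sample_profile(ps.profiles[state], rng, anchor, state)
    profiles["dog_dead"] = profiles["companion"]
    dog_costs = _sample_dog_costs(ps.dog_costs, rng, anchor)
    return replace(ps, profiles=profiles, dog_costs=dog_costs)


def compute_ceac(
    delta_cost: np.ndarray, delta_qaly: np.ndarray, thresholds
) -> dict[float, float]:
    """Probability of positive net monetary benefit at each threshold.

    A draw counts as cost-effective at λ when λ·ΔE − ΔC > 0 (ties count as
    not cost-effective).
    """
    delta_cost = np.asarray(delta_cost, dtype=float)
    delta_qaly = np.asarray(delta_qaly, dtype=float)
    if delta_cost.size == 0:
        raise ValueError("compute_ceac requires at least one draw")
    out = {}
    for lam in thresholds:
        nmb = lam * delta_qaly - delta_cost
        out[float(lam)] = float(np.mean(nmb > 0))
    return out


@dataclass
class PSAResults:
    """Monte-Carlo uncertainty summary of the incremental results."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int | None
    n_draws: int
    ceac: dict[float, float]
    p_cost_saving: float
    p_qaly_gain: float

    def quadrant_proportions(self) -> dict[str, float]:
        labels = [
            classify_quadrant(c, e) for c, e in zip(self.delta_cost, self.delta_qaly)
        ]
        out = {q: 0.0 for q in (DOMINANT, TRADEOFF_NE, DOMINATED, TRADEOFF_SW)}
        for lab in labels:
            out[lab] = out.get(lab, 0.0) + 1.0
        return {k: v / self.n_draws for k, v in out.items()}

    def ce_plane_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw_index": np.arange(self.n_draws),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
            }
        )

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": list(self.ceac), "probability": list(self.ceac.values())}
        )

    def summary(self) -> str:
        quads = self.quadrant_proportions()
        lines = [
            f"Probabilistic sensitivity analysis ({self.n_draws:,} draws, "
            f"seed={self.seed})",
            "-" * 70,
            f"P(cost saving)          : {self.p_cost_saving:.3f}",
            f"P(QALY gain)            : {self.p_qaly_gain:.3f}",
            f"Mean incremental cost   : {float(np.mean(self.delta_cost)):,.0f} USD",
            f"Mean incremental QALYs  : {float(np.mean(self.delta_qaly)):.3f}",
            "CE-plane quadrants: "
            + ", ".join(f"{k}={v:.3f}" for k, v in quads.items()),
        ]
        return "\n".join(lines)

    def plot_ce_plane(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.delta_qaly, self.delta_cost, s=4, alpha=0.3)
        ax.axhline(0, color="k", lw=0.8)
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("Incremental QALYs")
        ax.set_ylabel("Incremental cost (USD)")
        ax.set_title("Cost-effectiveness plane")
        return ax

    def plot_ceac(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.ceac_frame()
        ax.plot(frame["threshold"], frame["probability"])
        ax.set_ylim(0, 1)
        ax.set_xlabel("Willingness to pay (USD per QALY)")
        ax.set_ylabel("P(cost effective)")
        ax.set_title("Cost-effectiveness acceptability curve")
        return ax


def run_psa(ps: ParameterSet, n: int, seed: int | None = None) -> PSAResults:
    """Run ``n`` PSA iterations of both arms and summarise them."""
    if n < 1:
        raise ValueError("PSA needs n >= 1 draws")
    if seed is None:
        seed = ps.settings.rng_seed
    rng = np.random.default_rng(seed)
    delta_cost = np.empty(n)
    delta_qaly = np.empty(n)
    for i in range(n):
        try:
            drawn = sample_parameter_set(ps, rng)
            cert = run_trace(drawn, "certified_track")
            comp = run_trace(drawn, "companion_track")
        except Exception as exc:
            raise RuntimeError(f"PSA draw {i} failed: {exc}") from exc
        ce = compare_arms(cert, comp)
        delta_cost[i] = ce.delta_cost
        delta_qaly[i] = ce.delta_qaly
    ceac = compute_ceac(delta_cost, delta_qaly, ps.settings.threshold_grid)
    return PSAResults(
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        seed=seed,
        n_draws=n,
        ceac=ceac,
        p_cost_saving=float(np.mean(delta_cost < 0)),
        p_qaly_gain=float(np.mean(delta_qaly > 0)),
    )
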