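# Methods

## Model structure

The model is a hybrid decision tree + Markov cohort model with a 10-year
horizon and fixed one-year cycles.

**Cycle 0 (decision tree).** The whole cohort starts with an ordinary
companion dog (companion-state costs and utility weight). On the
certified track it additionally pays the year-1 certified dog-cost total,
which includes the suitability tests. The transition out of cycle 0
combines the year's owner and dog death risks with the certification
split: survivors pass into the certified state with probability
`p_minor · p_major · p_exam`, otherwise into the not-certified state. On
the companion track the split probability is zero and everything else is
identical, so with all pass probabilities set to zero the two arms differ
only by the suitability-test cost — a property the test suite asserts
exactly.

**Cycles 1–9 (Markov).** Five states: certified dog, dog retired, dog not
certified, dog dead, owner dead. Competing risks within a cycle are
ordered *owner death → dog death → retirement → decertification* and
applied as sequential conditional risks, which guarantees each row of the
transition matrix sums to one. The ordering itself is a modelling choice;
with annual risks of the magnitudes involved the ordering effect is far
below the reporting precision.

Both death states are absorbing. Treating *dog dead* as absorbing means no
replacement dog is acquired within the horizon; since it applies equally
to both arms it has little effect on the increments. The dog-dead state
accrues the companion-state (baseline) costs and utility weight but no
dog-category cost — a dead dog has no upkeep.

**Retirement timing.** A certified dog retires at the transition into the
cycle in which it attains the retirement age, so with a dog starting at
age 2 and retiring at 10 the cohort occupies the retired state from cycle
8 on. No cycle is spent certified at or beyond the retirement age.

**Benefit timing.** Certification is only attainable from cycle 1 (the
training year is cycle 0 on the tree; the year-2 dog-cost block carries
the training and cape costs). `benefit_start_cycle` (default 1) lets the
certified utility weight and cost profile start later if the user prefers
to treat the training year as unimproved.

**Accrual.** State costs (five categories) and utility weights are
multiplied by state occupancy and the discount factor `(1+r)^(−cycle)`;
cycle 0 is undiscounted and there is no half-cycle correction (the model
is a plain annual-cycle cohort model). Discounting applies identically to
costs and QALYs (default 3%/year).

## Parameters

* **State profiles.** Annual per-owner costs (USD, 2017, converted from
  SEK at 8.538 SEK/USD) in four state categories plus the dog-cost
  schedule, and an EQ-5D utility weight per state (UK tariff, range
  −0.594 to 1). The retired / lost-certification state is the arithmetic
  midpoint of the companion and certified profiles, truncated to whole
  USD; the packaged physical-service retired utility weight is the
  tabulated 0.309 rather than the midpoint 0.2885 — the shipped table is
  authoritative, the midpoint rule is used only when a retired column is
  absent from the input.
* **Dog costs.** Year-1 (purchase, upkeep, suitability tests), year-2
  (upkeep, training, capes) and subsequent-year (upkeep, maintenance
  test, health declaration) blocks per track. Printed block totals match
  component sums within 1 USD of rounding; the engine charges the block
  totals.
* **Transition probabilities.** The suitability-test/exam pass
  probabilities and the annual decertification risk were never published.
  Defaults: 0.9 / 0.9 / 0.9 and 0.02 per year — chosen as plausible for
  owner-dog teams that self-select into training — all overridable in
  `transitions.cfg` and logged at WARNING on every load so downstream
  results cannot silently depend on them.
* **Mortality.** Owner: Gompertz annual death probabilities anchored at
  q(44) = 0.002 doubling by age 54, a plausible general-population
  magnitude for a mid-40s cohort; any national life table can be dropped
  in via `owner_lifetable.csv`. Dog: constant annual hazard calibrated so
  cumulative mortality from age 2 to age 11 is 20% in the base case
  (the published anchors are 30% for the short-life-span scenario and 10%
  for the long one; the base case sits between them as a documented
  assumption, since the original breed-level estimates are not public).
* **Perspectives.** `societal` (all categories),
  `societal_no_productivity` (productivity zeroed) and `healthcare`.
  The composition of the health-care perspective is not standardised;
  here it keeps the health-care and dog (intervention) categories, on the
  argument that a payer who funds the programme always bears the
  intervention cost.

## Probabilistic sensitivity analysis

Costs are gamma-distributed, utility weights beta-distributed, all sampled
independently (no correlation structure is available to estimate one).
The tabulated (alfa, beta) pairs are inconsistent with the tabulated means
under both the shape/scale and shape/rate gamma conventions (e.g. shape 27
× scale 704 ≈ 19,000 against a mean of 8,928), so the default anchoring
(`psa_anchor = moment_matched`) keeps each distribution's printed shape —
hence its coefficient of variation — and rescales it so its mean equals
the base-case point value, the standard convention of centring a PSA on
the deterministic base case. `printed_params` samples the raw printed
distributions instead. Each distinct dog-cost component is drawn once per
iteration and shared across years and tracks; the dog-dead profile reuses
the companion draw so baseline reversion is preserved under sampling.

One shared `numpy` Generator drives a run; draws are parameter-major in a
fixed documented order (companion, certified, retired profiles — four cost
categories then the utility weight — then dog-cost components), so a seed
fully determines the result. Ties in net monetary benefit (exactly zero)
count as not cost-effective; for continuous distributions this is
immaterial. The default threshold grid is 0–150,000 USD/QALY in 2,500
steps. Transition and pass probabilities are *not* sampled — only
quantities with published distributional parameters are.

## Deterministic scenarios

Eleven built-in one-way scenarios: discount 0% and 5%; dog life span short
(30% cumulative mortality by age 11) and long (10%), implemented by
scaling the annual dog death probabilities by a single multiplier solved
by bisection to 1e-10; retirement at 8 and at 12; an exponential
retired-state trajectory; "all costs" (adds the per-state unrelated-cost
table — shipped as a zero add-on slot because no unrelated-cost magnitudes
are published, so the packaged scenario equals the base case); purchasing
a fully trained dog for 17,569 USD (year 1 becomes purchase + upkeep,
year 2 loses the training and cape costs); and the two alternative
perspectives.

The retired-trajectory rates are not published; the defaults grow retired
costs by 5% and shrink the retired utility weight by 5% per cycle *since
the earliest retirement cycle* (anchoring the trend at retirement rather
than model start, since the trend represents post-retirement
deterioration). Both rates are configurable and the scenario's results
should be read as assumption-dependent.

## Synthetic data

The generator emulates three inputs that cannot be downloaded: the owner
life table, the dog survival schedule (both above), and an
individual-level pre-post study sample. The pseudo-study draws, per
subject, quarterly costs per category (gamma, annual mean ÷ 4) and a
utility value (beta, clipped to the tariff range) from the companion
profile at baseline and the certified profile at follow-up, mirroring the
annualisation rule (quarterly × 4) used to build the cost tables. The
method-of-moments estimator recovers annualised means and gamma/beta
shapes per arm; recovery within three Monte-Carlo standard errors at
n = 100, 1,000 and 5,000 subjects is part of the test suite.

What the pseudo-study does **not** emulate: within-subject correlation
between baseline and follow-up, recall bias in self-reported resource
use, heterogeneity between owners, and selection into the training
programme. Passing recovery tests therefore validate the
distribution-to-table pipeline, not the epidemiological design.

## Numerical choices and limitations

* Occupancy conservation holds to 1e-12 by construction; the engine is
  checked against an independent path-enumeration oracle to 1e-9.
* Retired-midpoint costs are truncated (floor), matching the tabulated
  cells; utility midpoints are not rounded.
* ICERs are reported as labels ("Dominant", "Dominated") outside the
  trade-off quadrants and never as negative ratios; a zero QALY
  difference yields an undefined ICER classified by cost sign.
* Deterministic totals at the packaged defaults do **not** reproduce the
  original study's per-arm totals (those depend on the unpublished pass
  probabilities and the original Swedish life tables); the package's
  worked-example numbers are its own. Increment-assembly arithmetic on
  the shipped reference tables is exact.
* Problem sizes used by the reproduction script: 10,000 PSA draws per dog
  type, the full 11-scenario set and a 5,000-subject recovery check in
  the test suite.
* No microsimulation mode, no replacement dogs, no time-inhomogeneous
  decertification, no EVPI.
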