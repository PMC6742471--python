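# dogcea

Decision-analytic cost-effectiveness modelling of **certified assistance
dogs** — physical service dogs and diabetes alert dogs — compared with a
regular companion dog, from a societal perspective over a 10-year horizon.

People with severe functional impairments or intractable diabetes consume
substantial health care, municipal services and informal care, and often
cannot work. Training their companion dog into a certified assistance dog
may reduce that resource use and improve health-related quality of life.
`dogcea` is for health economists and HTA analysts who want to reproduce,
probe or extend that comparison: it implements the full model — a year-1
decision tree feeding a 9-year Markov cohort — together with probabilistic
and deterministic sensitivity analysis, a synthetic-data generator for the
inputs that are not publicly deposited, and a command-line interface.

## The model

Cycle 0 is a decision tree: owner and dog sit a minor and a major
suitability test and a final exam; the fraction
`p_minor · p_major · p_exam` enters the *certified dog* state at cycle 1,
the rest keep an uncertified dog. Cycles 1–9 are a Markov cohort over five
states — certified dog, dog retired, dog not certified, dog dead, owner
dead — with annual owner mortality `q_owner(age)`, dog mortality
`q_dog(age)`, forced retirement when the dog reaches its retirement age
(default 10, starting at 2), and an annual decertification risk. Within a
cycle the competing risks are applied sequentially (owner death → dog death
→ retirement → decertification), so each transition row sums to one.

Each state carries annual costs in five categories (health care, municipal
services, informal care, productivity loss, dog) and an EQ-5D utility
weight; both accrue per cycle, discounted at rate *r* (default 3%) by
`(1+r)^(−cycle)`, with no half-cycle correction. The primary outcome is the
incremental cost-effectiveness ratio

```
ICER = (C_certified − C_companion) / (E_certified − E_companion)
```

reported as "Dominant" when the certified dog is both cheaper and more
effective. The PSA resamples costs from gamma and utility weights from beta
distributions (10,000 draws) and summarises uncertainty on the
cost-effectiveness plane and as acceptability curves via net monetary
benefit `λ·ΔE − ΔC`. Eleven built-in one-way scenarios vary discounting,
dog life span and retirement age, the retired-state trajectory, cost scope
and perspective.

The packaged base case carries the published per-state cost and utility
tables for both dog types. The certification-test pass probabilities and
the annual decertification risk were never published; the packaged defaults
(0.9, 0.9, 0.9, 0.02) are documented assumptions and every run warns about
them. See `docs/methods.md` for all modelling choices.

## Worked example

```python
from dogcea import DecisionModel, load_example_parameters

model = DecisionModel(load_example_parameters("physical_service"))
print(model.fit().summary())
```

```
Cost-effectiveness summary — physical_service (societal perspective, 10-year horizon, 3% discount)
------------------------------------------------------------------------------
Arm                         Cost (USD)     QALYs
Certified dog                1,095,765      2.52
Companion dog                1,101,001      1.97
------------------------------------------------------------------------------
Incremental cost:       -5,237 USD
Incremental QALYs:       0.55
ICER: Dominant
```

Under the packaged assumptions a certified physical service dog saves about
5,200 USD over ten years and adds about half a QALY, so it *dominates* the
companion dog — no ratio is reported. The probabilistic analysis quantifies
how certain that is:

```python
psa = model.fit_psa(n_draws=10_000, seed=1)
print(f"P(cost saving) = {psa.p_cost_saving:.2f}, "
      f"P(QALY gain) = {psa.p_qaly_gain:.2f}")
# P(cost saving) = 0.51, P(QALY gain) = 0.95
psa.plot_ceac()
```

so the cost saving itself is a coin flip (the cost distributions are very
wide) while the QALY gain is highly probable. `model.fit_scenarios()` runs
the eleven one-way scenarios; switching to a health-care payer perspective
or making the retired-dog years more expensive and less healthy are the
changes that move the result away from dominance.

The same analyses are available from the shell:

```
dogcea run --dog-type physical_service --out results/base
dogcea psa --n 10000 --seed 1 --out results/psa
dogcea dsa --out results/dsa
dogcea simulate --n 500 --seed 1 --out results/sim
```

Every output directory gets a `manifest.json` (bundle hash, seed, package
version) sufficient to reproduce the run.

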