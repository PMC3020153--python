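# copdad — a decision-analytic advance-directive model for COPD

Patients with chronic obstructive pulmonary disease (COPD) face a concrete
advance-directive (AD) choice before the next severe exacerbation: **Full
Code** (invasive mechanical ventilation via endotracheal tube, ETT, may be
used) or **Do Not Intubate** (**DNI**; noninvasive ventilation and medical
treatment only). `copdad` is a decision-analytic model that compares the
two directives by expected quality-adjusted life years (QALYs) for a
hypothetical patient, given their COPD severity and their preferences about
intubation complications and permanent nursing-home placement. It is aimed
at clinical decision scientists and health-services researchers who want a
transparent, scriptable alternative to a point-and-click decision-tree
package.

## The model

Each directive is a fully resolved decision tree for a single
hospitalization for COPD exacerbation. Chance nodes split on exacerbation
severity (severely ill, pH < 7.29, vs. moderately ill), admission location
(ICU vs. ward), treatment intensity (ETT vs. noninvasive ventilation
[NIMV] vs. medical treatment without ventilation, with ETT only in the ICU
and ventilation-free treatment only on the ward), short-term outcome
(death, complication, uncomplicated course, with Comfort Measures Only
[CMO] an option after failed ventilation), and disposition (death, home,
short-term rehabilitation, or permanent extended-care-facility [ECF]
residence — the last reachable only after ventilation complications or CMO
survival).

A terminal node's payoff combines a life expectancy `LE` with a utility
`u` per health state, plus an optional month spent with intubation
complications valued at its own (possibly negative) utility:

    QALY = (LE − t_comp) · u_state + t_comp · u_complication,  t_comp in years

The expected value of a strategy is the probability-weighted rollback of
its tree, and the recommended directive maximizes expected QALYs:

    ΔQALY = E[QALY | Full Code] − E[QALY | DNI]

Supporting machinery, each usable on its own:

* **Evidence pooling** — DerSimonian–Laird random-effects meta-analysis
  (Cochran's Q, τ², I²) with the decision rules: pool when homogeneous
  (p(Q) > 0.10 and I² < 25%), fall back to the study median otherwise, use
  expert opinion when no studies exist, and close chance nodes by
  complement back-calculation with interval-arithmetic ranges.
* **DEALE** — the declining exponential approximation of life expectancy:
  a survival fraction S at horizon t implies mortality rate m = −ln(S)/t
  and LE = 1/m.
* **Time-tradeoff utilities** — u = (d − t)/d for a state of duration d
  and a traded amount t; trading more time than the state lasts yields
  utilities below zero (states worse than death), deliberately not floored.
* **Sensitivity analysis** — one-way sweeps over plausible ranges, tornado
  ordering, bisection threshold search for recommendation flips, and the
  two-way preference grid over tradeoff ladders.

## Worked example

The package ships a generator for a complete stand-in parameter set
(`copdad fixture out.yaml`, or `copdad.params.fixture_parameters()`); its
values are clinically plausible and internally consistent but are **not**
published estimates. For a patient with severe COPD:

```sh
$ copdad --severity severe evaluate
EV(Full Code) = 1.3910 QALYs
EV(DNI) = 1.3353 QALYs
delta (Full Code - DNI) = 0.0558 QALYs
recommended: Full Code
```

With neutral preferences (no time traded to avoid complications or ECF
residence), Full Code yields 0.056 more expected QALYs than DNI, so it is
the recommended directive — but weakly: the margin shrinks from mild to
severe COPD. A one-way sweep of the ETT-complication probability shows the
recommendation is not robust to that parameter:

```sh
$ copdad --severity severe oneway p_comp_ett
p_comp_ett: range [0.2, 0.7]
delta at low = 0.0884, at high = -0.0205
recommendation flips at p_comp_ett = 0.606034
```

If the probability of a complication among ETT survivors exceeds ~0.61,
DNI becomes the recommended directive for severe COPD. The `tornado` and
`grid` subcommands emit the full one-way table and the two-way preference
grid; in the grid, patients willing to trade substantial life expectancy
to avoid intubation complications or permanent institutionalization flip
to DNI, and the DNI region only grows with increasing aversion.

The same surface is available as a library:

```python
from copdad import CopdScenario, evaluate_scenario, fixture_parameters

params = fixture_parameters(seed=0)
rec = evaluate_scenario(CopdScenario("severe"), params)
print(rec.delta_qaly, rec.recommended)   # 0.0558 Full Code
```

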