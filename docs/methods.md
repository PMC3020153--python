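# Methods

## Model structure and assumptions

The model values two advance directives — Full Code and DNI — for a
single index hospitalization for COPD exacerbation. It is a plain decision
tree, not a state-transition model: one exacerbation, one hospital course,
one disposition, followed by remaining life at the post-discharge state's
utility. Annual AD review is represented by re-evaluating the same
one-shot tree with updated inputs, not by within-tree transitions. There
is deliberately no root chance node for "exacerbation vs. stable year":
the model conditions on the exacerbation having happened.

The tree factors each hospital course as a sequence of binary chance
nodes: exacerbation severity (severely ill, pH < 7.29, with probability
`exacerbation_mix`, default 0.5) → admission location → treatment
intensity → in-hospital death → complication status among survivors →
post-failure choices → disposition. Factoring death before complication
makes every probability a free parameter on [0, 1]: sweeping one never
breaks the probability simplex because its sibling is always a complement
edge resolved at validation time.

Structural rules enforced programmatically on every generated tree
(`audit_structure`):

1. ETT (and escalation to ETT) only inside the ICU arm.
2. Medical treatment without mechanical ventilation only on the ward.
3. No ETT anywhere under DNI.
4. CMO reachable only after a ventilation failure.
5. Long-term ECF terminals only downstream of ventilation complications
   or CMO survival.

Consequences of rules 1–2 worth making explicit, since the clinical
pathway does not uniquely determine them: NIMV is available in both ICU and ward
arms; a DNI patient admitted to the ICU receives NIMV (the only ICU
option without intubation); a Full Code patient whose NIMV fails in the
ICU may escalate to ETT, while one failing on the ward continues
supportive care — escalating ward patients would place an ETT branch
outside the ICU and violate rule 1. Patients on ventilation-free medical
treatment are an absorbing arm (no within-tree deterioration to
ventilation). Whether such deterioration occurs in reality is not modeled.

Two supportive-care death parameters exist because the states differ
clinically: `p_death_comp` (death after an ETT complication — end-organ
damage, infection, inability to discontinue ventilation — managed without
CMO) and `p_death_failed_nimv` (death after refractory NIMV failure with
no escalation, a substantially more lethal situation). Collapsing them to
one parameter makes DNI and Full Code nearly indistinguishable in
complication exposure and removes the preference sensitivity the model
exists to expose.

## Terminal payoffs

    death:           0
    home:            u_copd(severity) × le_copd(severity)
    short-term ECF:  valued as home (rehabilitation then return home;
                     an optional transient-disutility hook defaults off)
    long-term ECF:   u_ecf × le_ecf

A complicated course adds `complication_months` (default 1, matching the
time-tradeoff scenario; configurable) valued at `u_complication`, with the
same duration deducted from the post-discharge term, floored at zero. The
complication month attaches only to ETT pathways: the elicited preference
is specifically about intubation complications, and NIMV failure survivors
carry long-term-ECF risk but not that month. Survivors of a complicated
course keep the same severity-specific COPD life expectancy and utility
they had before the exacerbation — an explicit simplification; real
post-exacerbation quality of life recovers slowly. No discounting is
applied anywhere.

## Utilities and life expectancy

Time-tradeoff utilities are linear: u = (d − t)/d for a state of duration
d and traded time t. For the intubation-complication state d = 1 month;
for chronic long-term ECF residence d is the severity-specific remaining
life expectancy (the chronic reference could defensibly be the ECF life
expectancy instead; the severity-specific LE is the default because the
question is posed from the patient's current state of health). Utilities
are not floored at −1 — large tradeoffs are meaningful and flooring would
collapse the preference grid — though `floor_utility` exists as an opt-in
transform. Durations accept weeks, months, or years (1 year = 12 months,
1 month = 4.345 weeks).

Life expectancies may be given directly in years or as a survival
fraction at a horizon, converted at load time by the DEALE: m = −ln(S)/t,
LE = 1/m (conversion logged). The DEALE assumes a constant mortality
rate; it is a deliberate simplification over Gompertz-type models and is
least accurate for long horizons at low mortality.

## Evidence synthesis

With k ≥ 2 studies the DerSimonian–Laird random-effects estimator is
used: fixed-effect weights 1/vᵢ, Cochran's Q, moment estimator
τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)), random-effects weights
1/(vᵢ + τ²). Homogeneity is declared when the Q-test p-value exceeds 0.10
**and** I² < 25%; the thresholds commonly quoted for this rule mix a
p-value and an I² cutoff inconsistently, so this implementation fixes the
conjunction explicitly and conservatively. Heterogeneous data fall back
to the study median (midpoint for even k) with a plausible range spanning
the outermost per-study 95% confidence bounds; a pooled estimate's range
is its 95% CI under the random-effects model; expert-only parameters
carry their supplied wide range. Probability ranges are clamped to
[0, 1]. Event-count inputs use binomial variance p(1−p)/n with a 0.5
continuity correction on zero cells. Outlier screening is not automated;
`forest_data` emits per-study CIs for visual inspection.
Back-calculation is supported as complement-of-siblings closure only,
with interval-arithmetic range propagation.

## Sensitivity analysis

One-way sweeps re-evaluate ΔQALY at each bound of a parameter's plausible
range with all else at base case; because sibling probabilities are
complement edges, the complement absorbs the change (the standard
normalization for one-way analysis on chance nodes). ΔQALY is continuous
and piecewise-smooth in every scalar parameter, so flip values use plain
bisection, stopping at |ΔQALY| < 1e-9 or a parameter interval < 1e-6;
bracket endpoints within the ΔQALY tolerance count as roots. Tornado
output sorts bars by |ΔQALY(high) − ΔQALY(low)| descending. The two-way
preference grid sets `u_complication` and `u_ecf` from the linear TTO
formula along two tradeoff ladders (default: 0, 1 week, 1, 2, 3, 6, 12
months) and records the recommendation per cell; probabilities and
utilities are swept in the same one-way machinery rather than separate
diagrams. Ties at decision nodes resolve to the first-listed child with a
logged notice; the indifference tolerance defaults to 1e-9 QALY.

## The stand-in parameter set

`generate_fixture(seed, jitter)` emits a complete parameter file whose
values are fixed, clinically plausible stand-ins — **not** published
estimates — chosen once to reproduce the qualitative regime the model is
meant to explore: Full Code favored at every severity under neutral
preferences; the margin shrinking as COPD severity worsens (life
expectancy 10/6/3 years and utility 0.85/0.76/0.65 for mild/moderate/
severe); invasive ventilation genuinely life-saving for severely ill
patients (ward medical-treatment mortality 0.60 when severely ill vs.
ETT mortality 0.22); and plausible ranges for the ETT-complication and
severe-illness NIMV-failure probabilities wide enough that one-way sweeps
can cross indifference. The long-term ECF life expectancy ships as a
one-year nursing-home survival fraction (0.65) so loading exercises the
DEALE path. `jitter` perturbs points uniformly within their ranges for
robustness checks; the default of 0 yields the canonical set, and output
is deterministic given the seed.

What the generator does **not** emulate: correlations between parameters,
age/sex/comorbidity structure, multiple exacerbations per year, or any
real cohort's joint distribution. Tests passing on this set demonstrate
the machinery's correctness and the model's directional logic, not the
calibration of any published base case; replacing the stand-in file with
transcribed literature estimates is the intended workflow for substantive
use.

## Known limitations

* Single-hospitalization tree: no Markov extension, no repeat
  exacerbations, no increasing-severity dynamics.
* No costs, no cost-effectiveness, no probabilistic (Monte Carlo)
  sensitivity analysis, no EVPI.
* The post-discharge state is permanent: no recovery of utility, no
  transition out of long-term ECF.
* Uncomplicated in-hospital time contributes no disutility.
* The chance-node ordering (admission → intensity → outcome →
  disposition) is one defensible reading of the clinical pathway; the
  alternative orderings are not implemented.
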