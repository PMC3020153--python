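"""The two-strategy COPD advance-directive decision model.

Builds the Full Code and DNI strategy trees for a single index
hospitalization for COPD exacerbation and compares them by expected QALYs.

Structure, for each advance directive
-------------------------------------
The exacerbation is severely ill (pH < 7.29) or moderately ill; the
patient is admitted to the ICU or a regular ward.  Treatment intensity
depends on location and directive:

* ICU, Full Code: invasive ventilation (ETT) or noninvasive ventilation
  (NIMV).  ETT is offered only in the ICU.
* ICU, DNI: NIMV (the only ICU option without intubation).
* Ward, either directive: NIMV or medical treatment without mechanical
  ventilation (offered only on the ward).

Short-term (in-hospital) outcomes: ETT leads to death, an ETT complication
(end-organ damage, infection, or inability to discontinue ventilation), or
an uncomplicated course; NIMV leads to death, NIMV failure (inability to
wean), or a successful wean; ward medical treatment leads to death or
survival.  Patients who fail ventilation may choose Comfort Measures Only
(CMO); Full Code patients failing NIMV in the ICU may instead escalate to
ETT, while all others continue supportive care with the same in-hospital
death risk as ward medical management.

Long-term outcomes: uncomplicated survivors go home or to a short-term
rehabilitation facility (valued as home); survivors of a complicated
course or of CMO may instead be permanently institutionalized (long-term
ECF) — the only pathways that reach long-term ECF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .evidence import ParameterEstimate
from .preferences import UtilitySet
from .survival import (
    DEATH,
    HOME,
    LONG_TERM_ECF,
    SEVERITIES,
    SHORT_TERM_ECF,
    LifeTable,
    PayoffSpec,
    terminal_qaly,
)
from .tree import (
    DNI,
    FULL_CODE,
    Recommendation,
    Strategy,
    TreeNode,
    TreeValidationError,
    recommend,
)

SEVERELY_ILL = "severely_ill"
MODERATELY_ILL = "moderately_ill"
ILLNESS_LEVELS = (SEVERELY_ILL, MODERATELY_ILL)
DIRECTIVES = (FULL_CODE, DNI)

_DIRECTIVE_KEY = {FULL_CODE: "full_code", DNI: "dni"}

# canonical edge labels, shared with the structural audit
L_SEVERE = "severely ill"
L_MODERATE = "moderately ill"
L_ICU = "ICU"
L_WARD = "Ward"
L_ETT = "ETT"
L_NIMV = "NIMV"
L_NO_MV = "no mechanical ventilation"
L_DEATH = "death"
L_ETT_COMP = "ETT complication"
L_ETT_OK = "ETT uncomplicated"
L_NIMV_FAIL = "NIMV failure"
L_WEAN = "wean success"
L_SURVIVE = "survives"
L_CMO = "CMO"
L_ESCALATE = "escalate to ETT"
L_SUPPORTIVE = "continue supportive care"
L_CMO_SURVIVE = "CMO survives"
L_CMO_DEATH = "CMO death"
L_LT_ECF = "long-term ECF"
L_ST_ECF = "short-term ECF"
L_HOME = "home"

#: Ventilation-complication edges: NIMV failure, or an ETT complication.
COMPLICATION_LABELS = frozenset({L_ETT_COMP, L_NIMV_FAIL})


class ConfigurationError(ValueError):
    pass


class StructuralError(AssertionError):
    """A generated tree violates one of the model's structural rules."""


#: Every parameter the tree builder resolves, with a short meaning.
REQUIRED_PARAMETERS: dict[str, str] = {
    # admission location, by directive and severity of the exacerbation
    "p_icu.full_code.severely_ill": "P(ICU admission | severely ill, Full Code)",
    "p_icu.full_code.moderately_ill": "P(ICU admission | moderately ill, Full Code)",
    "p_icu.dni.severely_ill": "P(ICU admission | severely ill, DNI)",
    "p_icu.dni.moderately_ill": "P(ICU admission | moderately ill, DNI)",
    # treatment intensity
    "p_ett.severely_ill": "P(ETT | ICU, severely ill, Full Code)",
    "p_ett.moderately_ill": "P(ETT | ICU, moderately ill, Full Code)",
    "p_nimv_ward.full_code.severely_ill": "P(NIMV | ward, severely ill, Full Code)",
    "p_nimv_ward.full_code.moderately_ill": "P(NIMV | ward, moderately ill, Full Code)",
    "p_nimv_ward.dni.severely_ill": "P(NIMV | ward, severely ill, DNI)",
    "p_nimv_ward.dni.moderately_ill": "P(NIMV | ward, moderately ill, DNI)",
    # short-term outcomes; complication probabilities are conditional on
    # surviving the initial course, so every probability sweeps freely in [0, 1]
    "p_death_ett": "P(in-hospital death | ETT)",
    "p_comp_ett": "P(ETT complication | survived ETT)",
    "p_death_nimv.severely_ill": "P(in-hospital death | NIMV, severely ill)",
    "p_death_nimv.moderately_ill": "P(in-hospital death | NIMV, moderately ill)",
    "p_comp_nimv.severely_ill": "P(NIMV failure | survived NIMV, severely ill)",
    "p_comp_nimv.moderately_ill": "P(NIMV failure | survived NIMV, moderately ill)",
    "p_death_nomv.severely_ill": "P(in-hospital death | medical treatment, severely ill)",
    "p_death_nomv.moderately_ill": "P(in-hospital death | medical treatment, moderately ill)",
    "p_death_comp": "P(in-hospital death | ETT complication, supportive care)",
    "p_death_failed_nimv": "P(in-hospital death | NIMV failure, no escalation)",
    # choices and outcomes after failed ventilation
    "p_cmo": "P(CMO chosen | failed ventilation)",
    "p_surv_cmo": "P(survival | CMO)",
    # dispositions
    "p_ltecf": "P(long-term ECF | complicated course or CMO survivor)",
    "p_stecf": "P(short-term ECF | uncomplicated survivor)",
    # utilities
    "u_copd.mild": "utility of home life with mild COPD",
    "u_copd.moderate": "utility of home life with moderate COPD",
    "u_copd.severe": "utility of home life with severe COPD",
    "u_complication": "utility of the month with ventilation complications (TTO)",
    "u_ecf": "utility of long-term ECF residence (TTO)",
    # life expectancies (years)
    "le_copd.mild": "life expectancy with mild COPD",
    "le_copd.moderate": "life expectancy with moderate COPD",
    "le_copd.severe": "life expectancy with severe COPD",
    "le_ecf": "life expectancy in a long-term ECF",
}

PROBABILITY_PARAMETERS = tuple(n for n in REQUIRED_PARAMETERS if n.startswith("p_"))
UTILITY_PARAMETERS = tuple(n for n in REQUIRED_PARAMETERS if n.startswith("u_"))
LIFE_EXPECTANCY_PARAMETERS = tuple(n for n in REQUIRED_PARAMETERS if n.startswith("le_"))


@dataclass
class CopdScenario:
    """Baseline COPD severity (GOLD-based) and the exacerbation mix: the
    probability that the index exacerbation is severely ill (pH < 7.29)
    rather than moderately ill."""

    copd_severity: str
    exacerbation_mix: float = 0.5

    def __post_init__(self) -> None:
        if self.copd_severity not in SEVERITIES:
            raise ConfigurationError(
                f"unknown COPD severity {self.copd_severity!r}; "
                f"expected one of {SEVERITIES}"
            )
        if not (0 <= self.exacerbation_mix <= 1):
            raise ConfigurationError("exacerbation_mix must be in [0, 1]")


@dataclass
class ModelParameters:
    """The named parameter set driving both strategy trees.

    ``estimates`` maps parameter names (see REQUIRED_PARAMETERS) to
    ParameterEstimates; ``complication_months`` is the duration of the
    ventilation-complication period (the TTO scenario uses 1 month).
    """

    estimates: dict[str, ParameterEstimate] = field(default_factory=dict)
    complication_months: float = 1.0

    def require(self) -> None:
        missing = sorted(set(REQUIRED_PARAMETERS) - set(self.estimates))
        if missing:
            raise ConfigurationError(f"missing parameters: {', '.join(missing)}")
        bad = [
            n for n in PROBABILITY_PARAMETERS
            if not (0 <= self.estimates[n].point <= 1)
        ]
        if bad:
            raise ConfigurationError(
                f"probabilities outside [0, 1]: {', '.join(sorted(bad))}"
            )

    def value(self, name: str) -> float:
        try:
            return self.estimates[name].point
        except KeyError:
            raise ConfigurationError(f"missing parameter: {name}") from None

    def estimate(self, name: str) -> ParameterEstimate:
        try:
            return self.estimates[name]
        except KeyError:
            raise ConfigurationError(f"missing parameter: {name}") from None

    def with_value(self, name: str, value: float) -> "ModelParameters":
        """A copy with one parameter's point value overridden (range kept,
        widened if needed so the estimate stays valid)."""
        est = self.estimate(name)
        new = ParameterEstimate(
            name=est.name,
            point=value,
            low=min(est.low, value),
            high=max(est.high, value),
            provenance=est.provenance,
        )
        estimates = dict(self.estimates)
        estimates[name] = new
        return replace(self, estimates=estimates)

    def utility_set(self) -> UtilitySet:
        return UtilitySet(
            u_copd={s: self.value(f"u_copd.{s}") for s in SEVERITIES},
            u_complication=self.value("u_complication"),
            u_ecf=self.value("u_ecf"),
        )

    def life_table(self) -> LifeTable:
        return LifeTable(
            le_copd={s: self.value(f"le_copd.{s}") for s in SEVERITIES},
            le_ecf=self.value("le_ecf"),
        )


def build_strategy_tree(
    directive: str, scenario: CopdScenario, params: ModelParameters
) -> Strategy:
    """Build and validate one directive's strategy tree for a scenario."""
    if directive not in DIRECTIVES:
        raise ConfigurationError(f"unknown directive {directive!r}")
    params.require()
    utilities = params.utility_set()
    lifetable = params.life_table()
    sev = scenario.copd_severity
    dkey = _DIRECTIVE_KEY[directive]
    comp_months = params.complication_months

    def q(disposition: str, complicated: bool = False) -> float:
        return terminal_qaly(
            PayoffSpec(
                disposition=disposition,
                severity=sev,
                complication_months=comp_months if complicated else 0.0,
            ),
            lifetable,
            utilities,
        )

    def death() -> TreeNode:
        return TreeNode.terminal(L_DEATH, q(DEATH))

    def uncomplicated_disposition() -> TreeNode:
        return TreeNode.chance("disposition", [
            (L_ST_ECF, params.value("p_stecf"), TreeNode.terminal(L_ST_ECF, q(SHORT_TERM_ECF))),
            (L_HOME, "complement", TreeNode.terminal(L_HOME, q(HOME))),
        ])

    def complicated_disposition(ett: bool) -> TreeNode:
        # survivors of any ventilation complication risk permanent
        # institutionalization; the month spent with intubation
        # complications (the TTO state) attaches only to ETT pathways
        return TreeNode.chance("disposition after complications", [
            (L_LT_ECF, params.value("p_ltecf"), TreeNode.terminal(L_LT_ECF, q(LONG_TERM_ECF, complicated=ett))),
            (L_HOME, "complement", TreeNode.terminal(L_HOME, q(HOME, complicated=ett))),
        ])

    def cmo_outcome() -> TreeNode:
        # CMO survivors may be discharged to long-term ECF or home
        return TreeNode.chance("CMO outcome", [
            (L_CMO_SURVIVE, params.value("p_surv_cmo"), TreeNode.chance("disposition after CMO", [
                (L_LT_ECF, params.value("p_ltecf"), TreeNode.terminal(L_LT_ECF, q(LONG_TERM_ECF))),
                (L_HOME, "complement", TreeNode.terminal(L_HOME, q(HOME))),
            ])),
            (L_CMO_DEATH, "complement", death()),
        ])

    def supportive_after_complication(ett: bool) -> TreeNode:
        # continued supportive care after a ventilation complication still
        # carries in-hospital mortality; refractory NIMV failure without
        # escalation is substantially more lethal than a managed ETT
        # complication, so the two arms have separate death parameters
        p_death = params.value("p_death_comp" if ett else "p_death_failed_nimv")
        return TreeNode.chance("supportive care outcome", [
            (L_DEATH, p_death, death()),
            (L_SURVIVE, "complement", complicated_disposition(ett)),
        ])

    def after_complication() -> TreeNode:
        return TreeNode.chance("after ETT complication", [
            (L_CMO, params.value("p_cmo"), cmo_outcome()),
            (L_SUPPORTIVE, "complement", supportive_after_complication(ett=True)),
        ])

    def ett_outcome(illness: str) -> TreeNode:
        # death first; complication status among survivors
        return TreeNode.chance("ETT outcome", [
            (L_DEATH, params.value("p_death_ett"), death()),
            (L_SURVIVE, "complement", TreeNode.chance("ETT course", [
                (L_ETT_COMP, params.value("p_comp_ett"), after_complication()),
                (L_ETT_OK, "complement", uncomplicated_disposition()),
            ])),
        ])

    def failed_nimv(illness: str, in_icu: bool) -> TreeNode:
        if directive == FULL_CODE and in_icu:
            alternative = (L_ESCALATE, "complement", ett_outcome(illness))
        else:
            alternative = (L_SUPPORTIVE, "complement", supportive_after_complication(ett=False))
        return TreeNode.chance("after NIMV failure", [
            (L_CMO, params.value("p_cmo"), cmo_outcome()),
            alternative,
        ])

    def nimv_outcome(illness: str, in_icu: bool) -> TreeNode:
        return TreeNode.chance("NIMV outcome", [
            (L_DEATH, params.value(f"p_death_nimv.{illness}"), death()),
            (L_SURVIVE, "complement", TreeNode.chance("NIMV course", [
                (L_NIMV_FAIL, params.value(f"p_comp_nimv.{illness}"), failed_nimv(illness, in_icu)),
                (L_WEAN, "complement", uncomplicated_disposition()),
            ])),
        ])

    def no_mv_outcome(illness: str) -> TreeNode:
        return TreeNode.chance("medical treatment outcome", [
            (L_DEATH, params.value(f"p_death_nomv.{illness}"), death()),
            (L_SURVIVE, "complement", uncomplicated_disposition()),
        ])

    def icu_arm(illness: str) -> TreeNode:
        if directive == FULL_CODE:
            return TreeNode.chance("ICU treatment", [
                (L_ETT, params.value(f"p_ett.{illness}"), ett_outcome(illness)),
                (L_NIMV, "complement", nimv_outcome(illness, in_icu=True)),
            ])
        # DNI: without intubation, ICU treatment is NIMV
        return nimv_outcome(illness, in_icu=True)

    def ward_arm(illness: str) -> TreeNode:
        return TreeNode.chance("ward treatment", [
            (L_NIMV, params.value(f"p_nimv_ward.{dkey}.{illness}"), nimv_outcome(illness, in_icu=False)),
            (L_NO_MV, "complement", no_mv_outcome(illness)),
        ])

    def admission(illness: str) -> TreeNode:
        return TreeNode.chance("admission", [
            (L_ICU, params.value(f"p_icu.{dkey}.{illness}"), icu_arm(illness)),
            (L_WARD, "complement", ward_arm(illness)),
        ])

    root = TreeNode.chance("exacerbation severity", [
        (L_SEVERE, scenario.exacerbation_mix, admission(SEVERELY_ILL)),
        (L_MODERATE, "complement", admission(MODERATELY_ILL)),
    ])
    strategy = Strategy(name=directive, root=root)
    strategy.validate()
    audit_structure(strategy)
    return strategy


def audit_structure(strategy: Strategy) -> None:
    """Programmatic check of the model's five structural rules.

    1. ETT appears only inside the ICU arm.
    2. Medical treatment without mechanical ventilation appears only on
       the ward.
    3. A DNI tree contains no ETT edges at all.
    4. CMO is reachable only after a ventilation failure (NIMV failure or
       ETT complication).
    5. Long-term ECF terminals appear only downstream of ventilation
       complications or CMO survival.

    Raises StructuralError naming the violated rule.
    """

    def _walk(node: TreeNode, ancestors: tuple[str, ...]) -> None:
        for edge in node.children:
            lbl = edge.label
            if lbl in (L_ETT, L_ESCALATE):
                if strategy.name == DNI:
                    raise StructuralError(
                        f"rule 'no ETT under DNI' violated at edge {lbl!r}"
                    )
                if L_ICU not in ancestors:
                    raise StructuralError(
                        f"rule 'ETT only in the ICU' violated at edge {lbl!r}"
                    )
            if lbl == L_NO_MV and L_WARD not in ancestors:
                raise StructuralError(
                    "rule 'non-ventilatory treatment only on the ward' violated"
                )
            if lbl == L_CMO and not COMPLICATION_LABELS.intersection(ancestors):
                raise StructuralError(
                    "rule 'CMO only after ventilation failure' violated"
                )
            if edge.child.kind == "terminal" and edge.child.label == L_LT_ECF:
                if not (
                    COMPLICATION_LABELS.intersection(ancestors)
                    or L_CMO_SURVIVE in ancestors
                    or lbl in COMPLICATION_LABELS
                ):
                    raise StructuralError(
                        "rule 'long-term ECF only after complications or CMO "
                        "survival' violated"
                    )
            _walk(edge.child, ancestors + (lbl,))

    _walk(strategy.root, ())


def evaluate_scenario(
    scenario: CopdScenario,
    params: ModelParameters,
    tolerance: float = 1e-9,
) -> Recommendation:
    """Build both strategy trees, roll them back, and recommend the
    directive with the greater expected QALYs."""
    strategies = [
        build_strategy_tree(d, scenario, params) for d in (FULL_CODE, DNI)
    ]
    return recommend(strategies, tolerance=tolerance)


def delta_qaly(scenario: CopdScenario, params: ModelParameters) -> float:
    """Expected QALY difference, Full Code minus DNI."""
    return evaluate_scenario(scenario, params).delta_qaly
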