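"""Life-expectancy math (DEALE) and terminal-node QALY payoffs.

The DEALE (declining exponential approximation of life expectancy) treats
survival as a simple exponential decay: a fraction S surviving to horizon
t years implies a constant mortality rate m = -ln(S)/t, and life
expectancy is its reciprocal, 1/m.  The model uses it to convert published
survival fractions (BODE-index COPD survival, nursing-home one-year
mortality) into life expectancies.

Terminal payoffs combine a disposition (death, home, short- or long-term
extended-care facility) with a utility weight and a life expectancy, plus
an optional period spent with ventilation complications valued at its own
utility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .preferences import UtilitySet

MILD = "mild"
MODERATE = "moderate"
SEVERE = "severe"
SEVERITIES = (MILD, MODERATE, SEVERE)

DEATH = "death"
HOME = "home"
SHORT_TERM_ECF = "short_term_ecf"
LONG_TERM_ECF = "long_term_ecf"
DISPOSITIONS = (DEATH, HOME, SHORT_TERM_ECF, LONG_TERM_ECF)

MONTHS_PER_YEAR = 12.0


class InputError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass
class SurvivalDatum:
    """A survival fraction at a fixed horizon, e.g. S(1 yr) = 0.68."""

    horizon: float  # years
    survival: float  # proportion surviving to the horizon

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise InputError(f"horizon must be positive, got {self.horizon}")
        if not (0 < self.survival <= 1):
            raise InputError(f"survival must be in (0, 1], got {self.survival}")


def deale_rate(datum: SurvivalDatum) -> float:
    """Constant mortality rate (per year) implied by the survival datum:
    m = -ln(S)/t.  S = 1 gives rate 0."""
    return -math.log(datum.survival) / datum.horizon


def deale_le(rate: float) -> float:
    """Life expectancy (years) under a constant mortality rate: LE = 1/m."""
    if rate <= 0:
        raise InputError(f"mortality rate must be positive, got {rate}")
    return 1.0 / rate


def le_from_survival(datum: SurvivalDatum) -> float:
    """Convenience composition: survival fraction -> DEALE life expectancy."""
    return deale_le(deale_rate(datum))


@dataclass
class LifeTable:
    """Life expectancies (years) by COPD severity, plus long-term ECF."""

    le_copd: dict[str, float]  # keyed by severity
    le_ecf: float

    def __post_init__(self) -> None:
        for sev, le in self.le_copd.items():
            if le <= 0:
                raise InputError(f"le_copd[{sev!r}] must be positive, got {le}")
        if self.le_ecf <= 0:
            raise InputError(f"le_ecf must be positive, got {self.le_ecf}")


@dataclass
class PayoffSpec:
    """What a terminal node represents: where the patient ends up, how
    long they spent with ventilation complications, and their baseline
    COPD severity."""

    disposition: str
    severity: str
    complication_months: float = 0.0

    def __post_init__(self) -> None:
        if self.disposition not in DISPOSITIONS:
            raise InputError(f"unknown disposition {self.disposition!r}")
        if self.complication_months < 0:
            raise InputError("complication_months must be >= 0")


def terminal_qaly(spec: PayoffSpec, lifetable: LifeTable, utilities: UtilitySet) -> float:
    """QALY payoff for a terminal node.

    death -> 0.  Otherwise the post-discharge life expectancy is weighted
    by the state utility: home and short-term ECF (rehabilitation followed
    by return home) use the severity-specific COPD utility and LE;
    long-term ECF uses the ECF utility and nursing-home LE.  Any
    complication period contributes complication_months/12 years at the
    complication utility, and the same duration is deducted from the
    post-discharge term (floored at 0).
    """
    if spec.disposition == DEATH:
        return 0.0
    comp_years = spec.complication_months / MONTHS_PER_YEAR
    if spec.disposition == LONG_TERM_ECF:
        u, le = utilities.u_ecf, lifetable.le_ecf
    else:  # home and short-term ECF are valued alike
        if spec.severity not in lifetable.le_copd:
            raise ConfigurationError(f"no life expectancy for severity {spec.severity!r}")
        u = utilities.copd_utility(spec.severity)
        le = lifetable.le_copd[spec.severity]
    qaly = max(le - comp_years, 0.0) * u
    if comp_years > 0:
        qaly += comp_years * utilities.u_complication
    return qaly
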