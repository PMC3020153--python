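"""Time-tradeoff (TTO) utilities, including states worse than death.

A TTO question asks how much life expectancy a respondent would give up to
avoid a health state.  With a state of duration d and a traded amount t,
the linear TTO utility is

    u = (d - t) / d

so trading nothing gives u = 1, trading exactly the state's duration gives
u = 0 (the state is as bad as being dead for its duration), and trading
more than the duration gives a negative utility (worse than death).  For
the one-month intubation-complication scenario d = 1 month; for chronic
long-term extended-care-facility residence d is the respondent's remaining
life expectancy.

Utilities are deliberately not floored at -1: respondents willing to trade
large amounts of time alive produce large-magnitude negative utilities,
and flooring would erase those distinctions.  :func:`floor_utility` is
available as an opt-in transform.
"""

from __future__ import annotations

from dataclasses import dataclass

ETT_COMPLICATION = "ett_complication"
LONG_TERM_ECF = "long_term_ecf"
TTO_STATES = (ETT_COMPLICATION, LONG_TERM_ECF)

WEEKS_PER_MONTH = 4.345
MONTHS_PER_YEAR = 12.0


class InputError(ValueError):
    pass


def to_months(value: float, units: str) -> float:
    """Convert a duration to months (1 year = 12 months, 1 month = 4.345
    weeks)."""
    if units in ("month", "months", "mo"):
        return float(value)
    if units in ("week", "weeks", "wk"):
        return float(value) / WEEKS_PER_MONTH
    if units in ("year", "years", "yr"):
        return float(value) * MONTHS_PER_YEAR
    raise InputError(f"unknown duration units {units!r}")


@dataclass
class TTOResponse:
    """One time-tradeoff answer.

    ``time_traded`` and ``reference_duration`` are in months; the
    reference duration is the duration of the avoided state (1 month for
    the intubation-complication scenario, the severity-specific life
    expectancy for chronic ECF residence).
    """

    state: str
    time_traded: float
    reference_duration: float

    def __post_init__(self) -> None:
        if self.state not in TTO_STATES:
            raise InputError(f"unknown TTO state {self.state!r}")
        if self.time_traded < 0:
            raise InputError("time_traded must be >= 0")
        if self.reference_duration <= 0:
            raise InputError("reference_duration must be positive")


def tto_utility(response: TTOResponse) -> float:
    """Linear TTO utility u = (d - t)/d; negative when t exceeds d."""
    d = response.reference_duration
    return (d - response.time_traded) / d


def tradeoff_grid(
    state: str, tradeoffs: list[float], reference_duration: float
) -> list[tuple[float, float]]:
    """Utilities along a ladder of traded durations (months, ascending).

    Returns (tradeoff, utility) pairs; utilities are strictly decreasing.
    """
    if any(t < 0 for t in tradeoffs):
        raise InputError("tradeoffs must be nonnegative")
    if list(tradeoffs) != sorted(tradeoffs):
        raise InputError("tradeoffs must be sorted ascending")
    return [
        (t, tto_utility(TTOResponse(state, t, reference_duration)))
        for t in tradeoffs
    ]


def floor_utility(u: float, floor: float = -1.0) -> float:
    """Opt-in transform bounding a utility below (not applied by default)."""
    return max(u, floor)


@dataclass
class UtilitySet:
    """Utility weights used by the model's terminal payoffs.

    u_copd maps COPD severity to the baseline utility of living at home
    with that severity (in (0, 1]); u_complication values the month spent
    with ventilation complications and u_ecf values long-term ECF
    residence — both may be negative (worse than death).
    """

    u_copd: dict[str, float]
    u_complication: float
    u_ecf: float

    def __post_init__(self) -> None:
        for sev, u in self.u_copd.items():
            if not (0 < u <= 1):
                raise InputError(f"u_copd[{sev!r}] must be in (0, 1], got {u}")
        if self.u_complication > 1 or self.u_ecf > 1:
            raise InputError("utilities cannot exceed 1")

    def copd_utility(self, severity: str) -> float:
        if severity not in self.u_copd:
            raise InputError(f"no COPD utility for severity {severity!r}")
        return self.u_copd[severity]
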