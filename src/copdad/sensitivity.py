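"""One-way, two-way, and threshold sensitivity analyses.

All analyses perturb a base-case :class:`~copdad.model.ModelParameters`
and re-evaluate the QALY difference Full Code − DNI.  Because chance
nodes are built with complement edges, sweeping one sibling probability
automatically renormalizes the node: the complement absorbs the change.

ΔQALY is continuous and piecewise-smooth in every scalar parameter, so
threshold (flip-value) searches use plain bisection.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import (
    ConfigurationError,
    CopdScenario,
    ModelParameters,
    REQUIRED_PARAMETERS,
    delta_qaly,
    evaluate_scenario,
)
from .preferences import (
    ETT_COMPLICATION,
    LONG_TERM_ECF,
    MONTHS_PER_YEAR,
    TTOResponse,
    WEEKS_PER_MONTH,
    tto_utility,
)
from .tree import INDIFFERENT

#: Default tradeoff ladder (months): none, 1 week, 1, 2, 3, 6 months, 1 year.
DEFAULT_TRADEOFF_LADDER = (
    0.0,
    1.0 / WEEKS_PER_MONTH,
    1.0,
    2.0,
    3.0,
    6.0,
    12.0,
)

DELTA_TOL = 1e-9  # |ΔQALY| convergence target for threshold search
PARAM_TOL = 1e-6  # parameter-interval convergence target


class RootNotBracketedError(ValueError):
    """ΔQALY has the same sign at both bracket ends."""


@dataclass
class OneWayResult:
    parameter: str
    low: float
    high: float
    delta_low: float  # ΔQALY with the parameter at its low bound
    delta_high: float  # ΔQALY with the parameter at its high bound
    crosses_zero: bool
    flip_value: float | None  # parameter value where ΔQALY = 0

    @property
    def width(self) -> float:
        return abs(self.delta_high - self.delta_low)


@dataclass
class TornadoBar:
    parameter: str
    delta_low: float
    delta_high: float

    @property
    def width(self) -> float:
        return abs(self.delta_high - self.delta_low)


@dataclass
class TwoWayGrid:
    """Recommended directive over a grid of preference tradeoffs.

    ``x_axis``: months traded to avoid long-term ECF; ``y_axis``: months
    traded to avoid the month of intubation complications.  ``cells[i][j]``
    is the recommendation at (y_axis[i], x_axis[j]).
    """

    x_axis: list[float]
    y_axis: list[float]
    cells: list[list[str]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells,
            index=pd.Index(self.y_axis, name="tradeoff_avoid_complication_months"),
            columns=pd.Index(self.x_axis, name="tradeoff_avoid_ltecf_months"),
        )


def _delta_at(
    scenario: CopdScenario, params: ModelParameters, name: str, value: float
) -> float:
    return delta_qaly(scenario, params.with_value(name, value))


def one_way(
    scenario: CopdScenario, params: ModelParameters, parameter: str
) -> OneWayResult:
    """ΔQALY at both ends of one parameter's plausible range, all other
    parameters held at base case; if the sign flips across the range the
    flip value is located by bisection."""
    if parameter not in params.estimates:
        raise ConfigurationError(f"unknown parameter: {parameter}")
    est = params.estimate(parameter)
    d_low = _delta_at(scenario, params, parameter, est.low)
    d_high = _delta_at(scenario, params, parameter, est.high)
    crosses = (d_low == 0 or d_high == 0 or (d_low < 0) != (d_high < 0)) and (
        est.low != est.high or d_low == 0
    )
    flip = None
    if crosses:
        if d_low == 0:
            flip = est.low
        elif d_high == 0:
            flip = est.high
        else:
            flip = find_threshold(scenario, params, parameter, (est.low, est.high))
    return OneWayResult(
        parameter=parameter,
        low=est.low,
        high=est.high,
        delta_low=d_low,
        delta_high=d_high,
        crosses_zero=crosses,
        flip_value=flip,
    )


def tornado(
    scenario: CopdScenario,
    params: ModelParameters,
    parameters: list[str] | None = None,
) -> list[TornadoBar]:
    """One bar per swept parameter, sorted by descending width (the most
    influential parameters first)."""
    names = parameters if parameters is not None else list(REQUIRED_PARAMETERS)
    bars = []
    for name in names:
        res = one_way(scenario, params, name)
        bars.append(TornadoBar(name, res.delta_low, res.delta_high))
    bars.sort(key=lambda b: b.width, reverse=True)
    return bars


def tornado_frame(bars: list[TornadoBar]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"parameter": b.parameter, "delta_low": b.delta_low,
             "delta_high": b.delta_high, "width": b.width}
            for b in bars
        ]
    )


def find_threshold(
    scenario: CopdScenario,
    params: ModelParameters,
    parameter: str,
    bracket: tuple[float, float],
) -> float:
    """Bisection for the parameter value where ΔQALY crosses zero.

    Stops when |ΔQALY| < 1e-9 or the parameter interval is below 1e-6.
    Raises RootNotBracketedError when ΔQALY has the same sign at both
    bracket ends (an endpoint where ΔQALY is exactly zero is returned).
    """
    a, b = float(bracket[0]), float(bracket[1])
    fa = _delta_at(scenario, params, parameter, a)
    fb = _delta_at(scenario, params, parameter, b)
    if abs(fa) < DELTA_TOL:
        return a
    if abs(fb) < DELTA_TOL:
        return b
    if (fa < 0) == (fb < 0):
        raise RootNotBracketedError(
            f"ΔQALY has the same sign at both ends of {bracket} for "
            f"{parameter!r} ({fa:.4g}, {fb:.4g})"
        )
    while abs(b - a) > PARAM_TOL:
        mid = 0.5 * (a + b)
        fm = _delta_at(scenario, params, parameter, mid)
        if abs(fm) < DELTA_TOL:
            return mid
        if (fm < 0) == (fa < 0):
            a, fa = mid, fm
        else:
            b, fb = mid, fm
    return 0.5 * (a + b)


def two_way_preference_grid(
    scenario: CopdScenario,
    params: ModelParameters,
    ecf_tradeoffs: list[float] | None = None,
    complication_tradeoffs: list[float] | None = None,
) -> TwoWayGrid:
    """Recommended directive as both preference tradeoffs vary jointly.

    Each axis is a ladder of months of life expectancy the patient would
    trade: to avoid permanent ECF residence (x; the TTO reference is the
    severity-specific life expectancy) and to avoid the month of
    intubation complications (y; reference 1 month, or whatever
    ``params.complication_months`` is).  Each cell re-evaluates the model
    with u_ecf and u_complication set from the linear TTO formula, all
    other parameters at base case.
    """
    xs = list(ecf_tradeoffs if ecf_tradeoffs is not None else DEFAULT_TRADEOFF_LADDER)
    ys = list(
        complication_tradeoffs
        if complication_tradeoffs is not None
        else DEFAULT_TRADEOFF_LADDER
    )
    for axis, vals in (("ecf_tradeoffs", xs), ("complication_tradeoffs", ys)):
        if vals != sorted(vals):
            raise ConfigurationError(f"{axis} must be sorted ascending")
        if any(v < 0 for v in vals):
            raise ConfigurationError(f"{axis} must be nonnegative")
    le_months = params.value(f"le_copd.{scenario.copd_severity}") * MONTHS_PER_YEAR
    comp_ref = params.complication_months
    cells: list[list[str]] = []
    for ty in ys:
        u_comp = tto_utility(TTOResponse(ETT_COMPLICATION, ty, comp_ref))
        row: list[str] = []
        for tx in xs:
            u_ecf = tto_utility(TTOResponse(LONG_TERM_ECF, tx, le_months))
            p = params.with_value("u_complication", u_comp).with_value("u_ecf", u_ecf)
            row.append(evaluate_scenario(scenario, p).recommended)
        cells.append(row)
    return TwoWayGrid(x_axis=xs, y_axis=ys, cells=cells)


def grid_is_upward_closed(grid: TwoWayGrid) -> bool:
    """True when scanning any row or column toward greater aversion never
    switches DNI back to Full Code (the DNI region is upward-closed)."""
    from .tree import DNI as _DNI

    def monotone(seq: list[str]) -> bool:
        seen_dni = False
        for cell in seq:
            if cell == _DNI:
                seen_dni = True
            elif seen_dni and cell != INDIFFERENT:
                return False
        return True

    rows_ok = all(monotone(row) for row in grid.cells)
    cols = [[grid.cells[i][j] for i in range(len(grid.y_axis))] for j in range(len(grid.x_axis))]
    return rows_ok and all(monotone(col) for col in cols)


def tornado_figure(bars: list[TornadoBar], base_delta: float, path: str) -> None:
    """Render a tornado diagram to ``path`` (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bars = [b for b in bars if b.width > 0]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(bars) + 1.5))
    names = [b.parameter for b in bars][::-1]
    for i, b in enumerate(bars[::-1]):
        lo, hi = sorted((b.delta_low, b.delta_high))
        ax.barh(i, hi - lo, left=lo, color="steelblue")
    ax.axvline(base_delta, color="k", lw=0.8, ls="--", label="base case")
    ax.axvline(0.0, color="r", lw=0.8, label="indifference")
    ax.set_yticks(range(len(names)), names, fontsize=7)
    ax.set_xlabel("ΔQALY (Full Code − DNI)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
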