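"""Evidence synthesis: turn per-study inputs into model parameter estimates.

The pooling decision rules are:

1. With two or more studies and sufficiently homogeneous data, pool with
   the DerSimonian-Laird random-effects estimator; the plausible range is
   the 95% CI of the pooled estimate.
2. With heterogeneous data, fall back to the median study estimate, with a
   plausible range spanning the lowest and highest reported per-study 95%
   confidence bounds.
3. With no study data, use expert opinion with a wide supplied range.
4. Some probabilities are closed by back-calculation: the complement of
   their siblings at a chance node, with interval-arithmetic ranges.

Homogeneity is declared when the Q-test p-value exceeds 0.10 AND I² is
below 25%.  (The combination of thresholds is deliberate: each alone is a
common rule of thumb; requiring both is conservative.)  Outlier screening
on a forest plot is not automated; :func:`forest_data` emits the plot data
for visual inspection instead.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

import pandas as pd
from scipy import stats

POOLED = "pooled"
MEDIAN = "median"
EXPERT = "expert"
BACK_CALCULATED = "back-calculated"

#: Homogeneity thresholds: Cochran's Q p-value must exceed this ...
Q_PVALUE_THRESHOLD = 0.10
#: ... and I² (percent) must be below this.
I2_THRESHOLD = 25.0

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class InputError(ValueError):
    """Invalid study-level inputs."""


class ConfigurationError(ValueError):
    """No usable evidence supplied for a parameter."""


@dataclass
class StudyEffect:
    """One study's estimate (a proportion or continuous effect) and its
    sampling variance."""

    study_id: str
    estimate: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise InputError(
                f"study {self.study_id!r}: variance must be positive, "
                f"got {self.variance}"
            )

    @staticmethod
    def from_events(study_id: str, events: float, n: float) -> "StudyEffect":
        """Build a proportion effect from an event count.

        Zero cells (events == 0 or events == n) get a continuity correction
        of 0.5 added to both cells so the binomial variance is positive.
        """
        if n <= 0:
            raise InputError(f"study {study_id!r}: n must be positive")
        if events < 0 or events > n:
            raise InputError(f"study {study_id!r}: events must be in [0, n]")
        if events == 0 or events == n:
            events = events + 0.5
            n = n + 1.0
        p = events / n
        return StudyEffect(study_id=study_id, estimate=p, variance=p * (1 - p) / n)

    def ci95(self) -> tuple[float, float]:
        half = Z_95 * self.variance**0.5
        return self.estimate - half, self.estimate + half


@dataclass
class PoolingResult:
    pooled: float  # random-effects pooled estimate
    pooled_fe: float  # fixed-effect (inverse-variance) mean
    se: float  # standard error of the pooled estimate
    tau2: float  # between-study variance (DL moment estimator)
    Q: float  # Cochran's heterogeneity statistic
    q_pvalue: float  # chi-square p-value of Q on k-1 df
    i2: float  # percent of variability attributable to heterogeneity
    k: int  # number of studies

    @property
    def homogeneous(self) -> bool:
        return self.q_pvalue > Q_PVALUE_THRESHOLD and self.i2 < I2_THRESHOLD

    def ci95(self) -> tuple[float, float]:
        return self.pooled - Z_95 * self.se, self.pooled + Z_95 * self.se


@dataclass
class ParameterEstimate:
    """A named model input: point value, plausible range, and provenance."""

    name: str
    point: float
    low: float
    high: float
    provenance: str

    def __post_init__(self) -> None:
        if not (self.low <= self.point <= self.high):
            raise InputError(
                f"parameter {self.name!r}: require low <= point <= high, "
                f"got ({self.low}, {self.point}, {self.high})"
            )

    def clamped(self, lo: float = 0.0, hi: float = 1.0) -> "ParameterEstimate":
        """Range (and point) clamped to [lo, hi]; used for probabilities."""
        return ParameterEstimate(
            name=self.name,
            point=min(max(self.point, lo), hi),
            low=min(max(self.low, lo), hi),
            high=min(max(self.high, lo), hi),
            provenance=self.provenance,
        )


def pool_dl(studies: list[StudyEffect]) -> PoolingResult:
    """DerSimonian-Laird random-effects pooling.

    Fixed-effect weights w_i = 1/v_i give the fixed-effect mean and
    Cochran's Q = sum w_i (theta_i - theta_FE)^2.  The moment estimator
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) then yields
    random-effects weights 1/(v_i + tau^2) and the pooled mean.
    """
    k = len(studies)
    if k < 2:
        raise InputError(f"pooling requires at least 2 studies, got {k}")
    w = [1.0 / s.variance for s in studies]
    sw = sum(w)
    theta_fe = sum(wi * s.estimate for wi, s in zip(w, studies)) / sw
    Q = sum(wi * (s.estimate - theta_fe) ** 2 for wi, s in zip(w, studies))
    c = sw - sum(wi**2 for wi in w) / sw
    tau2 = max(0.0, (Q - (k - 1)) / c) if c > 0 else 0.0
    w_re = [1.0 / (s.variance + tau2) for s in studies]
    sw_re = sum(w_re)
    pooled = sum(wi * s.estimate for wi, s in zip(w_re, studies)) / sw_re
    se = (1.0 / sw_re) ** 0.5
    q_pvalue = float(stats.chi2.sf(Q, df=k - 1))
    i2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
    return PoolingResult(
        pooled=pooled, pooled_fe=theta_fe, se=se, tau2=tau2, Q=Q,
        q_pvalue=q_pvalue, i2=i2, k=k,
    )


def choose_estimate(
    name: str,
    studies: list[StudyEffect] | None = None,
    expert_value: float | None = None,
    expert_range: tuple[float, float] | None = None,
    clamp_probability: bool = False,
) -> ParameterEstimate:
    """Apply the pooling decision rules to produce a ParameterEstimate.

    k >= 2 homogeneous studies -> pooled point with its 95% CI as range;
    k >= 2 heterogeneous -> median point, range spanning the outermost
    per-study 95% CI bounds; otherwise the expert value with its supplied
    wide range.  A single study is treated like expert input being absent:
    its estimate is used directly with its own CI as the range.
    """
    studies = studies or []
    if not studies and expert_value is None:
        raise ConfigurationError(f"parameter {name!r}: no studies and no expert value")
    if len(studies) >= 2:
        result = pool_dl(studies)
        if result.homogeneous:
            low, high = result.ci95()
            est = ParameterEstimate(name, result.pooled, min(low, result.pooled),
                                    max(high, result.pooled), POOLED)
        else:
            point = statistics.median(s.estimate for s in studies)
            bounds = [b for s in studies for b in s.ci95()]
            est = ParameterEstimate(name, point, min(min(bounds), point),
                                    max(max(bounds), point), MEDIAN)
    elif len(studies) == 1:
        s = studies[0]
        low, high = s.ci95()
        est = ParameterEstimate(name, s.estimate, min(low, s.estimate),
                                max(high, s.estimate), MEDIAN)
    else:
        if expert_range is None:
            expert_range = (expert_value, expert_value)  # type: ignore[assignment]
        est = ParameterEstimate(name, float(expert_value), float(expert_range[0]),
                                float(expert_range[1]), EXPERT)
    return est.clamped() if clamp_probability else est


def back_calculate_complement(
    siblings: list[ParameterEstimate], name: str = "complement"
) -> ParameterEstimate:
    """Close a chance node: the remaining probability is one minus the
    sibling sum, with the range propagated by interval arithmetic and
    clamped to [0, 1]."""
    total = sum(s.point for s in siblings)
    if total > 1:
        raise InputError(
            f"back-calculation for {name!r}: sibling points sum to {total} > 1"
        )
    point = 1.0 - total
    low = 1.0 - sum(s.high for s in siblings)
    high = 1.0 - sum(s.low for s in siblings)
    return ParameterEstimate(
        name=name, point=point, low=low, high=high, provenance=BACK_CALCULATED
    ).clamped()


def forest_data(studies: list[StudyEffect], result: PoolingResult | None = None) -> pd.DataFrame:
    """Per-study estimates with 95% CIs plus the pooled row, for a forest
    plot (outlier screening is visual, not automated)."""
    rows = []
    for s in studies:
        lo, hi = s.ci95()
        rows.append({"study_id": s.study_id, "estimate": s.estimate,
                     "low": lo, "high": hi, "weight": 1.0 / s.variance})
    if result is not None:
        lo, hi = result.ci95()
        rows.append({"study_id": "pooled (RE)", "estimate": result.pooled,
                     "low": lo, "high": hi, "weight": float("nan")})
    return pd.DataFrame(rows)


def read_study_table(path: str) -> list[StudyEffect]:
    """Read a delimited study table.

    Columns: ``study_id`` plus either (``estimate``, ``variance``) or
    (``events``, ``n``); the latter is converted to a proportion with
    binomial variance p(1-p)/n.
    """
    df = pd.read_csv(path)
    if {"estimate", "variance"}.issubset(df.columns):
        return [
            StudyEffect(str(r.study_id), float(r.estimate), float(r.variance))
            for r in df.itertuples()
        ]
    if {"events", "n"}.issubset(df.columns):
        return [
            StudyEffect.from_events(str(r.study_id), float(r.events), float(r.n))
            for r in df.itertuples()
        ]
    raise InputError(
        f"{path}: need columns (study_id, estimate, variance) or (study_id, events, n)"
    )
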