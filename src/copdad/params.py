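"""Parameter-file reading/writing, validation, and fixture generation.

The parameter file is human-editable YAML with sections:

``metadata``
    free-form provenance notes (model name, version, description).
``scenario``
    default COPD severity and exacerbation mix.
``settings``
    ``complication_months`` (duration of the ventilation-complication
    period; the time-tradeoff scenario uses 1 month).
``probabilities`` / ``utilities`` / ``life_expectancy``
    named entries ``{point, low, high, provenance}``.  Life-expectancy
    entries may instead supply ``{survival, horizon_years, ...}`` rows,
    converted to years at load time via the DEALE (conversion logged).
``tto_responses``
    optional time-tradeoff answers that override ``u_complication`` /
    ``u_ecf``.
``studies``
    optional per-parameter study tables (estimate+variance or events+n)
    run through the evidence-synthesis decision rules; they take
    precedence over a direct entry for the same parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .evidence import ParameterEstimate, StudyEffect, choose_estimate
from .model import (
    ConfigurationError,
    CopdScenario,
    LIFE_EXPECTANCY_PARAMETERS,
    ModelParameters,
    PROBABILITY_PARAMETERS,
    REQUIRED_PARAMETERS,
    UTILITY_PARAMETERS,
)
from .preferences import (
    ETT_COMPLICATION,
    LONG_TERM_ECF,
    TTOResponse,
    to_months,
    tto_utility,
)
from .survival import SurvivalDatum, le_from_survival

logger = logging.getLogger(__name__)

STAND_IN_NOTE = (
    "synthetic stand-in parameter set: values are internally consistent and "
    "severity-ordered but are NOT the published base-case estimates"
)


class ParameterFileError(ValueError):
    """The parameter file is missing entries or contains invalid values."""


@dataclass
class ParameterFile:
    """Parsed parameter-file content (pre-validation)."""

    metadata: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)
    probabilities: dict = field(default_factory=dict)
    utilities: dict = field(default_factory=dict)
    life_expectancy: dict = field(default_factory=dict)
    tto_responses: list = field(default_factory=list)
    studies: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "metadata": self.metadata,
            "scenario": self.scenario,
            "settings": self.settings,
            "probabilities": self.probabilities,
            "utilities": self.utilities,
            "life_expectancy": self.life_expectancy,
        }
        if self.tto_responses:
            d["tto_responses"] = self.tto_responses
        if self.studies:
            d["studies"] = self.studies
        return d

    @staticmethod
    def from_dict(d: dict) -> "ParameterFile":
        return ParameterFile(
            metadata=d.get("metadata", {}) or {},
            scenario=d.get("scenario", {}) or {},
            settings=d.get("settings", {}) or {},
            probabilities=d.get("probabilities", {}) or {},
            utilities=d.get("utilities", {}) or {},
            life_expectancy=d.get("life_expectancy", {}) or {},
            tto_responses=d.get("tto_responses", []) or [],
            studies=d.get("studies", {}) or {},
        )

    def default_scenario(self) -> CopdScenario:
        return CopdScenario(
            copd_severity=self.scenario.get("copd_severity", "moderate"),
            exacerbation_mix=float(self.scenario.get("exacerbation_mix", 0.5)),
        )


def _entry_to_estimate(name: str, entry: dict, issues: list[str]) -> ParameterEstimate | None:
    try:
        point = float(entry["point"])
    except (KeyError, TypeError, ValueError):
        issues.append(f"{name}: missing or non-numeric 'point'")
        return None
    low = float(entry.get("low", point))
    high = float(entry.get("high", point))
    provenance = str(entry.get("provenance", "expert"))
    try:
        return ParameterEstimate(name, point, low, high, provenance)
    except ValueError as exc:
        issues.append(str(exc))
        return None


def _le_entry_to_estimate(name: str, entry: dict, issues: list[str]) -> ParameterEstimate | None:
    if "survival" in entry:
        try:
            horizon = float(entry.get("horizon_years", 1.0))
            point = le_from_survival(SurvivalDatum(horizon, float(entry["survival"])))
            low = le_from_survival(
                SurvivalDatum(horizon, float(entry.get("survival_low", entry["survival"])))
            )
            high = le_from_survival(
                SurvivalDatum(horizon, float(entry.get("survival_high", entry["survival"])))
            )
        except ValueError as exc:
            issues.append(f"{name}: {exc}")
            return None
        logger.info(
            "%s: converted survival %.3f at %.2f yr to LE %.4f yr (DEALE)",
            name, float(entry["survival"]), horizon, point,
        )
        provenance = str(entry.get("provenance", "median"))
        return ParameterEstimate(name, point, min(low, point), max(high, point), provenance)
    return _entry_to_estimate(name, entry, issues)


def parameter_file_to_model(pf: ParameterFile) -> ModelParameters:
    """Resolve a ParameterFile into validated ModelParameters.

    Raises ParameterFileError listing every missing or out-of-range entry
    by name.
    """
    issues: list[str] = []
    estimates: dict[str, ParameterEstimate] = {}

    for name, entry in pf.probabilities.items():
        est = _entry_to_estimate(name, entry, issues)
        if est is not None:
            if not (0 <= est.low and est.high <= 1):
                issues.append(
                    f"{name}: probability range [{est.low}, {est.high}] outside [0, 1]"
                )
            else:
                estimates[name] = est
    for name, entry in pf.utilities.items():
        est = _entry_to_estimate(name, entry, issues)
        if est is not None:
            estimates[name] = est
    for name, entry in pf.life_expectancy.items():
        est = _le_entry_to_estimate(name, entry, issues)
        if est is not None:
            estimates[name] = est

    # per-parameter study tables run through the pooling decision rules
    for name, rows in pf.studies.items():
        studies = []
        for r in rows:
            if "estimate" in r:
                studies.append(StudyEffect(str(r["study_id"]), float(r["estimate"]),
                                           float(r["variance"])))
            else:
                studies.append(StudyEffect.from_events(str(r["study_id"]),
                                                       float(r["events"]), float(r["n"])))
        est = choose_estimate(name, studies, clamp_probability=name.startswith("p_"))
        logger.info("%s: %s from %d studies -> %.4f [%.4f, %.4f]",
                    name, est.provenance, len(studies), est.point, est.low, est.high)
        estimates[name] = est

    # TTO responses override the preference utilities
    settings = pf.settings or {}
    comp_months = float(settings.get("complication_months", 1.0))
    for row in pf.tto_responses:
        state = row["state"]
        traded = to_months(float(row["time_traded"]), row.get("units", "months"))
        ref = to_months(
            float(row.get("reference_duration", comp_months)),
            row.get("reference_units", "months"),
        )
        u = tto_utility(TTOResponse(state, traded, ref))
        target = "u_complication" if state == ETT_COMPLICATION else "u_ecf"
        prior = estimates.get(target)
        low = min(u, prior.low) if prior else u
        high = max(u, prior.high) if prior else u
        estimates[target] = ParameterEstimate(target, u, low, high, "expert")
        logger.info("%s: set to %.4f from TTO response (traded %.3f of %.3f months)",
                    target, u, traded, ref)

    missing = sorted(set(REQUIRED_PARAMETERS) - set(estimates))
    for name in missing:
        issues.append(f"missing parameter: {name} ({REQUIRED_PARAMETERS[name]})")
    if issues:
        raise ParameterFileError(
            "invalid parameter file:\n  " + "\n  ".join(issues)
        )
    return ModelParameters(estimates=estimates, complication_months=comp_months)


def load_parameter_file(path: str) -> ParameterFile:
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ParameterFileError(f"{path}: parse error: {exc}") from exc
    if not isinstance(data, dict):
        raise ParameterFileError(f"{path}: expected a mapping at top level")
    return ParameterFile.from_dict(data)


def load_parameters(path: str) -> ModelParameters:
    """Load and fully validate a parameter file."""
    return parameter_file_to_model(load_parameter_file(path))


def save_parameter_file(pf: ParameterFile, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(pf.to_dict(), fh, sort_keys=True)


def model_to_parameter_file(
    params: ModelParameters,
    metadata: dict | None = None,
    scenario: dict | None = None,
) -> ParameterFile:
    """Express resolved ModelParameters as file content (all studies and
    survival rows already folded into point estimates)."""

    def entry(name: str) -> dict:
        e = params.estimates[name]
        return {"point": e.point, "low": e.low, "high": e.high,
                "provenance": e.provenance}

    return ParameterFile(
        metadata=metadata or {},
        scenario=scenario or {},
        settings={"complication_months": params.complication_months},
        probabilities={n: entry(n) for n in PROBABILITY_PARAMETERS if n in params.estimates},
        utilities={n: entry(n) for n in UTILITY_PARAMETERS if n in params.estimates},
        life_expectancy={n: entry(n) for n in LIFE_EXPECTANCY_PARAMETERS if n in params.estimates},
    )


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

#: Canonical stand-in values: (point, low, high, provenance).  Chosen to be
#: clinically plausible for hospitalized COPD exacerbations and strictly
#: severity-ordered (worse survival, LE, and utility with worse COPD), with
#: plausible ranges wide enough for meaningful sensitivity analyses.
FIXTURE_BASE: dict[str, tuple[float, float, float, str]] = {
    "p_icu.full_code.severely_ill": (0.70, 0.55, 0.85, "median"),
    "p_icu.full_code.moderately_ill": (0.30, 0.15, 0.45, "median"),
    "p_icu.dni.severely_ill": (0.40, 0.20, 0.60, "expert"),
    "p_icu.dni.moderately_ill": (0.15, 0.05, 0.30, "expert"),
    "p_ett.severely_ill": (0.60, 0.40, 0.80, "pooled"),
    "p_ett.moderately_ill": (0.25, 0.10, 0.40, "pooled"),
    "p_nimv_ward.full_code.severely_ill": (0.60, 0.40, 0.80, "median"),
    "p_nimv_ward.full_code.moderately_ill": (0.40, 0.20, 0.60, "median"),
    "p_nimv_ward.dni.severely_ill": (0.70, 0.40, 0.90, "expert"),
    "p_nimv_ward.dni.moderately_ill": (0.40, 0.15, 0.65, "expert"),
    "p_death_ett": (0.22, 0.15, 0.40, "pooled"),
    "p_comp_ett": (0.35, 0.20, 0.70, "median"),
    "p_death_nimv.severely_ill": (0.25, 0.12, 0.40, "pooled"),
    "p_death_nimv.moderately_ill": (0.08, 0.04, 0.15, "pooled"),
    "p_comp_nimv.severely_ill": (0.35, 0.10, 0.52, "pooled"),
    "p_comp_nimv.moderately_ill": (0.15, 0.07, 0.30, "pooled"),
    "p_death_nomv.severely_ill": (0.60, 0.40, 0.80, "expert"),
    "p_death_nomv.moderately_ill": (0.12, 0.05, 0.25, "median"),
    "p_death_comp": (0.40, 0.25, 0.60, "expert"),
    "p_death_failed_nimv": (0.75, 0.55, 0.90, "expert"),
    "p_cmo": (0.30, 0.10, 0.50, "expert"),
    "p_surv_cmo": (0.15, 0.05, 0.30, "median"),
    "p_ltecf": (0.30, 0.15, 0.50, "median"),
    "p_stecf": (0.25, 0.10, 0.40, "median"),
    "u_copd.mild": (0.85, 0.75, 0.95, "median"),
    "u_copd.moderate": (0.76, 0.66, 0.86, "median"),
    "u_copd.severe": (0.65, 0.50, 0.80, "median"),
    # neutral preferences at base case (no time traded); ranges span the
    # time-tradeoff ladder used in the preference analyses
    "u_complication": (1.00, -11.0, 1.00, "expert"),
    "u_ecf": (1.00, -1.0, 1.00, "expert"),
    "le_copd.mild": (10.0, 8.0, 14.0, "median"),
    "le_copd.moderate": (6.0, 4.5, 8.0, "median"),
    "le_copd.severe": (3.0, 2.0, 4.5, "median"),
}

#: le_ecf ships as a one-year nursing-home survival fraction so loading
#: exercises the DEALE conversion path.
FIXTURE_LE_ECF_SURVIVAL = {"survival": 0.65, "survival_low": 0.55,
                           "survival_high": 0.75, "horizon_years": 1.0,
                           "provenance": "median"}


def generate_fixture(seed: int, jitter: float = 0.0) -> ParameterFile:
    """A complete, internally consistent stand-in parameter set.

    Deterministic given ``seed``.  With ``jitter`` > 0, point values are
    perturbed uniformly by up to ``jitter`` times their half-range and
    clipped to stay inside their plausible range; the default emits the
    canonical stand-in values unchanged.
    """
    rng = np.random.default_rng(seed)
    probabilities: dict[str, dict] = {}
    utilities: dict[str, dict] = {}
    life_expectancy: dict[str, dict] = {}
    for name, (point, low, high, provenance) in FIXTURE_BASE.items():
        if jitter > 0 and high > low:
            half = 0.5 * (high - low)
            point = float(np.clip(point + rng.uniform(-1, 1) * jitter * half, low, high))
            point = round(point, 6)
        entry = {"point": point, "low": low, "high": high, "provenance": provenance}
        if name.startswith("p_"):
            probabilities[name] = entry
        elif name.startswith("u_"):
            utilities[name] = entry
        else:
            life_expectancy[name] = entry
    life_expectancy["le_ecf"] = dict(FIXTURE_LE_ECF_SURVIVAL)
    return ParameterFile(
        metadata={
            "model": "copdad",
            "version": 1,
            "seed": int(seed),
            "jitter": float(jitter),
            "note": STAND_IN_NOTE,
        },
        scenario={"copd_severity": "moderate", "exacerbation_mix": 0.5},
        settings={"complication_months": 1.0},
        probabilities=probabilities,
        utilities=utilities,
        life_expectancy=life_expectancy,
    )


def fixture_parameters(seed: int = 0, jitter: float = 0.0) -> ModelParameters:
    """Resolved ModelParameters for the stand-in parameter set."""
    return parameter_file_to_model(generate_fixture(seed, jitter))
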