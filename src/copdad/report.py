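"""Delimited-text reporting for a model run."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .model import CopdScenario, ModelParameters, build_strategy_tree, evaluate_scenario
from .sensitivity import tornado, tornado_frame, two_way_preference_grid
from .tree import DNI, FULL_CODE, enumerate_paths

logger = logging.getLogger(__name__)

ANALYSES = ("paths", "tornado", "grid")


def run_report(
    scenario: CopdScenario,
    params: ModelParameters,
    analyses: list[str] | None = None,
    outdir: str | Path = ".",
    seed: int | None = None,
) -> dict[str, Path]:
    """Evaluate the scenario and write delimited report files.

    Always writes ``recommendation.csv`` and ``run_log.txt``; the optional
    analyses add ``paths_*.csv``, ``tornado.csv`` and ``grid.csv``.
    Returns the mapping of report name to file path.  Content is
    deterministic for identical inputs.
    """
    analyses = list(analyses or [])
    unknown = set(analyses) - set(ANALYSES)
    if unknown:
        raise ValueError(f"unknown analyses: {sorted(unknown)}; expected {ANALYSES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    rec = evaluate_scenario(scenario, params)
    rec_df = pd.DataFrame(
        [
            {"strategy": FULL_CODE, "expected_qalys": rec.ev_by_strategy[FULL_CODE]},
            {"strategy": DNI, "expected_qalys": rec.ev_by_strategy[DNI]},
        ]
    )
    rec_df["delta_qaly_full_code_minus_dni"] = rec.delta_qaly
    rec_df["recommended"] = rec.recommended
    path = outdir / "recommendation.csv"
    rec_df.to_csv(path, index=False)
    written["recommendation"] = path

    if "paths" in analyses:
        for directive in (FULL_CODE, DNI):
            strat = build_strategy_tree(directive, scenario, params)
            rows = [
                {"probability": p, "payoff_qalys": payoff, "path": " > ".join(labels)}
                for p, payoff, labels in enumerate_paths(strat.root)
            ]
            fname = f"paths_{directive.lower().replace(' ', '_')}.csv"
            p_out = outdir / fname
            pd.DataFrame(rows).to_csv(p_out, index=False)
            written[fname.removesuffix(".csv")] = p_out

    if "tornado" in analyses:
        bars = tornado(scenario, params)
        p_out = outdir / "tornado.csv"
        tornado_frame(bars).to_csv(p_out, index=False)
        written["tornado"] = p_out

    if "grid" in analyses:
        grid = two_way_preference_grid(scenario, params)
        p_out = outdir / "grid.csv"
        grid.to_frame().to_csv(p_out)
        written["grid"] = p_out

    log_lines = [
        f"copdad version: {__version__}",
        f"seed: {seed}",
        f"scenario: copd_severity={scenario.copd_severity} "
        f"exacerbation_mix={scenario.exacerbation_mix}",
        f"complication_months: {params.complication_months}",
        f"analyses: {', '.join(analyses) if analyses else '(recommendation only)'}",
        "parameter provenance:",
    ]
    for name in sorted(params.estimates):
        e = params.estimates[name]
        log_lines.append(
            f"  {name}: point={e.point:.6g} range=[{e.low:.6g}, {e.high:.6g}] "
            f"provenance={e.provenance}"
        )
    log_path = outdir / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    written["run_log"] = log_path
    logger.info("report written to %s", outdir)
    return written
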