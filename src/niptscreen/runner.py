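"""Scenario grid driver and report writers.

Runs the full experiment grid (strategy × risk cut-off × NIPT price × uptake
scenario), producing the published outcome- and cost-table shapes as CSV plus
an exact-value JSON sidecar.  Grid results are a pure function of the parameter
bundle and the axes: reruns are bitwise identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cohort import MaternalAgeDistribution, PrevalenceModel
from .costing import CostSummary, cost_events, round_thousands
from .parameters import ParameterSet, StrategySpec
from .pathways import OutcomeSummary, PathwayEvents, run_strategy

log = logging.getLogger(__name__)

DEFAULT_CUTOFFS = [150, 500, 1000, 2000]
DEFAULT_PRICES = [50.0, 250.0, 500.0, 750.0]
DEFAULT_STRATEGIES = ["current", "contingent_nipt", "firstline_nipt"]

OUTCOME_COLUMNS = [
    "strategy", "screening_risk_cutoff", "n_screened", "n_nipt", "n_nipt_positive",
    "n_invasive", "n_procedure_miscarriages", "n_ds_detected",
]
COST_COLUMNS = [
    "strategy", "screening_risk_cutoff", "nipt_unit_cost",
    "cost_screening_thousands", "cost_nipt_thousands", "cost_invasive_thousands",
    "cost_pregnancy_outcomes_thousands", "total_thousands",
]


@dataclass
class ScenarioResult:
    """One grid cell: a strategy run with its outcome and per-price costs."""

    spec: StrategySpec
    events: PathwayEvents
    outcome: OutcomeSummary
    costs_by_price: dict[float, CostSummary]


def _spec_for(strategy: str, cutoff: int, uptake_scenario: str, **kwargs) -> StrategySpec:
    scenario = uptake_scenario
    if strategy != "contingent_nipt" and scenario in ("nipt_100", "nipt_100_screen_79"):
        scenario = "base"
    if strategy != "firstline_nipt" and scenario == "firstline_79":
        scenario = "base"
    return StrategySpec(
        strategy=strategy, screening_risk_cutoff=cutoff, uptake_scenario=scenario, **kwargs
    )


def run_grid(
    params: ParameterSet,
    cutoffs: list[int] | None = None,
    prices: list[float] | None = None,
    scenarios: list[str] | None = None,
    uptake_scenario: str = "base",
    include_pregnancy_outcome_costs: bool = False,
    separate_nipt_blood_draw: bool = False,
    ages: MaternalAgeDistribution | None = None,
    prev: PrevalenceModel | None = None,
) -> list[ScenarioResult]:
    """Evaluate every (strategy, cut-off) cell and price it across NIPT prices.

    ``scenarios`` selects strategies; the cut-off axis applies only to
    strategies with a screening stage, and current screening appears once
    (its costs are NIPT-price independent).
    """
    cutoffs = DEFAULT_CUTOFFS if cutoffs is None else cutoffs
    prices = DEFAULT_PRICES if prices is None else prices
    scenarios = DEFAULT_STRATEGIES if scenarios is None else scenarios
    if not cutoffs or not prices or not scenarios:
        raise ValueError("cutoffs, prices and scenarios must be non-empty")
    unknown = set(scenarios) - set(DEFAULT_STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies {sorted(unknown)}; known: {DEFAULT_STRATEGIES}")

    flags = dict(
        include_pregnancy_outcome_costs=include_pregnancy_outcome_costs,
        separate_nipt_blood_draw=separate_nipt_blood_draw,
    )
    results: list[ScenarioResult] = []
    for strategy in scenarios:
        if strategy == "current":
            cells = [(cutoffs[0], [prices[0]])]  # price-independent, single row
        elif strategy == "contingent_nipt":
            cells = [(c, prices) for c in cutoffs]
        else:  # firstline
            cells = [(cutoffs[0], prices)]
        for cutoff, cell_prices in cells:
            spec = _spec_for(strategy, cutoff, uptake_scenario, **flags)
            events, outcome = run_strategy(params, spec, ages=ages, prev=prev)
            log.info(
                "strategy=%s cutoff=%s conservation_error=%.3e",
                strategy, cutoff, events.conservation_error(),
            )
            costs = {
                price: cost_events(
                    events, params.costs.model_copy(update={"nipt_unit_cost": float(price)}), spec
                )
                for price in cell_prices
            }
            results.append(ScenarioResult(spec=spec, events=events, outcome=outcome, costs_by_price=costs))
    return results


def outcomes_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        summary = res.outcome.rounded(2)
        rows.append(
            {
                "strategy": res.spec.strategy,
                "screening_risk_cutoff": res.spec.screening_risk_cutoff
                if res.spec.strategy != "firstline_nipt"
                else "",
                **summary.as_dict(),
            }
        )
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)


def costs_frame(results: list[ScenarioResult], exact: bool = False) -> pd.DataFrame:
    """Cost table; £000s rounded half-up by default, exact pounds with ``exact=True``."""
    conv = (lambda x: x) if exact else round_thousands
    suffix = "" if exact else "_thousands"
    rows = []
    for res in results:
        for price, summary in sorted(res.costs_by_price.items()):
            rows.append(
                {
                    "strategy": res.spec.strategy,
                    "screening_risk_cutoff": res.spec.screening_risk_cutoff
                    if res.spec.strategy != "firstline_nipt"
                    else "",
                    "nipt_unit_cost": "" if res.spec.strategy == "current" else price,
                    f"cost_screening{suffix}": conv(summary.cost_screening),
                    f"cost_nipt{suffix}": conv(0.0 if res.spec.strategy == "current" else summary.cost_nipt),
                    f"cost_invasive{suffix}": conv(summary.cost_invasive),
                    f"cost_pregnancy_outcomes{suffix}": conv(summary.cost_pregnancy_outcomes),
                    f"total{suffix}": conv(summary.total),
                }
            )
    columns = [c if exact else c for c in COST_COLUMNS]
    if exact:
        columns = [c.replace("_thousands", "") for c in COST_COLUMNS]
    return pd.DataFrame(rows, columns=columns)


def _metadata_header(results: list[ScenarioResult], seed: int | None) -> str:
    strategies = sorted({r.spec.strategy for r in results})
    cutoffs = sorted({r.spec.screening_risk_cutoff for r in results})
    scenario = results[0].spec.uptake_scenario if results else "base"
    lines = [
        "# niptscreen scenario report",
        f"# strategies: {','.join(strategies)}",
        f"# cutoffs: {','.join(map(str, cutoffs))}",
        f"# uptake_scenario: {scenario}",
        f"# seed: {seed if seed is not None else 'n/a (deterministic)'}",
    ]
    return "\n".join(lines) + "\n"


def write_reports(
    results: list[ScenarioResult], destination: str | Path, seed: int | None = None
) -> dict[str, Path]:
    """Write outcome/cost CSVs plus a JSON sidecar with exact unrounded values."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    header = _metadata_header(results, seed)
    paths = {
        "outcomes": dest / "outcomes.csv",
        "costs": dest / "costs.csv",
        "costs_exact": dest / "costs_exact.csv",
        "sidecar": dest / "results.json",
    }
    for key, frame in (
        ("outcomes", outcomes_frame(results)),
        ("costs", costs_frame(results)),
        ("costs_exact", costs_frame(results, exact=True)),
    ):
        with open(paths[key], "w") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False)
    sidecar = [
        {
            "spec": res.spec.model_dump(),
            "outcome": res.outcome.as_dict(),
            "events": res.events.as_dict(),
            "costs_by_price": {
                str(price): {
                    "cost_screening": cs.cost_screening,
                    "cost_nipt": cs.cost_nipt,
                    "cost_invasive": cs.cost_invasive,
                    "cost_pregnancy_outcomes": cs.cost_pregnancy_outcomes,
                    "total": cs.total,
                }
                for price, cs in res.costs_by_price.items()
            },
        }
        for res in results
    ]
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return paths
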