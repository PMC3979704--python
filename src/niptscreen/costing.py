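"""Cost decomposition of a pathway event ledger.

Components mirror the published table layout: (A) screening, (B) NIPT,
(C) invasive diagnostic testing (which absorbs the cost of procedure-related
miscarriages), plus an optional pregnancy-outcome component (spontaneous
losses, terminations and live births) that is excluded from the headline
comparison because it is large and similar across strategies.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .parameters import CostSchedule, StrategySpec
from .pathways import PathwayEvents


@dataclass(frozen=True)
class CostSummary:
    """GBP cost decomposition for one strategy run (2011/12 prices)."""

    cost_screening: float
    cost_nipt: float
    cost_invasive: float
    cost_pregnancy_outcomes: float = 0.0
    include_pregnancy_outcomes: bool = False

    @property
    def total(self) -> float:
        base = self.cost_screening + self.cost_nipt + self.cost_invasive
        if self.include_pregnancy_outcomes:
            base += self.cost_pregnancy_outcomes
        return base


def cost_events(events: PathwayEvents, costs: CostSchedule, spec: StrategySpec | None = None) -> CostSummary:
    """Price an event ledger.

    Screening: per-test cost by trimester plus repeat NT measurements.
    NIPT: every performed test at full unit price (repeats after sample failure
    included in ``nipt_tests``), plus a separate phlebotomy cost per taker when
    the blood sample is not drawn at the screening visit.
    Invasive: every procedure (including repeats after sample failure) plus the
    cost of procedure-related fetal losses.
    """
    spec = spec or StrategySpec()
    screening = (
        events.screened_t1 * costs.combined_test
        + events.screened_t2 * costs.quadruple_test
        + events.repeat_nt * costs.repeat_nt
    )
    nipt = events.nipt_tests * costs.nipt_unit_cost
    if spec.separate_nipt_blood_draw:
        nipt += events.n_nipt_takers * costs.blood_draw
    invasive = (events.n_invasive + events.invasive_repeats) * costs.invasive_test
    invasive += events.n_procedure_miscarriages * costs.fetal_loss
    outcomes = 0.0
    if spec.include_pregnancy_outcome_costs:
        outcomes = (
            events.n_spontaneous_losses * costs.fetal_loss
            + events.top_t1 * costs.top_first_trimester
            + events.top_t2 * costs.top_second_trimester
            + (events.births_vaginal_affected + events.births_vaginal_unaffected) * costs.vaginal_birth
            + (events.births_caesarean_affected + events.births_caesarean_unaffected) * costs.caesarean_birth
        )
    return CostSummary(
        cost_screening=screening,
        cost_nipt=nipt,
        cost_invasive=invasive,
        cost_pregnancy_outcomes=outcomes,
        include_pregnancy_outcomes=spec.include_pregnancy_outcome_costs,
    )


def total_cost(summary: CostSummary) -> float:
    """Exact component sum in GBP."""
    return summary.total


def round_thousands(amount_gbp: float) -> int:
    """Report helper: GBP rounded half-up to the nearest £1,000 (in £000s)."""
    return int(Decimal(amount_gbp / 1000.0).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def cost_grid_row(
    events: PathwayEvents,
    costs: CostSchedule,
    nipt_prices: list[float],
    spec: StrategySpec | None = None,
) -> list[CostSummary]:
    """Re-price one ledger across NIPT unit prices.

    The ledger is price-independent, so screening and invasive components are
    constant along the row and the NIPT component is linear in price.
    """
    out = []
    for price in nipt_prices:
        priced = costs.model_copy(update={"nipt_unit_cost": float(price)})
        out.append(cost_events(events, priced, spec))
    return out
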