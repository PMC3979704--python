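"""Expected-value evaluation of the three testing strategies.

Each strategy run follows the published pathway diagrams: current screening
(combined test in trimester 1 or quadruple test for late bookers, screen
positives offered an invasive test), NIPT as contingent testing (screen
positives offered NIPT, NIPT positives offered an invasive test) and NIPT as
first-line testing (the whole cohort offered NIPT, positives offered an
invasive test).  The engine propagates expected counts, so every probability in
the parameter bundle acts multiplicatively; the companion microsimulator
(:mod:`niptscreen.microsim`) realizes the same rules woman-by-woman.

Accounting rules:

* every pregnancy ends in exactly one terminal state — spontaneous loss,
  procedure-related miscarriage, termination (TOP), or live birth — so each
  strategy run conserves the cohort exactly;
* a DS case counts as *detected* only on an invasive test result; women who
  decline NIPT or invasive testing are never "detected", and a pregnancy lost
  to the procedure itself is not counted as detected;
* sample failures (NIPT and invasive) trigger exactly one repeat, which incurs
  cost but never blocks completion or adds procedure risk;
* NT measurement failures trigger one repeat measurement (cost only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .cohort import (
    CohortSlice,
    MaternalAgeDistribution,
    PrevalenceModel,
    advance,
    default_prevalence_model,
    initial_cohort,
)
from .parameters import ParameterSet, StrategySpec, TestPerformance, apply_scenario


@dataclass
class StatusPair:
    """A quantity split by affected status."""

    affected: float = 0.0
    unaffected: float = 0.0

    @property
    def total(self) -> float:
        return self.affected + self.unaffected

    def __add__(self, other: "StatusPair") -> "StatusPair":
        return StatusPair(self.affected + other.affected, self.unaffected + other.unaffected)

    def scaled(self, f_affected: float, f_unaffected: float | None = None) -> "StatusPair":
        f_un = f_affected if f_unaffected is None else f_unaffected
        return StatusPair(self.affected * f_affected, self.unaffected * f_un)


@dataclass
class PathwayEvents:
    """Expected event ledger for one strategy run."""

    initial_affected: float = 0.0
    initial_unaffected: float = 0.0
    screened_t1: float = 0.0
    screened_t2: float = 0.0
    repeat_nt: float = 0.0
    screen_positive_affected: float = 0.0
    screen_positive_unaffected: float = 0.0
    nipt_takers_affected: float = 0.0
    nipt_takers_unaffected: float = 0.0
    nipt_tests: float = 0.0
    nipt_positive_affected: float = 0.0
    nipt_positive_unaffected: float = 0.0
    invasive_affected_t1: float = 0.0
    invasive_affected_t2: float = 0.0
    invasive_unaffected_t1: float = 0.0
    invasive_unaffected_t2: float = 0.0
    invasive_repeats: float = 0.0
    procedure_miscarriages_affected: float = 0.0
    procedure_miscarriages_unaffected: float = 0.0
    ds_detected: float = 0.0
    top_t1: float = 0.0
    top_t2: float = 0.0
    spontaneous_losses_affected: float = 0.0
    spontaneous_losses_unaffected: float = 0.0
    births_vaginal_affected: float = 0.0
    births_vaginal_unaffected: float = 0.0
    births_caesarean_affected: float = 0.0
    births_caesarean_unaffected: float = 0.0

    # --- derived totals -------------------------------------------------
    @property
    def n_screened(self) -> float:
        return self.screened_t1 + self.screened_t2

    @property
    def n_nipt_takers(self) -> float:
        return self.nipt_takers_affected + self.nipt_takers_unaffected

    @property
    def n_nipt_positive(self) -> float:
        return self.nipt_positive_affected + self.nipt_positive_unaffected

    @property
    def n_invasive(self) -> float:
        return (
            self.invasive_affected_t1
            + self.invasive_affected_t2
            + self.invasive_unaffected_t1
            + self.invasive_unaffected_t2
        )

    @property
    def n_procedure_miscarriages(self) -> float:
        return self.procedure_miscarriages_affected + self.procedure_miscarriages_unaffected

    @property
    def n_spontaneous_losses(self) -> float:
        return self.spontaneous_losses_affected + self.spontaneous_losses_unaffected

    @property
    def n_tops(self) -> float:
        return self.top_t1 + self.top_t2

    @property
    def n_births(self) -> float:
        return (
            self.births_vaginal_affected
            + self.births_vaginal_unaffected
            + self.births_caesarean_affected
            + self.births_caesarean_unaffected
        )

    @property
    def initial_total(self) -> float:
        return self.initial_affected + self.initial_unaffected

    def terminal_total(self) -> float:
        """Sum over the four terminal states; equals the initial cohort when conserved."""
        return self.n_spontaneous_losses + self.n_procedure_miscarriages + self.n_tops + self.n_births

    def conservation_error(self) -> float:
        return abs(self.initial_total - self.terminal_total())

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class OutcomeSummary:
    """The six headline outcome columns for one strategy."""

    n_screened: float
    n_nipt: float
    n_nipt_positive: float
    n_invasive: float
    n_procedure_miscarriages: float
    n_ds_detected: float

    def rounded(self, ndigits: int = 2) -> "OutcomeSummary":
        return OutcomeSummary(**{f.name: round(getattr(self, f.name), ndigits) for f in fields(self)})

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def summarize_outcomes(events: PathwayEvents) -> OutcomeSummary:
    return OutcomeSummary(
        n_screened=events.n_screened,
        n_nipt=events.n_nipt_takers,
        n_nipt_positive=events.n_nipt_positive,
        n_invasive=events.n_invasive,
        n_procedure_miscarriages=events.n_procedure_miscarriages,
        n_ds_detected=events.ds_detected,
    )


# --------------------------------------------------------------------------
# Stage operators (pure: survival between stages is applied by the caller)
# --------------------------------------------------------------------------

@dataclass
class ScreeningResult:
    takers: CohortSlice
    positives: StatusPair
    negatives: StatusPair
    decliners: StatusPair


def apply_screening(slice_: CohortSlice, perf: TestPerformance, uptake: float) -> ScreeningResult:
    """Offer a screening test to a slice; split into positives/negatives/decliners."""
    takers = slice_.scaled(uptake)
    decliners = StatusPair(slice_.affected - takers.affected, slice_.unaffected - takers.unaffected)
    positives = StatusPair(
        affected=takers.affected * perf.detection_rate,
        unaffected=takers.unaffected * perf.false_positive_rate,
    )
    negatives = StatusPair(
        affected=takers.affected - positives.affected,
        unaffected=takers.unaffected - positives.unaffected,
    )
    return ScreeningResult(takers=takers, positives=positives, negatives=negatives, decliners=decliners)


@dataclass
class NiptResult:
    takers: StatusPair
    tests: float  # including one repeat per sample failure
    positives: StatusPair
    negatives: StatusPair
    decliners: StatusPair


def apply_nipt(candidates: StatusPair, nipt: TestPerformance, uptake: StatusPair) -> NiptResult:
    """Offer NIPT; sample failures are repeated once and always resolve."""
    takers = StatusPair(candidates.affected * uptake.affected, candidates.unaffected * uptake.unaffected)
    decliners = StatusPair(candidates.affected - takers.affected, candidates.unaffected - takers.unaffected)
    tests = takers.total * (1.0 + nipt.sample_failure_rate)
    positives = StatusPair(
        affected=takers.affected * nipt.detection_rate,
        unaffected=takers.unaffected * nipt.false_positive_rate,
    )
    negatives = StatusPair(takers.affected - positives.affected, takers.unaffected - positives.unaffected)
    return NiptResult(takers=takers, tests=tests, positives=positives, negatives=negatives, decliners=decliners)


@dataclass
class InvasiveResult:
    takers: StatusPair
    repeats: float
    miscarriages: StatusPair
    confirmed_ds: float
    cleared_unaffected: float
    false_negative_affected: float
    decliners: StatusPair


def apply_invasive(candidates: StatusPair, test: TestPerformance, uptake: StatusPair) -> InvasiveResult:
    """Offer an invasive diagnostic test (CVS or amniocentesis).

    The procedure miscarries a fraction of takers of either status; a DS
    pregnancy lost to the procedure is not counted as confirmed.  Sample
    failures trigger one repeat procedure (extra test, no extra risk).
    """
    takers = StatusPair(candidates.affected * uptake.affected, candidates.unaffected * uptake.unaffected)
    decliners = StatusPair(candidates.affected - takers.affected, candidates.unaffected - takers.unaffected)
    repeats = takers.total * test.sample_failure_rate
    miscarriages = takers.scaled(test.procedure_miscarriage_rate)
    surviving_affected = takers.affected - miscarriages.affected
    surviving_unaffected = takers.unaffected - miscarriages.unaffected
    confirmed = surviving_affected * test.detection_rate
    return InvasiveResult(
        takers=takers,
        repeats=repeats,
        miscarriages=miscarriages,
        confirmed_ds=confirmed,
        cleared_unaffected=surviving_unaffected,
        false_negative_affected=surviving_affected - confirmed,
        decliners=decliners,
    )


@dataclass
class TopAndBirths:
    top: float
    continuing_affected: float


def apply_top(confirmed_ds: float, top_uptake: float) -> TopAndBirths:
    """Split confirmed diagnoses into terminations and continuing pregnancies."""
    top = confirmed_ds * top_uptake
    return TopAndBirths(top=top, continuing_affected=confirmed_ds - top)


# --------------------------------------------------------------------------
# Strategy runners
# --------------------------------------------------------------------------

@dataclass
class _Flow:
    """Mutable accumulator wiring stage operators into a full pathway."""

    params: ParameterSet
    events: PathwayEvents = field(default_factory=PathwayEvents)

    def lose(self, affected: float, unaffected: float) -> None:
        self.events.spontaneous_losses_affected += affected
        self.events.spontaneous_losses_unaffected += unaffected

    def move(self, slice_: CohortSlice, to_week: int) -> CohortSlice:
        out, lost_a, lost_u = advance(slice_, to_week, self.params.loss_rates)
        self.lose(lost_a, lost_u)
        return out

    def move_pair(self, pair: StatusPair, from_week: int, to_week: int) -> StatusPair:
        slice_ = CohortSlice(pair.affected, pair.unaffected, from_week)
        out = self.move(slice_, to_week)
        return StatusPair(out.affected, out.unaffected)

    def deliver(self, pair: StatusPair, from_week: int) -> None:
        """Propagate a group to term and realize births by mode."""
        term = self.params.timing.term_week
        at_term = self.move_pair(pair, from_week, term)
        v = self.params.vaginal_birth_fraction
        self.events.births_vaginal_affected += at_term.affected * v
        self.events.births_vaginal_unaffected += at_term.unaffected * v
        self.events.births_caesarean_affected += at_term.affected * (1.0 - v)
        self.events.births_caesarean_unaffected += at_term.unaffected * (1.0 - v)

    def top_and_continue(self, confirmed_ds: float, diagnosis_week: int) -> None:
        """Book TOPs at the diagnosis week; decliners continue to term."""
        result = apply_top(confirmed_ds, self.params.uptakes.top_uptake)
        if diagnosis_week <= self.params.timing.first_trimester_top_last_week:
            self.events.top_t1 += result.top
        else:
            self.events.top_t2 += result.top
        self.deliver(StatusPair(affected=result.continuing_affected), diagnosis_week)

    def invasive_stage(
        self,
        candidates: StatusPair,
        week: int,
        test: TestPerformance,
        trimester: int,
    ) -> None:
        """Run the invasive stage from candidates already advanced to ``week``."""
        up = self.params.uptakes
        result = apply_invasive(
            candidates, test, StatusPair(up.invasive_uptake_affected, up.invasive_uptake_unaffected)
        )
        ev = self.events
        if trimester == 1:
            ev.invasive_affected_t1 += result.takers.affected
            ev.invasive_unaffected_t1 += result.takers.unaffected
        else:
            ev.invasive_affected_t2 += result.takers.affected
            ev.invasive_unaffected_t2 += result.takers.unaffected
        ev.invasive_repeats += result.repeats
        ev.procedure_miscarriages_affected += result.miscarriages.affected
        ev.procedure_miscarriages_unaffected += result.miscarriages.unaffected
        ev.ds_detected += result.confirmed_ds
        self.top_and_continue(result.confirmed_ds, week)
        self.deliver(
            StatusPair(result.false_negative_affected, result.cleared_unaffected), week
        )
        self.deliver(result.decliners, week)


def _screening_arms(params: ParameterSet, spec: StrategySpec):
    """The two screening arms: (booking fraction, performance, weeks, invasive test)."""
    t = params.timing
    combined = params.combined_performance(spec.screening_risk_cutoff)
    late = params.uptakes.late_arrival_fraction
    return [
        # (fraction, screen perf, screen week, invasive perf, invasive week,
        #  trimester, nipt week, nipt invasive week, is_t1)
        (1.0 - late, combined, t.combined_screen_week, params.invasive_cvs, t.cvs_week,
         1, t.contingent_nipt_week_t1, t.contingent_invasive_week_t1, True),
        (late, params.quadruple_performance, t.quadruple_screen_week, params.invasive_amnio, t.amnio_week,
         2, t.contingent_nipt_week_t2, t.contingent_invasive_week_t2, False),
    ]


def _run_screening_based(
    params: ParameterSet,
    spec: StrategySpec,
    start: CohortSlice,
    contingent: bool,
) -> PathwayEvents:
    flow = _Flow(params)
    flow.events.initial_affected = start.affected
    flow.events.initial_unaffected = start.unaffected
    up = params.uptakes

    for (frac, perf, screen_week, inv_test, inv_week, trimester, nipt_week, nipt_inv_week, is_t1) in _screening_arms(params, spec):
        arm = start.scaled(frac)
        offered = flow.move(arm, screen_week)
        screen = apply_screening(offered, perf, up.screening_uptake)
        # decliners never tested; carry to term from the screening week
        flow.deliver(screen.decliners, screen_week)
        if is_t1:
            flow.events.screened_t1 += screen.takers.total
            flow.events.repeat_nt += screen.takers.total * params.nt_failure_rate(screen_week)
        else:
            flow.events.screened_t2 += screen.takers.total
        flow.events.screen_positive_affected += screen.positives.affected
        flow.events.screen_positive_unaffected += screen.positives.unaffected
        flow.deliver(screen.negatives, screen_week)

        if not contingent:
            candidates = flow.move_pair(screen.positives, screen_week, inv_week)
            flow.invasive_stage(candidates, inv_week, inv_test, trimester)
        else:
            nipt_candidates = flow.move_pair(screen.positives, screen_week, nipt_week)
            nipt = apply_nipt(
                nipt_candidates,
                params.nipt,
                StatusPair(up.nipt_uptake_affected, up.nipt_uptake_unaffected),
            )
            flow.events.nipt_takers_affected += nipt.takers.affected
            flow.events.nipt_takers_unaffected += nipt.takers.unaffected
            flow.events.nipt_tests += nipt.tests
            flow.events.nipt_positive_affected += nipt.positives.affected
            flow.events.nipt_positive_unaffected += nipt.positives.unaffected
            flow.deliver(nipt.decliners, nipt_week)
            flow.deliver(nipt.negatives, nipt_week)
            candidates = flow.move_pair(nipt.positives, nipt_week, nipt_inv_week)
            flow.invasive_stage(candidates, nipt_inv_week, inv_test, trimester)

    return flow.events


def run_current_screening(
    params: ParameterSet,
    spec: StrategySpec | None = None,
    ages: MaternalAgeDistribution | None = None,
    prev: PrevalenceModel | None = None,
) -> tuple[PathwayEvents, OutcomeSummary]:
    """Current DS screening: combined/quadruple screen, positives offered invasive."""
    spec = spec or StrategySpec(strategy="current")
    params = apply_scenario(params, spec)
    start = initial_cohort(params, ages, prev)
    events = _run_screening_based(params, spec, start, contingent=False)
    return events, summarize_outcomes(events)


def run_contingent_nipt(
    params: ParameterSet,
    spec: StrategySpec | None = None,
    ages: MaternalAgeDistribution | None = None,
    prev: PrevalenceModel | None = None,
) -> tuple[PathwayEvents, OutcomeSummary]:
    """NIPT as contingent testing: screen positives offered NIPT, then invasive."""
    spec = spec or StrategySpec(strategy="contingent_nipt")
    params = apply_scenario(params, spec)
    start = initial_cohort(params, ages, prev)
    events = _run_screening_based(params, spec, start, contingent=True)
    return events, summarize_outcomes(events)


def run_firstline_nipt(
    params: ParameterSet,
    spec: StrategySpec | None = None,
    ages: MaternalAgeDistribution | None = None,
    prev: PrevalenceModel | None = None,
) -> tuple[PathwayEvents, OutcomeSummary]:
    """NIPT as first-line testing: no conventional screening, cohort offered NIPT."""
    spec = spec or StrategySpec(strategy="firstline_nipt")
    params = apply_scenario(params, spec)
    start = initial_cohort(params, ages, prev)
    t = params.timing
    up = params.uptakes
    flow = _Flow(params)
    flow.events.initial_affected = start.affected
    flow.events.initial_unaffected = start.unaffected

    offered = flow.move(start, t.firstline_nipt_week)
    candidates = StatusPair(offered.affected, offered.unaffected)
    uptake = StatusPair(up.nipt_firstline_uptake, up.nipt_firstline_uptake)
    nipt = apply_nipt(candidates, params.nipt, uptake)
    flow.events.nipt_takers_affected = nipt.takers.affected
    flow.events.nipt_takers_unaffected = nipt.takers.unaffected
    flow.events.nipt_tests = nipt.tests
    flow.events.nipt_positive_affected = nipt.positives.affected
    flow.events.nipt_positive_unaffected = nipt.positives.unaffected
    flow.deliver(nipt.decliners, t.firstline_nipt_week)
    flow.deliver(nipt.negatives, t.firstline_nipt_week)
    invasive_candidates = flow.move_pair(nipt.positives, t.firstline_nipt_week, t.firstline_invasive_week)
    flow.invasive_stage(invasive_candidates, t.firstline_invasive_week, params.invasive_cvs, trimester=1)
    return flow.events, summarize_outcomes(flow.events)


_RUNNERS = {
    "current": run_current_screening,
    "contingent_nipt": run_contingent_nipt,
    "firstline_nipt": run_firstline_nipt,
}


def run_strategy(
    params: ParameterSet,
    spec: StrategySpec,
    ages: MaternalAgeDistribution | None = None,
    prev: PrevalenceModel | None = None,
) -> tuple[PathwayEvents, OutcomeSummary]:
    """Dispatch on ``spec.strategy``."""
    return _RUNNERS[spec.strategy](params, spec, ages=ages, prev=prev)
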