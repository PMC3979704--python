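"""Individual-level microsimulator of the screening pathways.

This is the stochastic counterpart of the deterministic expectation engine in
:mod:`niptscreen.pathways`: each woman's trajectory is realized by independent
Bernoulli draws at exactly the same parameter-bundle rates, so tabulated event
counts converge to the engine's expectations by the law of large numbers.  It
serves as an internal validation oracle and as an emulator of the (undeposited)
population data the model family is built on.

Randomness uses a counter-based Philox stream: a fixed-width matrix of uniforms
is drawn with one row per woman, so woman ``i``'s draws depend only on
``(seed, i)`` and growing ``n`` never reshuffles earlier women.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    WEEK_MAX,
    WEEK_MIN,
    MaternalAgeDistribution,
    PrevalenceModel,
    default_prevalence_model,
)
from .parameters import ParameterSet, StrategySpec, apply_scenario
from .pathways import PathwayEvents

# Draw-slot layout: one column of uniforms per stochastic decision.
_N_SLOTS = 16
(_AGE, _AFFECTED, _BOOKING, _UPTAKE, _LOSS, _SCREEN, _NT_FAIL, _NIPT_UPTAKE,
 _NIPT_FAIL, _NIPT_RESULT, _INV_UPTAKE, _INV_FAIL, _INV_MISC, _INV_RESULT,
 _TOP, _MODE) = range(_N_SLOTS)

#: Column order of the per-woman trajectory frame.
WOMAN_COLUMNS = [
    "maternal_age", "affected", "booking_t1", "screened", "screen_positive",
    "repeat_nt", "nipt_taken", "nipt_failed", "nipt_positive", "invasive_taken",
    "invasive_trimester", "invasive_failed", "procedure_miscarriage", "ds_detected",
    "top", "top_trimester", "spontaneous_loss_week", "birth_mode",
]


def _survival_curve(params: ParameterSet, status: str) -> np.ndarray:
    """S(10→w) for w = 10..term_week (index 0 ↔ week 10)."""
    term = params.timing.term_week
    surv = np.ones(term - WEEK_MIN + 1)
    for w in range(WEEK_MIN, term):
        surv[w - WEEK_MIN + 1] = surv[w - WEEK_MIN] * (1.0 - params.loss_rates.hazard(status, w))
    return surv


def _loss_week(u: np.ndarray, surv: np.ndarray) -> np.ndarray:
    """Invert a survival curve: week of spontaneous loss, or -1 for none.

    A woman with uniform ``u`` is still pregnant at the start of week ``w``
    iff ``u < S(10→w)``; she is lost during week ``w`` iff
    ``S(10→w+1) <= u < S(10→w)``.
    """
    # surv is decreasing; count (on the reversed, increasing curve) how many
    # of S(10→term), ..., S(10→10) are <= u: zero means u < S(10→term) (no
    # loss); k >= 1 means u ∈ [S(10→w+1), S(10→w)) with w = term - k
    count = np.searchsorted(surv[::-1], u, side="right")
    week = WEEK_MIN + (len(surv) - 1) - count
    return np.where(count == 0, -1, week)


@dataclass
class SimulatedWoman:
    """One realized trajectory (a named view of a frame row)."""

    maternal_age: int
    affected: bool
    booking_t1: bool
    screened: bool
    screen_positive: bool
    repeat_nt: bool
    nipt_taken: bool
    nipt_failed: bool
    nipt_positive: bool
    invasive_taken: bool
    invasive_trimester: int  # 0 = no invasive test
    invasive_failed: bool
    procedure_miscarriage: bool
    ds_detected: bool
    top: bool
    top_trimester: int  # 0 = no TOP
    spontaneous_loss_week: int  # -1 = none
    birth_mode: str  # "vaginal", "caesarean" or "" if no live birth


def simulate_women(
    params: ParameterSet,
    spec: StrategySpec,
    n: int,
    seed: int,
    ages: MaternalAgeDistribution | None = None,
    prev: PrevalenceModel | None = None,
) -> pd.DataFrame:
    """Simulate ``n`` independent trajectories under one strategy.

    Returns a DataFrame with one row per woman and columns
    :data:`WOMAN_COLUMNS`; use :func:`tabulate_events` to reduce it to the
    deterministic engine's ledger shape, and ``df.itertuples()`` /
    :class:`SimulatedWoman` for per-woman inspection.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    params = apply_scenario(params, spec)
    ages = ages or MaternalAgeDistribution.england_default()
    prev = prev or default_prevalence_model(ages, params.loss_rates)
    t = params.timing
    up = params.uptakes

    rng = np.random.Generator(np.random.Philox(key=seed))
    u = rng.random((n, _N_SLOTS))

    age_cdf = np.cumsum(ages.proportions)
    age = ages.ages[np.searchsorted(age_cdf, u[:, _AGE], side="right").clip(max=len(ages.ages) - 1)]
    prev10 = np.asarray(prev.prevalence(age, WEEK_MIN))
    affected = u[:, _AFFECTED] < prev10

    surv_a = _survival_curve(params, "affected")
    surv_u = _survival_curve(params, "unaffected")
    loss_week = np.where(affected, _loss_week(u[:, _LOSS], surv_a), _loss_week(u[:, _LOSS], surv_u))
    alive_at = lambda week: (loss_week == -1) | (loss_week >= week)  # noqa: E731

    booking_t1 = u[:, _BOOKING] < (1.0 - up.late_arrival_fraction)

    screened = np.zeros(n, dtype=bool)
    screen_positive = np.zeros(n, dtype=bool)
    repeat_nt = np.zeros(n, dtype=bool)
    nipt_taken = np.zeros(n, dtype=bool)
    nipt_failed = np.zeros(n, dtype=bool)
    nipt_positive = np.zeros(n, dtype=bool)
    invasive_taken = np.zeros(n, dtype=bool)
    invasive_failed = np.zeros(n, dtype=bool)
    procedure_misc = np.zeros(n, dtype=bool)
    detected = np.zeros(n, dtype=bool)
    top = np.zeros(n, dtype=bool)
    top_trimester = np.zeros(n, dtype=int)
    invasive_week = np.zeros(n, dtype=int)

    def bernoulli(slot: int, p: np.ndarray | float) -> np.ndarray:
        return u[:, slot] < p

    if spec.strategy in ("current", "contingent_nipt"):
        combined = params.combined_performance(spec.screening_risk_cutoff)
        quad = params.quadruple_performance
        screen_week = np.where(booking_t1, t.combined_screen_week, t.quadruple_screen_week)
        wants_screen = bernoulli(_UPTAKE, up.screening_uptake)
        screened = wants_screen & alive_at(screen_week)
        dr = np.where(booking_t1, combined.detection_rate, quad.detection_rate)
        fpr = np.where(booking_t1, combined.false_positive_rate, quad.false_positive_rate)
        p_pos = np.where(affected, dr, fpr)
        screen_positive = screened & bernoulli(_SCREEN, p_pos)
        repeat_nt = screened & booking_t1 & bernoulli(_NT_FAIL, params.nt_failure_rate(t.combined_screen_week))

        invasive_trimester_if_taken = np.where(booking_t1, 1, 2)
        if spec.strategy == "current":
            invasive_week = np.where(booking_t1, t.cvs_week, t.amnio_week)
            wants_invasive = bernoulli(
                _INV_UPTAKE, np.where(affected, up.invasive_uptake_affected, up.invasive_uptake_unaffected)
            )
            invasive_taken = screen_positive & wants_invasive & alive_at(invasive_week)
        else:
            nipt_week = np.where(booking_t1, t.contingent_nipt_week_t1, t.contingent_nipt_week_t2)
            invasive_week = np.where(booking_t1, t.contingent_invasive_week_t1, t.contingent_invasive_week_t2)
            wants_nipt = bernoulli(
                _NIPT_UPTAKE, np.where(affected, up.nipt_uptake_affected, up.nipt_uptake_unaffected)
            )
            nipt_taken = screen_positive & wants_nipt & alive_at(nipt_week)
            nipt_failed = nipt_taken & bernoulli(_NIPT_FAIL, params.nipt.sample_failure_rate)
            p_nipt_pos = np.where(affected, params.nipt.detection_rate, params.nipt.false_positive_rate)
            nipt_positive = nipt_taken & bernoulli(_NIPT_RESULT, p_nipt_pos)
            wants_invasive = bernoulli(
                _INV_UPTAKE, np.where(affected, up.invasive_uptake_affected, up.invasive_uptake_unaffected)
            )
            invasive_taken = nipt_positive & wants_invasive & alive_at(invasive_week)
        inv_fail_rate = np.where(
            booking_t1, params.invasive_cvs.sample_failure_rate, params.invasive_amnio.sample_failure_rate
        )
        inv_misc_rate = np.where(
            booking_t1,
            params.invasive_cvs.procedure_miscarriage_rate,
            params.invasive_amnio.procedure_miscarriage_rate,
        )
        inv_dr = np.where(booking_t1, params.invasive_cvs.detection_rate, params.invasive_amnio.detection_rate)
    elif spec.strategy == "firstline_nipt":
        nipt_week = np.full(n, t.firstline_nipt_week)
        invasive_week = np.full(n, t.firstline_invasive_week)
        wants_nipt = bernoulli(_UPTAKE, up.nipt_firstline_uptake)
        nipt_taken = wants_nipt & alive_at(nipt_week)
        nipt_failed = nipt_taken & bernoulli(_NIPT_FAIL, params.nipt.sample_failure_rate)
        p_nipt_pos = np.where(affected, params.nipt.detection_rate, params.nipt.false_positive_rate)
        nipt_positive = nipt_taken & bernoulli(_NIPT_RESULT, p_nipt_pos)
        wants_invasive = bernoulli(
            _INV_UPTAKE, np.where(affected, up.invasive_uptake_affected, up.invasive_uptake_unaffected)
        )
        invasive_taken = nipt_positive & wants_invasive & alive_at(invasive_week)
        inv_fail_rate = np.full(n, params.invasive_cvs.sample_failure_rate)
        inv_misc_rate = np.full(n, params.invasive_cvs.procedure_miscarriage_rate)
        inv_dr = np.full(n, params.invasive_cvs.detection_rate)
        invasive_trimester_if_taken = np.ones(n, dtype=int)
    else:
        raise ValueError(f"unknown strategy {spec.strategy!r}")

    invasive_trimester = np.where(invasive_taken, invasive_trimester_if_taken, 0)
    invasive_failed = invasive_taken & bernoulli(_INV_FAIL, inv_fail_rate)
    procedure_misc = invasive_taken & bernoulli(_INV_MISC, inv_misc_rate)
    detected = invasive_taken & ~procedure_misc & affected & bernoulli(_INV_RESULT, inv_dr)

    top = detected & bernoulli(_TOP, up.top_uptake)
    top_trimester = np.where(
        top, np.where(invasive_week <= t.first_trimester_top_last_week, 1, 2), 0
    )

    # terminal-state partition: an invasive event at week w already required
    # survival to w, so procedural miscarriage and TOP (both at w) pre-empt
    # any spontaneous loss, which by construction falls in week >= w
    spont_loss = (loss_week != -1) & ~procedure_misc & ~top
    live_birth = (loss_week == -1) & ~procedure_misc & ~top
    birth_mode = np.where(
        live_birth, np.where(u[:, _MODE] < params.vaginal_birth_fraction, "vaginal", "caesarean"), ""
    )
    loss_week_out = np.where(spont_loss, loss_week, -1)

    return pd.DataFrame(
        {
            "maternal_age": age,
            "affected": affected,
            "booking_t1": booking_t1,
            "screened": screened,
            "screen_positive": screen_positive,
            "repeat_nt": repeat_nt,
            "nipt_taken": nipt_taken,
            "nipt_failed": nipt_failed,
            "nipt_positive": nipt_positive,
            "invasive_taken": invasive_taken,
            "invasive_trimester": invasive_trimester,
            "invasive_failed": invasive_failed,
            "procedure_miscarriage": procedure_misc,
            "ds_detected": detected,
            "top": top,
            "top_trimester": top_trimester,
            "spontaneous_loss_week": loss_week_out,
            "birth_mode": birth_mode,
        }
    )


def tabulate_events(women: pd.DataFrame) -> PathwayEvents:
    """Reduce realized trajectories to the deterministic engine's ledger shape."""
    w = women
    aff = w["affected"]
    t1 = w["booking_t1"]
    return PathwayEvents(
        initial_affected=float(aff.sum()),
        initial_unaffected=float((~aff).sum()),
        screened_t1=float((w["screened"] & t1).sum()),
        screened_t2=float((w["screened"] & ~t1).sum()),
        repeat_nt=float(w["repeat_nt"].sum()),
        screen_positive_affected=float((w["screen_positive"] & aff).sum()),
        screen_positive_unaffected=float((w["screen_positive"] & ~aff).sum()),
        nipt_takers_affected=float((w["nipt_taken"] & aff).sum()),
        nipt_takers_unaffected=float((w["nipt_taken"] & ~aff).sum()),
        nipt_tests=float(w["nipt_taken"].sum() + w["nipt_failed"].sum()),
        nipt_positive_affected=float((w["nipt_positive"] & aff).sum()),
        nipt_positive_unaffected=float((w["nipt_positive"] & ~aff).sum()),
        invasive_affected_t1=float(((w["invasive_trimester"] == 1) & aff).sum()),
        invasive_affected_t2=float(((w["invasive_trimester"] == 2) & aff).sum()),
        invasive_unaffected_t1=float(((w["invasive_trimester"] == 1) & ~aff).sum()),
        invasive_unaffected_t2=float(((w["invasive_trimester"] == 2) & ~aff).sum()),
        invasive_repeats=float(w["invasive_failed"].sum()),
        procedure_miscarriages_affected=float((w["procedure_miscarriage"] & aff).sum()),
        procedure_miscarriages_unaffected=float((w["procedure_miscarriage"] & ~aff).sum()),
        ds_detected=float(w["ds_detected"].sum()),
        top_t1=float((w["top_trimester"] == 1).sum()),
        top_t2=float((w["top_trimester"] == 2).sum()),
        spontaneous_losses_affected=float(((w["spontaneous_loss_week"] >= 0) & aff).sum()),
        spontaneous_losses_unaffected=float(((w["spontaneous_loss_week"] >= 0) & ~aff).sum()),
        births_vaginal_affected=float(((w["birth_mode"] == "vaginal") & aff).sum()),
        births_vaginal_unaffected=float(((w["birth_mode"] == "vaginal") & ~aff).sum()),
        births_caesarean_affected=float(((w["birth_mode"] == "caesarean") & aff).sum()),
        births_caesarean_unaffected=float(((w["birth_mode"] == "caesarean") & ~aff).sum()),
    )


# Ledger fields compared between simulation and expectation (counts of events).
_COMPARED_FIELDS = [
    "screened_t1", "screened_t2", "repeat_nt",
    "screen_positive_affected", "screen_positive_unaffected",
    "nipt_takers_affected", "nipt_takers_unaffected", "nipt_tests",
    "nipt_positive_affected", "nipt_positive_unaffected",
    "invasive_affected_t1", "invasive_affected_t2",
    "invasive_unaffected_t1", "invasive_unaffected_t2",
    "invasive_repeats", "procedure_miscarriages_affected",
    "procedure_miscarriages_unaffected", "ds_detected", "top_t1", "top_t2",
    "spontaneous_losses_affected", "spontaneous_losses_unaffected",
    "births_vaginal_affected", "births_vaginal_unaffected",
    "births_caesarean_affected", "births_caesarean_unaffected",
]


def compare_to_expectation(
    simulated: PathwayEvents, expected: PathwayEvents, n: int, flag_threshold: float = 3.0
) -> pd.DataFrame:
    """Per-field z-scores of realized counts against expected counts.

    ``expected`` must be scaled to the same cohort size ``n`` as the
    simulation.  The standard error is binomial, ``sqrt(n·p·(1-p))`` with
    ``p = expected/n``; fields that are structurally zero under the strategy
    (expected == observed == 0) get z = 0.
    """
    import math

    if abs(expected.initial_total - n) > 1e-6 * max(n, 1):
        raise ValueError(
            f"expected ledger cohort size {expected.initial_total} does not match simulation n={n}"
        )
    rows = []
    for name in _COMPARED_FIELDS:
        obs = getattr(simulated, name)
        exp = getattr(expected, name)
        p = min(max(exp / n, 0.0), 1.0)
        se = math.sqrt(n * p * (1.0 - p))
        if se == 0.0:
            z = 0.0 if obs == exp else math.inf
        else:
            z = (obs - exp) / se
        rows.append({"field": name, "observed": obs, "expected": exp, "z": z, "flag": abs(z) > flag_threshold})
    return pd.DataFrame(rows)
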