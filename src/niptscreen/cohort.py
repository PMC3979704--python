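"""Cohort construction and gestational-week dynamics.

The model follows an expected-value cohort of pregnancies from gestational week
10 to term (week 40).  Two ingredients define the cohort: a maternal-age
distribution (single years, ≤13 through ≥50) and a Down's syndrome prevalence
surface over (maternal age, gestational week).  The prevalence surface is
packaged as a term-risk-by-age table back-projected to earlier weeks with the
weekly loss hazards: because affected pregnancies miscarry at a much higher
weekly rate, prevalence at week 10 exceeds prevalence at term for every age.

Week convention: the weekly hazard for week ``w`` applies between the start of
week ``w`` and the start of week ``w+1``; surviving "to week ``t``" means
surviving weeks ``f..t-1``.  Live birth happens at the start of the term week.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import LossRates, ParameterSet

WEEK_MIN, WEEK_MAX = 10, 40

AGE_MIN, AGE_MAX = 13, 50  # bins: ≤13, 14, ..., 49, ≥50


def survival_probability(status: str, from_week: int, to_week: int, rates: LossRates) -> float:
    """Probability a pregnancy of ``status`` survives from ``from_week`` to ``to_week``.

    Product over weeks w in [from_week, to_week) of (1 - hazard(status, w)).
    """
    if not (WEEK_MIN <= from_week <= to_week <= WEEK_MAX):
        raise ValueError(f"require {WEEK_MIN} <= from_week <= to_week <= {WEEK_MAX}, got ({from_week}, {to_week})")
    prob = 1.0
    for week in range(from_week, to_week):
        prob *= 1.0 - rates.hazard(status, week)
    return prob


@dataclass(frozen=True)
class MaternalAgeDistribution:
    """Proportion of pregnancies per single year of maternal age."""

    ages: np.ndarray
    proportions: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        props = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "proportions", props)
        if ages.shape != props.shape or ages.ndim != 1:
            raise ValueError("ages and proportions must be matching 1-D arrays")
        if np.any(props < 0):
            raise ValueError("age proportions must be non-negative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"age proportions must sum to 1 (got {props.sum():.12f})")

    @classmethod
    def england_default(cls) -> "MaternalAgeDistribution":
        """Packaged England-like maternity age curve.

        A unimodal curve peaked near age 30 (mean ≈ 29.7 years, in line with
        national maternity statistics), floored at 0.0024 per year in the tails
        and normalized to 1.  User-replaceable via :meth:`from_csv`.
        """
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
        weights = np.exp(-0.5 * ((ages - 29.7) / 5.9) ** 2)
        props = weights / weights.sum()
        floor = 0.0024
        for _ in range(10):
            low = props < floor
            props = props.copy()
            props[low] = floor
            props[~low] *= (1.0 - floor * low.sum()) / props[~low].sum()
        props = props / props.sum()
        return cls(ages=ages, proportions=props)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MaternalAgeDistribution":
        """Load from a two-column CSV with header exactly ``age,proportion``."""
        frame = pd.read_csv(path)
        if list(frame.columns) != ["age", "proportion"]:
            raise ValueError(f"expected header 'age,proportion', got {list(frame.columns)}")
        frame = frame.sort_values("age")
        return cls(ages=frame["age"].to_numpy(), proportions=frame["proportion"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "proportion": self.proportions}).to_csv(path, index=False)

    def mean_age(self) -> float:
        return float(np.sum(self.ages * self.proportions))


@dataclass(frozen=True)
class PrevalenceModel:
    """DS prevalence as a function of (maternal age, gestational week).

    Holds a term-risk table (prevalence among pregnancies alive at the term
    week) and back-projects it to earlier weeks through the differential loss
    hazards: if ``p`` is the term prevalence then the week-``w`` odds are the
    term odds multiplied by ``S_unaffected(w→term) / S_affected(w→term)``.
    """

    ages: np.ndarray
    term_risk: np.ndarray
    loss_rates: LossRates
    term_week: int = WEEK_MAX

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        risk = np.asarray(self.term_risk, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "term_risk", risk)
        if ages.shape != risk.shape or ages.ndim != 1:
            raise ValueError("ages and term_risk must be matching 1-D arrays")
        if np.any((risk < 0) | (risk >= 1)):
            raise ValueError("term risks must lie in [0, 1)")

    def prevalence(self, age: int | np.ndarray, week: int) -> np.ndarray | float:
        """Prevalence of DS among pregnancies alive at the start of ``week``."""
        idx = np.searchsorted(self.ages, np.clip(age, self.ages[0], self.ages[-1]))
        p_term = self.term_risk[idx]
        s_a = survival_probability("affected", week, self.term_week, self.loss_rates)
        s_u = survival_probability("unaffected", week, self.term_week, self.loss_rates)
        odds = p_term / (1.0 - p_term) * (s_u / s_a)
        return odds / (1.0 + odds)

    def cohort_prevalence(self, ages: MaternalAgeDistribution, week: int) -> float:
        """Age-marginal prevalence at ``week`` for a given age distribution."""
        return float(np.sum(ages.proportions * self.prevalence(ages.ages, week)))

    @classmethod
    def from_csv(cls, path: str | Path, loss_rates: LossRates) -> "PrevalenceModel":
        """Load a term-risk table from a CSV with header exactly ``age,term_risk``."""
        frame = pd.read_csv(path)
        if list(frame.columns) != ["age", "term_risk"]:
            raise ValueError(f"expected header 'age,term_risk', got {list(frame.columns)}")
        frame = frame.sort_values("age")
        return cls(ages=frame["age"].to_numpy(), term_risk=frame["term_risk"].to_numpy(), loss_rates=loss_rates)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "term_risk": self.term_risk}).to_csv(path, index=False)


#: Packaged calibration: expected cohort prevalence at week 10.  2.5 per 1,000
#: pregnancies is consistent with national early-pregnancy estimates for an
#: England-age-structured cohort and keeps the packaged surface inside the
#: published 0.1-2.6% band.
DEFAULT_WEEK10_PREVALENCE = 0.0025

_TERM_RISK_FLOOR = 0.0012
_TERM_RISK_CAP = 0.0150
_AGE_SLOPE = 0.2862  # per year, exponential rise of DS risk with maternal age


def default_prevalence_model(
    ages: MaternalAgeDistribution | None = None,
    loss_rates: LossRates | None = None,
    week10_prevalence: float = DEFAULT_WEEK10_PREVALENCE,
) -> PrevalenceModel:
    """Packaged term-risk-by-age table, calibrated to a week-10 cohort prevalence.

    The curve is ``min(floor + k·exp(slope·(age-45)), cap)`` with ``k`` solved
    by bisection so that the age-marginal prevalence at week 10 equals
    ``week10_prevalence``.  The floor (0.0012) and cap (0.0150) pin the whole
    (age × week) surface inside [0.001, 0.026].  This is an approximation of
    the national risk tables the model family uses, replaceable via
    :meth:`PrevalenceModel.from_csv`.
    """
    ages = ages or MaternalAgeDistribution.england_default()
    loss_rates = loss_rates or LossRates()
    shape = np.exp(_AGE_SLOPE * (ages.ages - 45.0))

    def model_for(k: float) -> PrevalenceModel:
        risk = np.minimum(_TERM_RISK_FLOOR + k * shape, _TERM_RISK_CAP)
        return PrevalenceModel(ages=ages.ages, term_risk=risk, loss_rates=loss_rates)

    lo, hi = 0.0, 1.0
    if model_for(hi).cohort_prevalence(ages, WEEK_MIN) < week10_prevalence:
        raise ValueError(f"target week-10 prevalence {week10_prevalence} not attainable under the risk cap")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if model_for(mid).cohort_prevalence(ages, WEEK_MIN) < week10_prevalence:
            lo = mid
        else:
            hi = mid
    return model_for(0.5 * (lo + hi))


@dataclass(frozen=True)
class CohortSlice:
    """Expected pregnancy counts by affected status at one gestational week."""

    affected: float
    unaffected: float
    gestational_week: int

    def __post_init__(self) -> None:
        if self.affected < 0 or self.unaffected < 0:
            raise ValueError("cohort counts must be non-negative")
        if not WEEK_MIN <= self.gestational_week <= WEEK_MAX:
            raise ValueError(f"gestational week {self.gestational_week} outside [{WEEK_MIN}, {WEEK_MAX}]")

    @property
    def total(self) -> float:
        return self.affected + self.unaffected

    def scaled(self, factor: float) -> "CohortSlice":
        return replace(self, affected=self.affected * factor, unaffected=self.unaffected * factor)


def initial_cohort(
    params: ParameterSet,
    ages: MaternalAgeDistribution | None = None,
    prev: PrevalenceModel | None = None,
) -> CohortSlice:
    """Expected affected/unaffected split of the cohort at week 10.

    ``affected + unaffected == cohort_size`` exactly; the affected count is the
    cohort size times the age-marginal week-10 prevalence.
    """
    ages = ages or MaternalAgeDistribution.england_default()
    prev = prev or default_prevalence_model(ages, params.loss_rates)
    p10 = prev.cohort_prevalence(ages, WEEK_MIN)
    affected = params.cohort_size * p10
    return CohortSlice(affected=affected, unaffected=params.cohort_size - affected, gestational_week=WEEK_MIN)


def advance(slice_: CohortSlice, to_week: int, rates: LossRates) -> tuple[CohortSlice, float, float]:
    """Propagate a slice forward under the loss hazards.

    Returns ``(new_slice, affected_losses, unaffected_losses)`` with exact
    conservation: out-counts plus losses equal in-counts.
    """
    if to_week < slice_.gestational_week:
        raise ValueError(f"cannot advance backwards from week {slice_.gestational_week} to {to_week}")
    s_aff = survival_probability("affected", slice_.gestational_week, to_week, rates)
    s_un = survival_probability("unaffected", slice_.gestational_week, to_week, rates)
    out = CohortSlice(
        affected=slice_.affected * s_aff,
        unaffected=slice_.unaffected * s_un,
        gestational_week=to_week,
    )
    return out, slice_.affected - out.affected, slice_.unaffected - out.unaffected
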