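"""Model parameter bundle: definition, validation, defaults and scenario presets.

All probabilities are stored as proportions in [0, 1] (printed percentages are
converted once when the packaged defaults are transcribed).  All unit costs are
2011/12 GBP.  The bundle is a strict schema: unknown keys in a configuration
document are rejected rather than silently ignored, because a typo in a scenario
override would otherwise corrupt a strategy comparison without warning.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Any, Literal, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

Probability = Field(ge=0.0, le=1.0)

#: Risk cut-offs (1 in N) for which combined-test performance is packaged.
COMBINED_CUTOFFS = (150, 500, 1000, 2000)

#: Uptake scenario identifiers.
SCENARIO_NAMES = ("base_contingent", "nipt_100", "nipt_100_screen_79", "firstline_79")

StrategyName = Literal["current", "contingent_nipt", "firstline_nipt"]
UptakeScenario = Literal["base", "nipt_100", "nipt_100_screen_79", "firstline_79"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True, frozen=False)


class TestPerformance(_StrictModel):
    """Operating characteristics of one test (screening, NIPT or invasive)."""

    detection_rate: float = Probability
    false_positive_rate: float = Probability
    sample_failure_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    procedure_miscarriage_rate: float = Field(default=0.0, ge=0.0, le=1.0)


class LossRates(_StrictModel):
    """Weekly hazard of spontaneous fetal loss, piecewise constant in gestational week.

    Unaffected pregnancies: 0.0012/week over weeks 10-25 and 0.00034/week over
    weeks 26-40.  Down's-affected pregnancies: 0.07067/week over weeks 10-15 and
    0.0051/week over weeks 16-40.  An optional hook for age-varying unaffected
    hazards exists (``unaffected_by_age``) but no default data are packaged.
    """

    unaffected_weeks_10_25: float = Field(default=0.0012, ge=0.0, lt=1.0)
    unaffected_weeks_26_40: float = Field(default=0.00034, ge=0.0, lt=1.0)
    affected_weeks_10_15: float = Field(default=0.07067, ge=0.0, lt=1.0)
    affected_weeks_16_40: float = Field(default=0.0051, ge=0.0, lt=1.0)
    unaffected_by_age: dict[int, float] | None = None

    def hazard(self, status: str, week: int) -> float:
        """Weekly loss hazard for ``status`` ("affected"/"unaffected") at ``week``."""
        if not 10 <= week <= 40:
            raise ValueError(f"gestational week {week} outside [10, 40]")
        if status == "affected":
            return self.affected_weeks_10_15 if week <= 15 else self.affected_weeks_16_40
        if status == "unaffected":
            return self.unaffected_weeks_10_25 if week <= 25 else self.unaffected_weeks_26_40
        raise ValueError(f"unknown affected status {status!r}")


class UptakeRates(_StrictModel):
    """Uptake proportions along the pathway."""

    screening_uptake: float = Field(default=0.69, ge=0.0, le=1.0)
    late_arrival_fraction: float = Field(default=0.15, ge=0.0, le=1.0)
    invasive_uptake_unaffected: float = Field(default=0.80, ge=0.0, le=1.0)
    invasive_uptake_affected: float = Field(default=0.90, ge=0.0, le=1.0)
    nipt_uptake_unaffected: float = Field(default=0.80, ge=0.0, le=1.0)
    nipt_uptake_affected: float = Field(default=0.90, ge=0.0, le=1.0)
    nipt_firstline_uptake: float = Field(default=0.69, ge=0.0, le=1.0)
    top_uptake: float = Field(default=0.921, ge=0.0, le=1.0)


class CostSchedule(_StrictModel):
    """Unit costs in 2011/12 GBP.

    ``repeat_nt`` is not printed in the source cost schedule; the default of
    £6.50 is a package-level calibration so that the screening cost component of
    the reference run lands at the published ~£200k (see docs/methods.md).
    """

    combined_test: float = Field(default=27.0, ge=0.0)
    quadruple_test: float = Field(default=35.0, ge=0.0)
    invasive_test: float = Field(default=479.0, ge=0.0)
    fetal_loss: float = Field(default=511.0, ge=0.0)
    top_first_trimester: float = Field(default=697.0, ge=0.0)
    top_second_trimester: float = Field(default=882.0, ge=0.0)
    vaginal_birth: float = Field(default=1341.0, ge=0.0)
    caesarean_birth: float = Field(default=2436.0, ge=0.0)
    nipt_unit_cost: float = Field(default=500.0, ge=0.0)
    blood_draw: float = Field(default=3.0, ge=0.0)
    repeat_nt: float = Field(default=6.50, ge=0.0)


class EventTiming(_StrictModel):
    """Gestational weeks at which pathway events are booked.

    The published pathway diagrams give windows, not single weeks (combined
    test 11-14, quadruple after 14); these defaults sit inside those windows
    and are fully configurable.
    """

    combined_screen_week: int = Field(default=12, ge=10, le=40)
    cvs_week: int = Field(default=13, ge=10, le=40)
    quadruple_screen_week: int = Field(default=16, ge=10, le=40)
    amnio_week: int = Field(default=17, ge=10, le=40)
    contingent_nipt_week_t1: int = Field(default=13, ge=10, le=40)
    contingent_invasive_week_t1: int = Field(default=14, ge=10, le=40)
    contingent_nipt_week_t2: int = Field(default=17, ge=10, le=40)
    contingent_invasive_week_t2: int = Field(default=18, ge=10, le=40)
    firstline_nipt_week: int = Field(default=11, ge=10, le=40)
    firstline_invasive_week: int = Field(default=12, ge=10, le=40)
    term_week: int = Field(default=40, ge=10, le=40)
    #: diagnoses at or before this week are costed as first-trimester TOPs
    first_trimester_top_last_week: int = Field(default=14, ge=10, le=40)


class StrategySpec(_StrictModel):
    """Which strategy to run and under which reporting options."""

    strategy: StrategyName = "current"
    screening_risk_cutoff: int = 150
    uptake_scenario: UptakeScenario = "base"
    include_pregnancy_outcome_costs: bool = False
    separate_nipt_blood_draw: bool = False

    @model_validator(mode="after")
    def _check_combination(self) -> "StrategySpec":
        if self.screening_risk_cutoff not in COMBINED_CUTOFFS:
            raise ValueError(
                f"screening_risk_cutoff: unknown cut-off {self.screening_risk_cutoff}; "
                f"packaged cut-offs are {COMBINED_CUTOFFS}"
            )
        if self.uptake_scenario == "firstline_79" and self.strategy != "firstline_nipt":
            raise ValueError("uptake_scenario 'firstline_79' requires strategy 'firstline_nipt'")
        if self.uptake_scenario in ("nipt_100", "nipt_100_screen_79") and self.strategy != "contingent_nipt":
            raise ValueError(f"uptake_scenario {self.uptake_scenario!r} requires strategy 'contingent_nipt'")
        return self


class ParameterSet(_StrictModel):
    """The complete validated input bundle for one model run."""

    cohort_size: float = Field(default=10_000.0, ge=0.0)
    combined_performance_by_cutoff: dict[int, TestPerformance] = Field(
        default_factory=lambda: {
            150: TestPerformance(detection_rate=0.85, false_positive_rate=0.025),
            500: TestPerformance(detection_rate=0.94, false_positive_rate=0.07),
            1000: TestPerformance(detection_rate=0.96, false_positive_rate=0.12),
            2000: TestPerformance(detection_rate=0.98, false_positive_rate=0.19),
        }
    )
    quadruple_performance: TestPerformance = Field(
        default_factory=lambda: TestPerformance(detection_rate=0.805, false_positive_rate=0.04)
    )
    invasive_cvs: TestPerformance = Field(
        default_factory=lambda: TestPerformance(
            detection_rate=1.0,
            false_positive_rate=0.0,
            sample_failure_rate=0.013,
            procedure_miscarriage_rate=0.005,
        )
    )
    invasive_amnio: TestPerformance = Field(
        default_factory=lambda: TestPerformance(
            detection_rate=1.0,
            false_positive_rate=0.0,
            sample_failure_rate=0.008,
            procedure_miscarriage_rate=0.005,
        )
    )
    nipt: TestPerformance = Field(
        default_factory=lambda: TestPerformance(
            detection_rate=0.99,
            false_positive_rate=0.01,
            sample_failure_rate=0.05,
            procedure_miscarriage_rate=0.0,
        )
    )
    #: NT measurement failure, linear in week between the two anchors (range 14-19%)
    nt_failure_week11: float = Field(default=0.14, ge=0.0, le=1.0)
    nt_failure_week14: float = Field(default=0.19, ge=0.0, le=1.0)
    vaginal_birth_fraction: float = Field(default=0.752, ge=0.0, le=1.0)
    caesarean_birth_fraction: float = Field(default=0.248, ge=0.0, le=1.0)
    loss_rates: LossRates = Field(default_factory=LossRates)
    uptakes: UptakeRates = Field(default_factory=UptakeRates)
    costs: CostSchedule = Field(default_factory=CostSchedule)
    timing: EventTiming = Field(default_factory=EventTiming)

    @model_validator(mode="after")
    def _check_consistency(self) -> "ParameterSet":
        cutoffs = sorted(self.combined_performance_by_cutoff)
        drs = [self.combined_performance_by_cutoff[c].detection_rate for c in cutoffs]
        fprs = [self.combined_performance_by_cutoff[c].false_positive_rate for c in cutoffs]
        if any(b <= a for a, b in zip(drs, drs[1:])):
            raise ValueError("combined_performance_by_cutoff: detection rate must be strictly increasing in cut-off denominator")
        if any(b <= a for a, b in zip(fprs, fprs[1:])):
            raise ValueError("combined_performance_by_cutoff: false positive rate must be strictly increasing in cut-off denominator")
        if abs(self.vaginal_birth_fraction + self.caesarean_birth_fraction - 1.0) > 1e-9:
            raise ValueError("vaginal_birth_fraction + caesarean_birth_fraction must equal 1")
        return self

    def nt_failure_rate(self, week: int) -> float:
        """NT measurement failure probability at ``week`` (clamped linear interpolation)."""
        w = min(max(week, 11), 14)
        frac = (w - 11) / 3.0
        return self.nt_failure_week11 + frac * (self.nt_failure_week14 - self.nt_failure_week11)

    def combined_performance(self, cutoff: int) -> TestPerformance:
        try:
            return self.combined_performance_by_cutoff[cutoff]
        except KeyError:
            raise KeyError(
                f"combined_performance_by_cutoff: unknown cut-off {cutoff}; "
                f"available: {sorted(self.combined_performance_by_cutoff)}"
            ) from None


def default_parameters() -> ParameterSet:
    """The packaged default bundle (published base-case inputs)."""
    return ParameterSet()


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def to_document(params: ParameterSet) -> dict[str, Any]:
    """Serialize a ParameterSet to a plain dict (YAML/JSON friendly)."""
    return params.model_dump(mode="json")


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(to_document(params), sort_keys=False))


def load_parameters(config_source: str | Path | io.TextIOBase | Mapping | None) -> ParameterSet:
    """Load a parameter bundle from a YAML/JSON document, defaulting unset keys.

    ``config_source`` may be a path, an open text stream, a mapping, a YAML/JSON
    string, or None/empty (pure defaults).  Unknown keys and out-of-range values
    raise ``ValueError`` naming the offending key path.
    """
    if config_source is None or (isinstance(config_source, str) and not config_source.strip()):
        doc: Any = {}
    elif isinstance(config_source, Mapping):
        doc = dict(config_source)
    elif isinstance(config_source, io.TextIOBase):
        doc = yaml.safe_load(config_source.read())
    elif isinstance(config_source, Path) or (
        isinstance(config_source, str)
        and "\n" not in config_source
        and Path(config_source).is_file()
    ):
        doc = yaml.safe_load(Path(config_source).read_text())
    else:
        doc = yaml.safe_load(config_source)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError("parameter document must be a mapping at the top level")
    merged = _deep_merge(to_document(default_parameters()), doc)
    try:
        return ParameterSet.model_validate(merged)
    except Exception as exc:  # re-raise with a stable type, keep pydantic's key paths
        raise ValueError(f"invalid parameter document: {exc}") from exc


def scenario_presets(name: str) -> tuple[dict[str, Any], StrategySpec]:
    """Override bundle and strategy spec for one published uptake scenario.

    Returns a (parameter-overrides, StrategySpec) pair; apply the overrides via
    ``apply_overrides``.
    """
    if name == "base_contingent":
        return {}, StrategySpec(strategy="contingent_nipt", uptake_scenario="base")
    if name == "nipt_100":
        return (
            {"uptakes": {"nipt_uptake_unaffected": 1.0, "nipt_uptake_affected": 1.0}},
            StrategySpec(strategy="contingent_nipt", uptake_scenario="nipt_100"),
        )
    if name == "nipt_100_screen_79":
        return (
            {
                "uptakes": {
                    "nipt_uptake_unaffected": 1.0,
                    "nipt_uptake_affected": 1.0,
                    "screening_uptake": 0.79,
                }
            },
            StrategySpec(strategy="contingent_nipt", uptake_scenario="nipt_100_screen_79"),
        )
    if name == "firstline_79":
        return (
            {"uptakes": {"nipt_firstline_uptake": 0.79}},
            StrategySpec(strategy="firstline_nipt", uptake_scenario="firstline_79"),
        )
    raise ValueError(f"unknown uptake scenario {name!r}; known: {SCENARIO_NAMES}")


def apply_overrides(params: ParameterSet, overrides: Mapping) -> ParameterSet:
    """Return a new ParameterSet with a nested override mapping applied."""
    if not overrides:
        return params.model_copy(deep=True)
    return ParameterSet.model_validate(_deep_merge(to_document(params), overrides))


def apply_scenario(params: ParameterSet, spec: StrategySpec) -> ParameterSet:
    """Apply the uptake scenario named in ``spec`` to ``params``."""
    if spec.uptake_scenario == "base":
        return params
    name = spec.uptake_scenario
    overrides, _ = scenario_presets(name)
    return apply_overrides(params, overrides)
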