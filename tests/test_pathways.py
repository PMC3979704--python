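"""Pathway stage operators and full strategy runs."""

import numpy as np
import pytest

from niptscreen import (
    CohortSlice,
    StatusPair,
    StrategySpec,
    TestPerformance,
    apply_invasive,
    apply_nipt,
    apply_screening,
    apply_top,
    default_parameters,
    load_parameters,
    run_contingent_nipt,
    run_current_screening,
    run_firstline_nipt,
    run_strategy,
    summarize_outcomes,
)
from niptscreen.pathways import PathwayEvents


class TestApplyScreening:
    def test_rates_applied_by_status(self):
        slice_ = CohortSlice(affected=10.0, unaffected=990.0, gestational_week=12)
        perf = TestPerformance(detection_rate=0.85, false_positive_rate=0.025)
        res = apply_screening(slice_, perf, uptake=1.0)
        assert res.positives.affected == pytest.approx(8.5)
        assert res.positives.unaffected == pytest.approx(24.75)
        # conservation across the four outputs
        total = res.positives.total + res.negatives.total + res.decliners.total
        assert total == pytest.approx(slice_.total, abs=1e-12)

    def test_zero_uptake_all_decline(self):
        slice_ = CohortSlice(3.0, 7.0, 12)
        res = apply_screening(slice_, TestPerformance(detection_rate=0.9, false_positive_rate=0.1), 0.0)
        assert res.takers.total == 0.0
        assert res.decliners.total == pytest.approx(10.0)

    def test_zero_fpr_no_unaffected_positives(self):
        slice_ = CohortSlice(3.0, 7.0, 12)
        res = apply_screening(slice_, TestPerformance(detection_rate=0.9, false_positive_rate=0.0), 1.0)
        assert res.positives.unaffected == 0.0


class TestApplyNipt:
    def test_one_repeat_per_sample_failure(self):
        nipt = TestPerformance(detection_rate=0.99, false_positive_rate=0.01, sample_failure_rate=0.05)
        res = apply_nipt(StatusPair(0.0, 100.0), nipt, StatusPair(1.0, 1.0))
        assert res.tests == pytest.approx(105.0)

    def test_detection_rate_on_affected(self):
        nipt = TestPerformance(detection_rate=0.99, false_positive_rate=0.01)
        res = apply_nipt(StatusPair(10.0, 0.0), nipt, StatusPair(1.0, 1.0))
        assert res.positives.affected == pytest.approx(9.9)

    def test_zero_uptake_no_tests(self):
        nipt = TestPerformance(detection_rate=0.99, false_positive_rate=0.01, sample_failure_rate=0.05)
        res = apply_nipt(StatusPair(10.0, 100.0), nipt, StatusPair(0.0, 0.0))
        assert res.tests == 0.0
        assert res.decliners.total == pytest.approx(110.0)


class TestApplyInvasive:
    # the two published miscarriage counts follow from tests × 0.005 exactly
    @pytest.mark.parametrize("n_tests, printed", [(160.59, 0.80), (11.48, 0.06)])
    def test_miscarriage_identity_reproduces_published_cells(self, n_tests, printed):
        cvs = TestPerformance(
            detection_rate=1.0, false_positive_rate=0.0,
            sample_failure_rate=0.013, procedure_miscarriage_rate=0.005,
        )
        res = apply_invasive(StatusPair(0.0, n_tests), cvs, StatusPair(1.0, 1.0))
        assert round(res.miscarriages.total, 2) == printed

    def test_uptake_by_status(self):
        cvs = TestPerformance(detection_rate=1.0, false_positive_rate=0.0, procedure_miscarriage_rate=0.005)
        res = apply_invasive(StatusPair(10.0, 3.0), cvs, StatusPair(0.9, 0.8))
        assert res.takers.total == pytest.approx(9.0 + 2.4)

    def test_miscarried_ds_not_counted_detected(self):
        cvs = TestPerformance(detection_rate=1.0, false_positive_rate=0.0, procedure_miscarriage_rate=0.005)
        res = apply_invasive(StatusPair(100.0, 0.0), cvs, StatusPair(1.0, 1.0))
        assert res.confirmed_ds == pytest.approx(100.0 * 0.995)
        assert res.confirmed_ds + res.miscarriages.affected == pytest.approx(100.0)

    def test_decliners_never_detected(self):
        cvs = TestPerformance(detection_rate=1.0, false_positive_rate=0.0)
        res = apply_invasive(StatusPair(10.0, 0.0), cvs, StatusPair(0.0, 0.0))
        assert res.confirmed_ds == 0.0
        assert res.decliners.affected == pytest.approx(10.0)


def test_apply_top_split():
    res = apply_top(10.0, 0.921)
    assert res.top == pytest.approx(9.21)
    assert res.continuing_affected == pytest.approx(0.79)
    assert apply_top(10.0, 1.0).continuing_affected == 0.0


class TestStrategyRuns:
    def test_current_nipt_columns_zero(self, base_runs):
        events, outcome = base_runs["current"]
        assert outcome.n_nipt == 0.0
        assert outcome.n_nipt_positive == 0.0
        assert events.nipt_tests == 0.0

    def test_firstline_screening_columns_zero(self, base_runs):
        events, outcome = base_runs["firstline_nipt"]
        assert outcome.n_screened == 0.0
        assert events.repeat_nt == 0.0

    def test_contingent_screening_stage_identical_to_current(self, base_runs):
        current, _ = base_runs["current"]
        contingent, _ = base_runs["contingent_nipt"]
        assert contingent.screened_t1 == pytest.approx(current.screened_t1)
        assert contingent.screen_positive_affected == pytest.approx(current.screen_positive_affected)

    def test_zero_screening_uptake_gives_empty_ledger(self, ages, prev):
        params = load_parameters({"uptakes": {"screening_uptake": 0.0}})
        events, outcome = run_current_screening(params, ages=ages, prev=prev)
        assert outcome.n_screened == 0.0
        assert outcome.n_invasive == 0.0
        assert outcome.n_ds_detected == 0.0
        assert events.conservation_error() < 1e-9

    def test_zero_nipt_uptake_contingent_detects_nothing(self, ages, prev):
        params = load_parameters(
            {"uptakes": {"nipt_uptake_affected": 0.0, "nipt_uptake_unaffected": 0.0}}
        )
        events, outcome = run_contingent_nipt(params, ages=ages, prev=prev)
        assert outcome.n_screened > 0
        assert outcome.n_nipt == 0.0
        assert outcome.n_invasive == 0.0
        assert outcome.n_ds_detected == 0.0

    def test_zero_firstline_uptake_all_zero_events(self, ages, prev):
        params = load_parameters({"uptakes": {"nipt_firstline_uptake": 0.0}})
        events, outcome = run_firstline_nipt(params, ages=ages, prev=prev)
        assert outcome.n_nipt == 0.0
        assert outcome.n_ds_detected == 0.0
        assert events.n_births + events.n_spontaneous_losses == pytest.approx(10_000.0, abs=1e-9)

    def test_miscarriages_proportional_to_invasive_tests(self, base_runs):
        for events, _ in base_runs.values():
            assert events.n_procedure_miscarriages == pytest.approx(
                events.n_invasive * 0.005, abs=1e-9
            )

    def test_detected_bounded_by_initial_affected(self, base_runs):
        for events, _ in base_runs.values():
            assert 0.0 <= events.ds_detected <= events.initial_affected

    def test_conservation_under_base_inputs(self, base_runs):
        for events, _ in base_runs.values():
            assert events.conservation_error() < 1e-9

    def test_full_top_uptake_no_affected_births_among_confirmed(self, ages, prev):
        # with TOP uptake 1 and NIPT/invasive uptake 1, every surviving
        # affected pregnancy in the first-line arm is diagnosed and terminated
        params = load_parameters(
            {
                "uptakes": {
                    "top_uptake": 1.0,
                    "nipt_firstline_uptake": 1.0,
                    "invasive_uptake_affected": 1.0,
                    "invasive_uptake_unaffected": 1.0,
                },
                "nipt": {
                    "detection_rate": 1.0,
                    "false_positive_rate": 0.01,
                    "sample_failure_rate": 0.05,
                },
            }
        )
        events, _ = run_firstline_nipt(params, ages=ages, prev=prev)
        affected_births = events.births_vaginal_affected + events.births_caesarean_affected
        assert affected_births == pytest.approx(0.0, abs=1e-9)


class TestPublishedOrderings:
    def test_detected_and_nipt_increase_with_cutoff(self, params, ages, prev):
        detected, takers, miscarriages = [], [], []
        for cutoff in (150, 500, 1000, 2000):
            spec = StrategySpec(strategy="contingent_nipt", screening_risk_cutoff=cutoff)
            _, outcome = run_contingent_nipt(params, spec, ages=ages, prev=prev)
            detected.append(outcome.n_ds_detected)
            takers.append(outcome.n_nipt)
            miscarriages.append(outcome.n_procedure_miscarriages)
        assert all(b > a for a, b in zip(detected, detected[1:]))
        assert all(b > a for a, b in zip(takers, takers[1:]))
        assert all(b >= a for a, b in zip(miscarriages, miscarriages[1:]))

    def test_firstline_detects_more_than_contingent(self, base_runs):
        assert (
            base_runs["firstline_nipt"][1].n_ds_detected
            > base_runs["contingent_nipt"][1].n_ds_detected
            > 0.0
        )

    def test_contingent_fewer_miscarriages_than_current(self, base_runs):
        assert (
            base_runs["contingent_nipt"][1].n_procedure_miscarriages
            < base_runs["current"][1].n_procedure_miscarriages
        )


class TestConservationProperty:
    def test_random_valid_parameter_sets_conserve_cohort(self, ages):
        """Every strategy partitions the cohort into terminal states exactly."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            doc = {
                "uptakes": {
                    "screening_uptake": rng.uniform(0, 1),
                    "late_arrival_fraction": rng.uniform(0, 1),
                    "invasive_uptake_unaffected": rng.uniform(0, 1),
                    "invasive_uptake_affected": rng.uniform(0, 1),
                    "nipt_uptake_unaffected": rng.uniform(0, 1),
                    "nipt_uptake_affected": rng.uniform(0, 1),
                    "nipt_firstline_uptake": rng.uniform(0, 1),
                    "top_uptake": rng.uniform(0, 1),
                },
                "nipt": {
                    "detection_rate": rng.uniform(0.5, 1.0),
                    "false_positive_rate": rng.uniform(0.0, 0.2),
                    "sample_failure_rate": rng.uniform(0.0, 0.2),
                },
                "loss_rates": {
                    "affected_weeks_10_15": rng.uniform(0.01, 0.1),
                    "affected_weeks_16_40": rng.uniform(0.001, 0.01),
                    "unaffected_weeks_10_25": rng.uniform(0.0, 0.005),
                    "unaffected_weeks_26_40": rng.uniform(0.0, 0.001),
                },
            }
            params = load_parameters(doc)
            for strategy in ("current", "contingent_nipt", "firstline_nipt"):
                events, _ = run_strategy(params, StrategySpec(strategy=strategy), ages=ages)
                assert events.conservation_error() < 1e-6, (strategy, doc)


def test_summary_consistent_with_ledger(base_runs):
    for events, outcome in base_runs.values():
        assert summarize_outcomes(events).as_dict() == outcome.as_dict()
    zero = summarize_outcomes(PathwayEvents())
    assert all(v == 0.0 for v in zero.as_dict().values())
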