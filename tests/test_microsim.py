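"""Individual-level microsimulator: determinism, tabulation, convergence."""

import numpy as np
import pandas as pd
import pytest

from niptscreen import (
    StrategySpec,
    compare_to_expectation,
    load_parameters,
    run_strategy,
    simulate_women,
    tabulate_events,
)
from niptscreen.microsim import WOMAN_COLUMNS


@pytest.fixture(scope="module")
def contingent_spec():
    return StrategySpec(strategy="contingent_nipt")


class TestSeededDeterminism:
    def test_identical_trajectories_for_same_seed(self, params, contingent_spec):
        a = simulate_women(params, contingent_spec, n=2000, seed=11)
        b = simulate_women(params, contingent_spec, n=2000, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self, params, contingent_spec):
        a = simulate_women(params, contingent_spec, n=2000, seed=11)
        b = simulate_women(params, contingent_spec, n=2000, seed=12)
        assert not a.equals(b)

    def test_growing_n_preserves_earlier_women(self, params, contingent_spec):
        small = simulate_women(params, contingent_spec, n=500, seed=5)
        large = simulate_women(params, contingent_spec, n=1500, seed=5)
        pd.testing.assert_frame_equal(small, large.iloc[:500])


class TestTrajectoryValidity:
    def test_exactly_one_terminal_state(self, params):
        for strategy in ("current", "contingent_nipt", "firstline_nipt"):
            women = simulate_women(params, StrategySpec(strategy=strategy), n=20_000, seed=2)
            lost = women["spontaneous_loss_week"] >= 0
            miscarried = women["procedure_miscarriage"]
            topped = women["top"]
            born = women["birth_mode"] != ""
            states = lost.astype(int) + miscarried.astype(int) + topped.astype(int) + born.astype(int)
            assert (states == 1).all()

    def test_event_order_respected(self, params, contingent_spec):
        women = simulate_women(params, contingent_spec, n=20_000, seed=2)
        assert not (women["nipt_taken"] & ~women["screen_positive"]).any()
        assert not (women["invasive_taken"] & ~women["nipt_positive"]).any()
        assert not (women["ds_detected"] & ~women["affected"]).any()
        assert not (women["top"] & ~women["ds_detected"]).any()

    def test_no_nipt_under_current_strategy(self, params):
        women = simulate_women(params, StrategySpec(strategy="current"), n=10_000, seed=2)
        assert not women["nipt_taken"].any()
        assert list(women.columns) == WOMAN_COLUMNS

    def test_all_uptakes_zero_no_tests(self):
        params = load_parameters(
            {"uptakes": {"screening_uptake": 0.0, "nipt_firstline_uptake": 0.0}}
        )
        for strategy in ("current", "firstline_nipt"):
            women = simulate_women(params, StrategySpec(strategy=strategy), n=5000, seed=9)
            assert not women["screened"].any()
            assert not women["nipt_taken"].any()
            delivered = (women["birth_mode"] != "") | (women["spontaneous_loss_week"] >= 0)
            assert delivered.all()


class TestTabulation:
    def test_hand_built_fixture(self):
        women = pd.DataFrame(
            [
                # affected, screened T1, positive, NIPT+, invasive, detected, TOP in T1
                dict(maternal_age=38, affected=True, booking_t1=True, screened=True,
                     screen_positive=True, repeat_nt=False, nipt_taken=True, nipt_failed=True,
                     nipt_positive=True, invasive_taken=True, invasive_trimester=1, invasive_failed=False,
                     procedure_miscarriage=False, ds_detected=True, top=True, top_trimester=1,
                     spontaneous_loss_week=-1, birth_mode=""),
                # unaffected, screened T2, negative, vaginal birth
                dict(maternal_age=28, affected=False, booking_t1=False, screened=True,
                     screen_positive=False, repeat_nt=False, nipt_taken=False, nipt_failed=False,
                     nipt_positive=False, invasive_taken=False, invasive_trimester=0, invasive_failed=False,
                     procedure_miscarriage=False, ds_detected=False, top=False, top_trimester=0,
                     spontaneous_loss_week=-1, birth_mode="vaginal"),
                # unaffected decliner, spontaneous loss week 20
                dict(maternal_age=31, affected=False, booking_t1=True, screened=False,
                     screen_positive=False, repeat_nt=False, nipt_taken=False, nipt_failed=False,
                     nipt_positive=False, invasive_taken=False, invasive_trimester=0, invasive_failed=False,
                     procedure_miscarriage=False, ds_detected=False, top=False, top_trimester=0,
                     spontaneous_loss_week=20, birth_mode=""),
            ]
        )
        events = tabulate_events(women)
        assert events.initial_affected == 1 and events.initial_unaffected == 2
        assert events.screened_t1 == 1 and events.screened_t2 == 1
        assert events.nipt_tests == 2  # one take plus one repeat after failure
        assert events.ds_detected == 1 and events.top_t1 == 1
        assert events.spontaneous_losses_unaffected == 1
        assert events.births_vaginal_unaffected == 1
        assert events.terminal_total() == 3

    def test_empty_frame_zero_ledger(self):
        events = tabulate_events(pd.DataFrame({c: [] for c in WOMAN_COLUMNS}))
        assert events.initial_total == 0
        assert events.terminal_total() == 0

    def test_ledger_conserves_n_exactly(self, params, contingent_spec):
        women = simulate_women(params, contingent_spec, n=30_000, seed=4)
        events = tabulate_events(women)
        assert events.terminal_total() == 30_000
        assert events.initial_total == 30_000


class TestComparison:
    def test_zero_z_when_simulated_equals_expected(self, params, contingent_spec):
        expected, _ = run_strategy(params, contingent_spec)
        report = compare_to_expectation(expected, expected, n=10_000)
        assert (report["z"] == 0).all()
        assert not report["flag"].any()

    def test_mismatched_cohort_size_rejected(self, params, contingent_spec):
        expected, _ = run_strategy(params, contingent_spec)
        with pytest.raises(ValueError, match="cohort size"):
            compare_to_expectation(expected, expected, n=77)

    def test_no_systematic_drift_across_n(self, params, contingent_spec):
        """Max |z| stays bounded as n grows: stochastic error, not bias."""
        for n in (10_000, 50_000):
            women = simulate_women(params, contingent_spec, n=n, seed=13)
            sim = tabulate_events(women)
            expected, _ = run_strategy(
                params.model_copy(update={"cohort_size": float(n)}), contingent_spec
            )
            report = compare_to_expectation(sim, expected, n=n)
            finite = report.loc[np.isfinite(report["z"]), "z"]
            assert finite.abs().max() <= 4.0

    def test_corrupted_rate_is_detected(self, params, contingent_spec):
        """Doubling the NIPT false-positive rate must trip the z diagnostic."""
        corrupted = load_parameters({"nipt": {"false_positive_rate": 0.02}})
        women = simulate_women(corrupted, contingent_spec, n=200_000, seed=13)
        sim = tabulate_events(women)
        expected, _ = run_strategy(
            params.model_copy(update={"cohort_size": 200_000.0}), contingent_spec
        )
        report = compare_to_expectation(sim, expected, n=200_000).set_index("field")
        assert abs(report.loc["nipt_positive_unaffected", "z"]) > 3.0
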