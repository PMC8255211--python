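"""Unit tests for the analytic decision-tree cost model."""

import numpy as np
import pytest

from pecost import (
    CalibrationError,
    DecisionTreeProbabilities,
    ModelCohort,
    NeonatalAssumptions,
    UncalibratedParameterError,
    apply_overrides,
    budget_impact,
    calibrate_nicu_days,
    calibrated_parameters,
    check_los_consistency,
    expected_pre_onset_admissions,
    nicu_admissions,
    overall_test_hosp_rate,
    per_patient_saving,
    round_jpy,
    scenario_cost,
)
from pecost.model import COMPONENTS


class TestOverallTestHospRate:
    def test_reported_mixture_rounds_to_8_7_percent(self):
        p = DecisionTreeProbabilities(
            share_low=0.794, share_high=0.206, p_hosp_given_low=0.0056,
            p_hosp_given_high=0.40,
        )
        assert round(100 * overall_test_hosp_rate(p), 1) == 8.7

    def test_zero_stratum_rates_give_zero(self, params):
        p = params.probabilities.model_copy(
            update={"p_hosp_given_low": 0.0, "p_hosp_given_high": 0.0}
        )
        assert overall_test_hosp_rate(p) == 0.0

    @pytest.mark.parametrize("x", [0.0, 0.123, 0.9])
    def test_equal_stratum_rates_collapse_to_that_rate(self, x):
        p = DecisionTreeProbabilities(
            share_low=0.5, share_high=0.5, p_hosp_given_low=x, p_hosp_given_high=x
        )
        assert overall_test_hosp_rate(p) == pytest.approx(x)


class TestAdmissionCounts:
    def test_pre_onset_admissions_match_reported_counts(self, params):
        p, c = params.probabilities, params.cohort
        assert 4476 <= expected_pre_onset_admissions("no_test", p, c) <= 4478
        assert 2686.5 <= expected_pre_onset_admissions("test", p, c) <= 2692

    def test_empty_cohort_has_zero_admissions(self, params):
        c = ModelCohort(n_model=0)
        for scenario in ("no_test", "test"):
            assert expected_pre_onset_admissions(scenario, params.probabilities, c) == 0

    def test_unknown_scenario_label_rejected(self, params):
        with pytest.raises(ValueError, match="unknown scenario"):
            expected_pre_onset_admissions("both", params.probabilities, params.cohort)

    def test_nicu_admissions_reproduce_reported_counts(self, params):
        p, c, neo = params.probabilities, params.cohort, params.neonatal
        assert nicu_admissions("no_test", p, c, neo) == pytest.approx(537.17, abs=0.5)
        assert nicu_admissions("test", p, c, neo) == pytest.approx(429.73, abs=0.5)

    def test_zero_rds_reduction_equalizes_scenarios(self, params):
        p, c = params.probabilities, params.cohort
        neo = NeonatalAssumptions(rds_reduction=0.0)
        assert nicu_admissions("test", p, c, neo) == nicu_admissions(
            "no_test", p, c, neo
        )


class TestScenarioCost:
    def test_uncalibrated_nicu_days_raises(self, params):
        with pytest.raises(UncalibratedParameterError, match="nicu_days"):
            scenario_cost("no_test", params)

    def test_retest_exactly_doubles_testing_component(self, calibrated):
        once = scenario_cost("test", calibrated, retest=False)
        twice = scenario_cost("test", calibrated, retest=True)
        assert twice.components["testing"] == pytest.approx(
            2 * once.components["testing"]
        )

    def test_no_test_scenario_has_no_testing_cost(self, calibrated):
        assert scenario_cost("no_test", calibrated).components["testing"] == 0.0

    def test_all_zero_unit_costs_give_zero_total(self, calibrated):
        zeroed = apply_overrides(
            calibrated,
            {f"costs.{k}": 0.0
             for k in ("outpatient", "hosp_per_day", "test_cost",
                       "corticosteroid", "nicu_per_day")},
        )
        for scenario in ("no_test", "test"):
            assert scenario_cost(scenario, zeroed).total == 0.0

    def test_total_is_sum_of_components(self, calibrated):
        for scenario in ("no_test", "test"):
            bd = scenario_cost(scenario, calibrated)
            assert bd.total == pytest.approx(
                sum(bd.components.values()), abs=1e-6
            )
            assert bd.per_patient == pytest.approx(bd.total / calibrated.cohort.n_model)


class TestSaving:
    def test_base_case_saving_rounds_to_published_value(self, calibrated):
        assert round_jpy(per_patient_saving(calibrated).per_patient_saving) == 16373

    def test_outpatient_and_birth_components_cancel(self, calibrated):
        deltas = per_patient_saving(calibrated).component_deltas
        assert deltas["outpatient"] == 0.0
        assert deltas["birth_hospitalization"] == 0.0

    def test_component_deltas_sum_to_budget_impact(self, calibrated):
        r = per_patient_saving(calibrated)
        assert sum(r.component_deltas.values()) == pytest.approx(
            r.per_patient_saving * calibrated.cohort.n_model, abs=0.5
        )

    def test_budget_impact_is_unrounded_saving_times_cohort(self, calibrated):
        r = per_patient_saving(calibrated)
        assert budget_impact(r, calibrated.cohort) == pytest.approx(
            r.per_patient_saving * 31_000, abs=0.5
        )
        assert r.budget_impact == pytest.approx(507_560_536, abs=500)

    def test_single_woman_budget_equals_saving(self, calibrated):
        one = apply_overrides(calibrated, {"cohort.n_model": 1})
        r = per_patient_saving(one)
        assert budget_impact(r, one.cohort) == pytest.approx(r.per_patient_saving)


class TestCalibration:
    def test_closed_form_matches_brute_force_scan(self, params):
        target = params.target_base_saving()
        days = calibrate_nicu_days(params, target)
        grid = np.arange(0.0, 40.0001, 0.01)
        errors = []
        for d in grid:
            q = params.model_copy(
                update={"stays": params.stays.model_copy(update={"nicu_days": float(d)})}
            )
            errors.append(abs(per_patient_saving(q).per_patient_saving - target))
        assert abs(grid[int(np.argmin(errors))] - days) <= 0.01
        assert days == pytest.approx(14.5, abs=0.5)

    def test_round_trip_reproduces_target(self, params):
        target = params.target_base_saving()
        cal = calibrated_parameters(params, target)
        assert per_patient_saving(cal).per_patient_saving == pytest.approx(
            target, abs=0.5
        )

    def test_target_at_zero_days_gives_zero(self, params):
        zero = params.model_copy(
            update={"stays": params.stays.model_copy(update={"nicu_days": 0.0})}
        )
        s0 = per_patient_saving(zero).per_patient_saving
        assert calibrate_nicu_days(params, s0) == pytest.approx(0.0, abs=1e-9)

    def test_doubling_nicu_unit_cost_halves_calibrated_days(self, params):
        target = params.target_base_saving()
        days = calibrate_nicu_days(params, target)
        doubled = apply_overrides(params, {"costs.nicu_per_day": 2 * 101_302.0})
        assert calibrate_nicu_days(doubled, target) == pytest.approx(days / 2)

    def test_unreachable_target_raises(self, params):
        zero = params.model_copy(
            update={"stays": params.stays.model_copy(update={"nicu_days": 0.0})}
        )
        s0 = per_patient_saving(zero).per_patient_saving
        with pytest.raises(CalibrationError, match="negative"):
            calibrate_nicu_days(params, s0 - 1_000.0)

    def test_explicit_nicu_days_suppresses_calibration(self, params):
        explicit = params.model_copy(
            update={"stays": params.stays.model_copy(update={"nicu_days": 3.0})}
        )
        assert calibrated_parameters(explicit).stays.nicu_days == 3.0


class TestLosConsistency:
    def test_equal_stays_give_that_average(self, calibrated):
        stays = calibrated.stays.model_copy(
            update={"pre_onset_days": 7.0, "birth_pe_days": 7.0,
                    "birth_no_pe_days": 7.0}
        )
        report = check_los_consistency(calibrated.model_copy(update={"stays": stays}))
        assert report.implied_no_test == pytest.approx(7.0)
        assert report.implied_test == pytest.approx(7.0)

    def test_no_episodes_fall_back_to_pre_onset_stay(self, calibrated):
        empty = apply_overrides(calibrated, {"cohort.n_model": 0})
        report = check_los_consistency(empty)
        assert report.implied_no_test == calibrated.stays.pre_onset_days

    def test_reports_deviations_without_failing(self, calibrated):
        report = check_los_consistency(calibrated)
        assert report.reported_no_test == 10.4
        assert report.reported_test == 10.2
        # diagnostic only: deviations are finite numbers, no exception raised
        assert np.isfinite(report.deviation_no_test)
        assert np.isfinite(report.deviation_test)

    def test_breakdown_components_are_complete(self, calibrated):
        bd = scenario_cost("test", calibrated)
        assert tuple(bd.components) == COMPONENTS
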