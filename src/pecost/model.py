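"""Analytic evaluation of the two-scenario decision tree.

The model compares expected direct medical costs for a cohort of women with
suspected preeclampsia under standard care alone (``no_test``) against
standard care plus sFlt-1/PlGF ratio triage at the cutoff of 38 (``test``).
Costs are accumulated over six components:

``outpatient``
    every woman is managed in an outpatient setting at some stage, in both
    scenarios (cancels in the saving);
``testing``
    the ratio test, test scenario only (doubled under the retest option);
``pre_onset_hospitalization``
    precautionary admissions before preeclampsia onset — the component the
    test changes, via the scenario hospitalization rate;
``corticosteroid``
    antenatal corticosteroids ride with every pre-onset admission;
``birth_hospitalization``
    the birth-period stay, identical in both scenarios because the test
    does not change preeclampsia incidence (cancels in the saving);
``nicu``
    NICU care for neonatal RDS. By construction the test scenario's NICU
    admission count is the no-test count scaled down by the relative RDS
    reduction, not a product of test-scenario hospitalizations.

All quantities are expectations over the cohort; nothing here is random.
Currency is carried as floats in JPY and rounded half-up only for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .params import (
    DecisionTreeProbabilities,
    ModelCohort,
    ModelParameters,
    Scenario,
)

__all__ = [
    "COMPONENTS",
    "CostBreakdown",
    "SavingResult",
    "LosConsistencyReport",
    "UncalibratedParameterError",
    "CalibrationError",
    "overall_test_hosp_rate",
    "expected_pre_onset_admissions",
    "nicu_admissions",
    "expected_birth_days_per_woman",
    "analytic_per_patient_cost",
    "scenario_cost",
    "per_patient_saving",
    "budget_impact",
    "calibrate_nicu_days",
    "calibrated_parameters",
    "check_los_consistency",
    "round_jpy",
]

COMPONENTS = (
    "outpatient",
    "testing",
    "pre_onset_hospitalization",
    "corticosteroid",
    "birth_hospitalization",
    "nicu",
)

_SCENARIOS = ("no_test", "test")


class UncalibratedParameterError(ValueError):
    """Raised when a cost is requested while ``nicu_days`` is still unset."""


class CalibrationError(ValueError):
    """Raised when no non-negative NICU stay can reach the requested saving."""


def round_jpy(x: float) -> int:
    """Round a currency amount half-up to the nearest yen (presentation only)."""
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _check_scenario(scenario: str) -> None:
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {_SCENARIOS}")


def overall_test_hosp_rate(p: DecisionTreeProbabilities) -> float:
    """Overall hospitalization rate in the test scenario.

    Mixture of the stratum-specific rates over the cutoff split:
    ``share_low * p_hosp_given_low + share_high * p_hosp_given_high``.
    With the cohort defaults this is 0.0867, the reported 8.7%.
    """
    return p.share_low * p.p_hosp_given_low + p.share_high * p.p_hosp_given_high


def expected_pre_onset_admissions(
    scenario: Scenario, p: DecisionTreeProbabilities, cohort: ModelCohort
) -> float:
    """Expected number of precautionary (pre-onset) admissions in the cohort."""
    _check_scenario(scenario)
    rate = p.p_hosp_no_test if scenario == "no_test" else overall_test_hosp_rate(p)
    return cohort.n_model * rate


def nicu_admissions(
    scenario: Scenario,
    p: DecisionTreeProbabilities,
    cohort: ModelCohort,
    neo,
) -> float:
    """Expected NICU admissions for neonatal RDS.

    The no-test count is ``n_model * p_hosp_no_test * rds_rate``. The test
    count is that same quantity thinned by the relative RDS reduction —
    deliberately tied to the standard-care admission count, since the RDS
    risk attaches to the population that would be hospitalized under
    standard care and the test's effect is the risk reduction itself.
    """
    _check_scenario(scenario)
    base = cohort.n_model * p.p_hosp_no_test * neo.rds_rate
    if scenario == "no_test":
        return base
    return base * (1.0 - neo.rds_reduction)


def expected_birth_days_per_woman(stays, pe_incidence: float) -> float:
    """Mean birth-period inpatient days per woman (same in both scenarios)."""
    return (
        pe_incidence * stays.birth_pe_days
        + (1.0 - pe_incidence) * stays.birth_no_pe_days
    )


@dataclass(frozen=True)
class CostBreakdown:
    """Expected cohort costs for one scenario, by component (JPY)."""

    scenario: str
    components: dict[str, float]
    total: float = field(init=False)
    per_patient: float = field(init=False)
    n_model: int = 0

    def __post_init__(self) -> None:
        total = sum(self.components[k] for k in COMPONENTS)
        object.__setattr__(self, "total", total)
        per_patient = total / self.n_model if self.n_model else 0.0
        object.__setattr__(self, "per_patient", per_patient)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"scenario": self.scenario, "component": k, "cost_jpy": self.components[k]}
            for k in COMPONENTS
        ]
        rows.append(
            {"scenario": self.scenario, "component": "total", "cost_jpy": self.total}
        )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "components": dict(self.components),
            "total": self.total,
            "per_patient": self.per_patient,
            "n_model": self.n_model,
        }


@dataclass(frozen=True)
class SavingResult:
    """Saving from introducing the test: no-test costs minus test costs."""

    per_patient_saving: float
    budget_impact: float
    component_deltas: dict[str, float]
    no_test: CostBreakdown
    test: CostBreakdown

    def to_dict(self) -> dict:
        return {
            "per_patient_saving": self.per_patient_saving,
            "per_patient_saving_rounded": round_jpy(self.per_patient_saving),
            "budget_impact": self.budget_impact,
            "component_deltas": dict(self.component_deltas),
        }


def _require_nicu_days(params: ModelParameters) -> float:
    d = params.stays.nicu_days
    if d is None:
        raise UncalibratedParameterError(
            "stays.nicu_days is unset; calibrate it first "
            "(see calibrate_nicu_days / calibrated_parameters)"
        )
    return d


def scenario_cost(
    scenario: Scenario, params: ModelParameters, retest: bool = False
) -> CostBreakdown:
    """Expected cohort cost breakdown for one scenario.

    Requires ``stays.nicu_days`` to be set (explicitly or via calibration);
    raises :class:`UncalibratedParameterError` otherwise.
    """
    _check_scenario(scenario)
    nicu_days = _require_nicu_days(params)
    p, c = params.probabilities, params.cohort
    costs, stays, neo = params.costs, params.stays, params.neonatal

    n = c.n_model
    admissions = expected_pre_onset_admissions(scenario, p, c)
    nicu_n = nicu_admissions(scenario, p, c, neo)
    birth_days = expected_birth_days_per_woman(stays, params.pe_incidence)

    components = {
        "outpatient": n * costs.outpatient,
        "testing": (
            0.0 if scenario == "no_test" else n * costs.test_cost * (2 if retest else 1)
        ),
        "pre_onset_hospitalization": admissions
        * stays.pre_onset_days
        * costs.hosp_per_day,
        "corticosteroid": admissions * costs.corticosteroid,
        "birth_hospitalization": n * birth_days * costs.hosp_per_day,
        "nicu": nicu_n * nicu_days * costs.nicu_per_day,
    }
    return CostBreakdown(scenario=scenario, components=components, n_model=n)


def per_patient_saving(params: ModelParameters, retest: bool = False) -> SavingResult:
    """Saving per woman from introducing the test, with component deltas.

    The outpatient and birth-hospitalization components cancel exactly; the
    saving is driven by avoided pre-onset admissions (stay plus steroids)
    and avoided NICU days, minus the testing cost.
    """
    no_test = scenario_cost("no_test", params, retest=retest)
    test = scenario_cost("test", params, retest=retest)
    deltas = {k: no_test.components[k] - test.components[k] for k in COMPONENTS}
    n = params.cohort.n_model
    saving = (no_test.total - test.total) / n if n else 0.0
    return SavingResult(
        per_patient_saving=saving,
        budget_impact=saving * n,
        component_deltas=deltas,
        no_test=no_test,
        test=test,
    )


def budget_impact(saving: SavingResult, cohort: ModelCohort) -> float:
    """Whole-cohort saving: the unrounded per-patient saving times n_model."""
    return saving.per_patient_saving * cohort.n_model


def calibrate_nicu_days(
    params: ModelParameters, target_base_saving: float
) -> float:
    """Solve for the NICU length of stay reaching a target per-patient saving.

    The saving is affine in ``nicu_days`` with nonnegative slope
    ``rds_reduction * p_hosp_no_test * rds_rate * nicu_per_day`` per day, so
    the solution is closed-form. Raises :class:`CalibrationError` when the
    target sits below the saving at a zero-day NICU stay (negative solution)
    or the slope is zero while the target is not already met.
    """
    base = params.model_copy(
        update={"stays": params.stays.model_copy(update={"nicu_days": 0.0})}
    )
    s0 = per_patient_saving(base).per_patient_saving
    p, neo, costs = params.probabilities, params.neonatal, params.costs
    slope = neo.rds_reduction * p.p_hosp_no_test * neo.rds_rate * costs.nicu_per_day
    if slope == 0.0:
        if abs(target_base_saving - s0) < 0.5:
            return 0.0
        raise CalibrationError(
            "NICU cost slope is zero; the target saving is unreachable"
        )
    days = (target_base_saving - s0) / slope
    if days < -1e-9:
        raise CalibrationError(
            f"calibration yields negative NICU stay ({days:.4f} days); "
            "parameters are inconsistent with the target saving"
        )
    return max(days, 0.0)


def calibrated_parameters(
    params: ModelParameters, target_base_saving: float | None = None
) -> ModelParameters:
    """Return parameters with ``nicu_days`` resolved.

    An explicitly set ``nicu_days`` is kept as-is (no silent recalibration).
    Otherwise the target is the argument or, failing that, the per-patient
    target implied by ``target_budget_impact``.
    """
    if params.stays.nicu_days is not None:
        return params
    if target_base_saving is None:
        target_base_saving = params.target_base_saving()
    if target_base_saving is None:
        raise UncalibratedParameterError(
            "nicu_days is unset and no calibration target is available"
        )
    days = calibrate_nicu_days(params, target_base_saving)
    return params.model_copy(
        update={"stays": params.stays.model_copy(update={"nicu_days": days})}
    )


@dataclass(frozen=True)
class LosConsistencyReport:
    """Implied vs reported average length of stay (diagnostic only)."""

    implied_no_test: float
    implied_test: float
    reported_no_test: float
    reported_test: float

    @property
    def deviation_no_test(self) -> float:
        return self.implied_no_test - self.reported_no_test

    @property
    def deviation_test(self) -> float:
        return self.implied_test - self.reported_test

    def to_dict(self) -> dict:
        return {
            "implied_no_test": self.implied_no_test,
            "implied_test": self.implied_test,
            "reported_no_test": self.reported_no_test,
            "reported_test": self.reported_test,
            "deviation_no_test": self.deviation_no_test,
            "deviation_test": self.deviation_test,
        }


def check_los_consistency(params: ModelParameters) -> LosConsistencyReport:
    """Compare the model-implied average stay per admission with reported values.

    The implied average weights each admission episode by its length: every
    woman has one birth episode (mean set by the preeclampsia incidence) and
    hospitalized women add a pre-onset episode. Purely diagnostic: it
    reports deviations and never fails the model, since the denominator
    convention behind the reported averages is not fully determined.
    """
    p, stays = params.probabilities, params.stays
    birth = expected_birth_days_per_woman(stays, params.pe_incidence)

    def _avg(hosp_rate: float) -> float:
        episodes = hosp_rate + 1.0  # pre-onset admissions + birth episodes, per woman
        return (hosp_rate * stays.pre_onset_days + birth) / episodes

    n = params.cohort.n_model
    if n == 0:
        implied_no_test = implied_test = stays.pre_onset_days
    else:
        implied_no_test = _avg(p.p_hosp_no_test)
        implied_test = _avg(overall_test_hosp_rate(p))
    return LosConsistencyReport(
        implied_no_test=implied_no_test,
        implied_test=implied_test,
        reported_no_test=stays.avg_los_no_test,
        reported_test=stays.avg_los_test,
    )


def analytic_per_patient_cost(
    scenario: Scenario, params: ModelParameters, retest: bool = False
) -> float:
    """Expected cost per woman in one scenario (Monte Carlo oracle target)."""
    return scenario_cost(scenario, params, retest=retest).per_patient
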