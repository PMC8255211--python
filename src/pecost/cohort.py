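"""Patient-level synthetic cohorts for Monte Carlo validation.

Each simulated woman carries an sFlt-1/PlGF ratio, her risk stratum at the
cutoff of 38, hospitalization and preeclampsia outcomes, realized lengths of
stay, and her neonate's RDS/NICU trajectory. Averaging realized per-woman
costs over a large cohort must converge to the analytic expectations in
:mod:`pecost.model`; that equivalence is the module's reason to exist.

Two points where the generator realizes the analytic model's accounting
conventions rather than a literal clinical pathway:

* Every woman carries a latent standard-care hospitalization flag
  (``hosp_standard_care``), drawn at the no-test rate independently of her
  stratum. Neonatal RDS risk attaches to this flag in BOTH scenarios —
  thinned by the relative RDS reduction in the test scenario — because the
  analytic model ties test-scenario NICU admissions to the standard-care
  admission count. In the no-test scenario the flag and the realized
  admission coincide.
* The ratio values are drawn from an arbitrary two-component positive
  mixture straddling the cutoff; only the mixture weights (the stratum
  shares) carry information. No patient-level ratio distribution is
  reproduced, and no cost depends on the ratio beyond the stratum.

The joint structure linking hospitalization and preeclampsia onset is
illustrative only (stratum-conditional risks from the published NPV/PPV);
it is not claimed to match any observed in-hospital preeclampsia fraction.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .model import UncalibratedParameterError
from .params import DecisionTreeProbabilities, ModelParameters, Scenario

__all__ = [
    "PATIENT_COLUMNS",
    "PatientRecord",
    "SimulationConfig",
    "DegenerateCohortError",
    "simulate_cohort",
    "validate_cohort",
    "estimate_parameters",
    "monte_carlo_cost",
]

PATIENT_COLUMNS = [
    "id",
    "scenario",
    "sflt_plgf_ratio",
    "stratum",
    "hosp_standard_care",
    "hospitalized_pre_onset",
    "pe_within_1wk",
    "pe_within_4wks",
    "pre_onset_days",
    "birth_days",
    "neonate_rds",
    "nicu_days",
]

# gamma shapes for length-of-stay dispersion; only the means matter to the
# analytic model, so these are documented conventions, not data
_PRE_ONSET_SHAPE = 4.0
_BIRTH_SHAPE = 8.0
_NICU_SHAPE = 6.0


class PatientRecord(BaseModel):
    """One simulated woman and her neonate (a validated cohort row)."""

    model_config = ConfigDict(frozen=True)

    id: int
    scenario: Scenario
    sflt_plgf_ratio: float = Field(gt=0.0)
    stratum: str
    hosp_standard_care: bool
    hospitalized_pre_onset: bool
    pe_within_1wk: bool
    pe_within_4wks: bool
    pre_onset_days: float = Field(ge=0.0)
    birth_days: float = Field(ge=0.0)
    neonate_rds: bool
    nicu_days: float = Field(ge=0.0)


class SimulationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_women: int = Field(ge=1)
    seed: int
    scenario: Scenario = "test"


class DegenerateCohortError(ValueError):
    """Raised when an estimator is asked for a quantity with no support."""


def simulate_cohort(cfg: SimulationConfig, params: ModelParameters) -> pd.DataFrame:
    """Draw a synthetic cohort under one scenario.

    Same seed implies a byte-identical cohort. All random vectors are drawn
    in a fixed order independent of the scenario, so cohorts simulated under
    the two scenarios from the same seed share their latent randomness
    (common random numbers) and differ only through the decision pathway.
    """
    if params.stays.nicu_days is None:
        raise UncalibratedParameterError(
            "stays.nicu_days is unset; calibrate before simulating"
        )
    p, stays, neo, perf = (
        params.probabilities,
        params.stays,
        params.neonatal,
        params.performance,
    )
    n = cfg.n_women
    rng = np.random.default_rng(cfg.seed)

    high = rng.random(n) < p.share_high
    # arbitrary positive mixture straddling the cutoff; shape carries no info
    ratio_low = perf.cutoff * rng.beta(2.0, 4.0, size=n)
    ratio_high = perf.cutoff + rng.gamma(2.0, 30.0, size=n)
    ratio = np.where(high, ratio_high, ratio_low)

    hosp_standard = rng.random(n) < p.p_hosp_no_test
    u_hosp_test = rng.random(n)
    p_hosp_stratum = np.where(high, p.p_hosp_given_high, p.p_hosp_given_low)
    if cfg.scenario == "no_test":
        hospitalized = hosp_standard.copy()
    else:
        hospitalized = u_hosp_test < p_hosp_stratum

    # 4-week preeclampsia risk by stratum, 1-week outcome nested inside
    risk_4wk = np.where(high, perf.ppv_4wk, 1.0 - perf.npv_4wk)
    pe_4wk = rng.random(n) < risk_4wk
    with np.errstate(divide="ignore", invalid="ignore"):
        cond_low = np.divide(1.0 - perf.npv_1wk, 1.0 - perf.npv_4wk)
        cond_high = np.divide(perf.ppv_1wk, perf.ppv_4wk)
    cond_1wk = np.where(high, np.nan_to_num(cond_high), np.nan_to_num(cond_low))
    pe_1wk = pe_4wk & (rng.random(n) < cond_1wk)

    pre_days = np.where(
        hospitalized,
        rng.gamma(_PRE_ONSET_SHAPE, stays.pre_onset_days / _PRE_ONSET_SHAPE, size=n),
        0.0,
    )
    birth_mean = np.where(pe_4wk, stays.birth_pe_days, stays.birth_no_pe_days)
    birth_days = rng.gamma(_BIRTH_SHAPE, birth_mean / _BIRTH_SHAPE, size=n)

    rds_rate = neo.rds_rate * (
        (1.0 - neo.rds_reduction) if cfg.scenario == "test" else 1.0
    )
    rds = hosp_standard & (rng.random(n) < rds_rate)
    nicu = np.where(
        rds, rng.gamma(_NICU_SHAPE, stays.nicu_days / _NICU_SHAPE, size=n), 0.0
    )

    return pd.DataFrame(
        {
            "id": np.arange(n),
            "scenario": cfg.scenario,
            "sflt_plgf_ratio": ratio,
            "stratum": np.where(high, "high", "low"),
            "hosp_standard_care": hosp_standard,
            "hospitalized_pre_onset": hospitalized,
            "pe_within_1wk": pe_1wk,
            "pe_within_4wks": pe_4wk,
            "pre_onset_days": pre_days,
            "birth_days": birth_days,
            "neonate_rds": rds,
            "nicu_days": nicu,
        },
        columns=PATIENT_COLUMNS,
    )


def validate_cohort(records: pd.DataFrame, cutoff: float = 38.0) -> None:
    """Enforce record-level invariants; raises ``ValueError`` on violation.

    Checks: stratum consistent with ratio vs cutoff; 1-week preeclampsia
    implies 4-week; NICU days positive iff RDS; RDS only with a latent
    standard-care admission (which equals the realized admission in the
    no-test scenario); stays nonnegative, pre-onset days zero when not
    admitted.
    """
    r = records
    problems = []
    if not ((r["sflt_plgf_ratio"] > cutoff) == (r["stratum"] == "high")).all():
        problems.append("stratum inconsistent with ratio vs cutoff")
    if (r["pe_within_1wk"] & ~r["pe_within_4wks"]).any():
        problems.append("pe_within_1wk without pe_within_4wks")
    if not ((r["nicu_days"] > 0) == r["neonate_rds"]).all():
        if (r["neonate_rds"] & (r["nicu_days"] == 0)).any() or (
            ~r["neonate_rds"] & (r["nicu_days"] > 0)
        ).any():
            problems.append("nicu_days > 0 must hold iff neonate_rds")
    if (r["neonate_rds"] & ~r["hosp_standard_care"]).any():
        problems.append("neonate_rds without latent standard-care admission")
    no_test = r[r["scenario"] == "no_test"]
    if (no_test["hospitalized_pre_onset"] != no_test["hosp_standard_care"]).any():
        problems.append("no-test admission must equal the standard-care flag")
    if (r["pre_onset_days"] < 0).any() or (r["birth_days"] < 0).any():
        problems.append("negative stay")
    if ((r["pre_onset_days"] > 0) & ~r["hospitalized_pre_onset"]).any():
        problems.append("pre-onset stay without admission")
    if problems:
        raise ValueError("invalid cohort: " + "; ".join(problems))


def estimate_parameters(
    records: pd.DataFrame,
) -> tuple[DecisionTreeProbabilities, dict[str, float]]:
    """Plug-in decision-tree probabilities and stay means from a cohort.

    Proportions: standard-care hospitalization rate, stratum shares, and
    stratum-specific realized admission rates (informative for cohorts
    simulated under the test scenario). Stay means are conditional on the
    relevant event and NaN-free only where the event occurred at least once.
    Raises :class:`DegenerateCohortError` if either stratum is empty.
    """
    if len(records) == 0:
        raise DegenerateCohortError("empty cohort")
    low = records[records["stratum"] == "low"]
    high = records[records["stratum"] == "high"]
    if len(low) == 0 or len(high) == 0:
        raise DegenerateCohortError(
            "cannot estimate stratum rates: a stratum is empty "
            f"(low={len(low)}, high={len(high)})"
        )
    probs = DecisionTreeProbabilities(
        p_hosp_no_test=float(records["hosp_standard_care"].mean()),
        share_low=len(low) / len(records),
        share_high=len(high) / len(records),
        p_hosp_given_low=float(low["hospitalized_pre_onset"].mean()),
        p_hosp_given_high=float(high["hospitalized_pre_onset"].mean()),
    )
    admitted = records[records["hospitalized_pre_onset"]]
    pe = records[records["pe_within_4wks"]]
    no_pe = records[~records["pe_within_4wks"]]
    rds = records[records["neonate_rds"]]
    stay_means = {
        "pre_onset_days": float(admitted["pre_onset_days"].mean())
        if len(admitted)
        else float("nan"),
        "birth_pe_days": float(pe["birth_days"].mean()) if len(pe) else float("nan"),
        "birth_no_pe_days": float(no_pe["birth_days"].mean())
        if len(no_pe)
        else float("nan"),
        "nicu_days": float(rds["nicu_days"].mean()) if len(rds) else float("nan"),
    }
    return probs, stay_means


def per_woman_cost(
    records: pd.DataFrame, costs, retest: bool = False
) -> np.ndarray:
    """Realized cost of each woman's trajectory in JPY."""
    scenario_is_test = records["scenario"] == "test"
    test_units = np.where(scenario_is_test, 2 if retest else 1, 0)
    return (
        costs.outpatient
        + costs.test_cost * test_units
        + records["hospitalized_pre_onset"].to_numpy() * costs.corticosteroid
        + (records["pre_onset_days"] + records["birth_days"]).to_numpy()
        * costs.hosp_per_day
        + records["nicu_days"].to_numpy() * costs.nicu_per_day
    )


def monte_carlo_cost(
    records: pd.DataFrame, costs, retest: bool = False
) -> tuple[float, Optional[float]]:
    """Empirical mean per-woman cost and its standard error.

    The standard error is the sample standard deviation over sqrt(n); it is
    ``None`` for a single-woman cohort, where it is undefined.
    """
    values = per_woman_cost(records, costs, retest=retest)
    mean = float(np.mean(values))
    if len(values) < 2:
        return mean, None
    se = float(np.std(values, ddof=1) / math.sqrt(len(values)))
    return mean, se
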