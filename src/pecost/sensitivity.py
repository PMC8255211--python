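"""One-way sensitivity scenarios over the decision-tree cost model.

The built-in catalogue mirrors the published scenario table: the base case
plus seven one-way variations (no-test hospitalization rate raised to the
overall PROGNOSIS Asia rate; test cost +/-20%; a retest for every woman; the
low-stratum hospitalization rate moved to 4% and to 0%; the high-stratum
rate raised to 50%). Arbitrary user scenarios are expressed the same way:
a name plus dotted-path parameter overrides and a retest flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .model import per_patient_saving, round_jpy
from .params import ModelParameters, apply_overrides

__all__ = [
    "ScenarioSpec",
    "SensitivityTable",
    "builtin_scenarios",
    "run_sensitivity",
    "tornado_ranking",
]

TABLE_COLUMNS = [
    "scenario",
    "p_hosp_no_test",
    "test_cost",
    "retest",
    "p_hosp_given_low",
    "p_hosp_given_high",
    "saving_per_patient",
    "approximate",
    "error",
]


class ScenarioSpec(BaseModel):
    """One scenario: overrides applied to a fresh copy of the base parameters.

    ``approximate`` marks scenarios whose published value is known not to be
    reproducible from main-text parameters under this model structure.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str
    overrides: dict[str, float] = Field(default_factory=dict)
    retest: bool = False
    approximate: bool = False
    note: Optional[str] = None


def builtin_scenarios() -> list[ScenarioSpec]:
    """The eight published scenarios, base case first."""
    return [
        ScenarioSpec(name="base_case"),
        ScenarioSpec(
            name="no_test_rate_overall_asia",
            overrides={"probabilities.p_hosp_no_test": 0.269},
            approximate=True,
            note=(
                "no-test hospitalization rate raised to the overall PROGNOSIS "
                "Asia rate; published value not reproducible from main-text "
                "parameters under this model structure"
            ),
        ),
        ScenarioSpec(
            name="test_cost_minus_20pct", overrides={"costs.test_cost": 7200.0}
        ),
        ScenarioSpec(
            name="test_cost_plus_20pct", overrides={"costs.test_cost": 10800.0}
        ),
        ScenarioSpec(name="retest_every_woman", retest=True),
        ScenarioSpec(
            name="low_ratio_hosp_4pct",
            overrides={"probabilities.p_hosp_given_low": 0.04},
        ),
        ScenarioSpec(
            name="low_ratio_hosp_0pct",
            overrides={"probabilities.p_hosp_given_low": 0.0},
        ),
        ScenarioSpec(
            name="high_ratio_hosp_50pct",
            overrides={"probabilities.p_hosp_given_high": 0.50},
        ),
    ]


def _is_base(spec: ScenarioSpec) -> bool:
    return not spec.overrides and not spec.retest


@dataclass(frozen=True)
class SensitivityTable:
    """Scenario results, base case in row 1, published-table column layout."""

    frame: pd.DataFrame
    component_deltas: dict[str, dict[str, float]]

    @property
    def base_saving(self) -> float:
        return float(self.frame.iloc[0]["saving_per_patient"])

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["saving_per_patient"] = [
            round_jpy(v) if pd.notna(v) else "" for v in out["saving_per_patient"]
        ]
        out.to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "rows": self.frame.to_dict(orient="records"),
            "component_deltas": self.component_deltas,
        }


def run_sensitivity(
    specs: list[ScenarioSpec], base_params: ModelParameters
) -> SensitivityTable:
    """Evaluate each scenario against a fresh copy of the base parameters.

    Rows are independent: overrides never leak between scenarios, and
    permuting the spec order permutes rows without changing any value. A
    scenario with an invalid override path or value gets its error recorded
    in its row; the remaining rows still run. A base-case row is prepended
    when the first spec is not itself the base.

    ``base_params`` must be calibrated (``nicu_days`` set).
    """
    specs = list(specs)
    if not specs or not _is_base(specs[0]):
        specs.insert(0, ScenarioSpec(name="base_case"))

    rows: list[dict[str, Any]] = []
    deltas: dict[str, dict[str, float]] = {}
    for spec in specs:
        row: dict[str, Any] = {
            "scenario": spec.name,
            "retest": spec.retest,
            "approximate": spec.approximate,
            "error": "",
        }
        try:
            params = apply_overrides(base_params, spec.overrides)
            result = per_patient_saving(params, retest=spec.retest)
        except (KeyError, ValueError) as exc:
            row.update(
                p_hosp_no_test=None,
                test_cost=None,
                p_hosp_given_low=None,
                p_hosp_given_high=None,
                saving_per_patient=float("nan"),
                error=str(exc),
            )
        else:
            row.update(
                p_hosp_no_test=params.probabilities.p_hosp_no_test,
                test_cost=params.costs.test_cost,
                p_hosp_given_low=params.probabilities.p_hosp_given_low,
                p_hosp_given_high=params.probabilities.p_hosp_given_high,
                saving_per_patient=result.per_patient_saving,
            )
            deltas[spec.name] = dict(result.component_deltas)
        rows.append(row)

    frame = pd.DataFrame(rows)[TABLE_COLUMNS]
    return SensitivityTable(frame=frame, component_deltas=deltas)


def tornado_ranking(table: SensitivityTable) -> pd.DataFrame:
    """Non-base rows ordered by |saving - base saving|, ties in row order."""
    frame = table.frame
    base = table.base_saving
    others = frame.iloc[1:].copy()
    others = others[others["error"] == ""]
    others["delta_from_base"] = others["saving_per_patient"] - base
    others["abs_delta"] = others["delta_from_base"].abs()
    ranked = others.sort_values("abs_delta", ascending=False, kind="stable")
    return ranked.drop(columns=["abs_delta"]).reset_index(drop=True)
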