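#!/usr/bin/env python
"""Base case: calibrate the NICU stay, evaluate both scenarios, report the
per-patient saving and the whole-cohort budget impact.

Writes results/base_case_breakdown.csv and results/base_case.json.
"""

import json
from pathlib import Path

import pandas as pd

from pecost import (
    calibrated_parameters,
    check_los_consistency,
    default_parameters,
    expected_pre_onset_admissions,
    nicu_admissions,
    overall_test_hosp_rate,
    per_patient_saving,
    round_jpy,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    params = default_parameters()
    p, c, neo = params.probabilities, params.cohort, params.neonatal

    print("== Decision-tree rates ==")
    print(f"no-test hospitalization rate: {100 * p.p_hosp_no_test:.1f}%")
    print(f"test-scenario hospitalization rate: "
          f"{100 * overall_test_hosp_rate(p):.1f}%")
    print(f"pre-onset admissions (cohort of {c.n_model:,}): "
          f"{expected_pre_onset_admissions('no_test', p, c):,.0f} (no test) vs "
          f"{expected_pre_onset_admissions('test', p, c):,.0f} (test)")
    print(f"NICU admissions for RDS: "
          f"{nicu_admissions('no_test', p, c, neo):.2f} (no test) vs "
          f"{nicu_admissions('test', p, c, neo):.2f} (test)")

    calibrated = calibrated_parameters(params)
    print(f"\ncalibrated NICU stay per RDS admission: "
          f"{calibrated.stays.nicu_days:.2f} days")

    result = per_patient_saving(calibrated)
    print("\n== Base case ==")
    print(f"per-patient saving: {round_jpy(result.per_patient_saving):,} JPY")
    print(f"budget impact ({c.n_model:,} women): "
          f"{round_jpy(result.budget_impact):,} JPY")
    print("component deltas (no-test minus test, cohort JPY):")
    for name, delta in result.component_deltas.items():
        print(f"  {name:>26}: {delta:>16,.0f}")

    los = check_los_consistency(calibrated)
    print("\nlength-of-stay diagnostic (implied vs reported, days): "
          f"no-test {los.implied_no_test:.2f} vs {los.reported_no_test}; "
          f"test {los.implied_test:.2f} vs {los.reported_test}")

    OUT.mkdir(exist_ok=True)
    frame = pd.concat(
        [result.no_test.to_frame(), result.test.to_frame()], ignore_index=True
    )
    frame.to_csv(OUT / "base_case_breakdown.csv", index=False)
    (OUT / "base_case.json").write_text(
        json.dumps(
            {
                "nicu_days": calibrated.stays.nicu_days,
                "saving": result.to_dict(),
                "los_consistency": los.to_dict(),
            },
            indent=2,
        )
        + "\n"
    )
    print(f"\nwrote {OUT / 'base_case_breakdown.csv'} and {OUT / 'base_case.json'}")


if __name__ == "__main__":
    main()
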