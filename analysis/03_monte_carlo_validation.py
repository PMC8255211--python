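#!/usr/bin/env python
"""Monte Carlo validation: simulate patient-level cohorts under both
scenarios and check that empirical mean costs match the analytic
expectations within sampling error.

Writes results/mc_validation.json.
"""

import json
import math
from pathlib import Path

from pecost import (
    SimulationConfig,
    calibrated_parameters,
    default_parameters,
    monte_carlo_cost,
    per_patient_saving,
    simulate_cohort,
)
from pecost.model import analytic_per_patient_cost

OUT = Path(__file__).resolve().parent.parent / "results"
N = 200_000
SEEDS = {"no_test": 101, "test": 102}


def main() -> None:
    calibrated = calibrated_parameters(default_parameters())
    report = {}
    means, ses = {}, {}
    print(f"== Microsimulation vs analytic expectation (n = {N:,}) ==")
    for scenario, seed in SEEDS.items():
        cfg = SimulationConfig(n_women=N, seed=seed, scenario=scenario)
        records = simulate_cohort(cfg, calibrated)
        mean, se = monte_carlo_cost(records, calibrated.costs)
        analytic = analytic_per_patient_cost(scenario, calibrated)
        z = (mean - analytic) / se
        verdict = "PASS" if abs(z) < 3 else "FAIL"
        print(f"{scenario:>8}: MC {mean:,.1f} +/- {se:,.1f} vs analytic "
              f"{analytic:,.1f}  (z = {z:+.2f})  {verdict}")
        means[scenario], ses[scenario] = mean, se
        report[scenario] = {
            "n": N, "seed": seed, "mc_mean": mean, "mc_se": se,
            "analytic": analytic, "z": z, "verdict": verdict,
        }

    diff = means["no_test"] - means["test"]
    pooled = math.hypot(ses["no_test"], ses["test"])
    saving = per_patient_saving(calibrated).per_patient_saving
    z = (diff - saving) / pooled
    verdict = "PASS" if abs(z) < 3 else "FAIL"
    print(f"\nsimulated saving: {diff:,.1f} +/- {pooled:,.1f} vs analytic "
          f"{saving:,.1f}  (z = {z:+.2f})  {verdict}")
    report["saving"] = {
        "mc_diff": diff, "pooled_se": pooled, "analytic": saving,
        "z": z, "verdict": verdict,
    }

    OUT.mkdir(exist_ok=True)
    (OUT / "mc_validation.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {OUT / 'mc_validation.json'}")


if __name__ == "__main__":
    main()
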