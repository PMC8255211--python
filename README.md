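# pecost

Decision-analytic cost model for triaging suspected preeclampsia with the
sFlt-1/PlGF ratio test in the Japanese healthcare setting, with a synthetic
patient-level cohort generator for Monte Carlo validation.

## The problem

Women presenting with suspected preeclampsia are often hospitalized
precautionarily, yet most never develop the condition in the short term. The
serum sFlt-1/PlGF ratio at the cutoff of 38 rules preeclampsia out within
four weeks with high negative predictive value, so testing can divert
low-risk women to outpatient management. `pecost` quantifies what that is
worth: it compares expected direct medical costs for a model cohort of
31,000 women under standard care alone (*no-test* scenario) versus standard
care plus the ratio test (*test* scenario), for health-economics and
HTA-minded users.

## The model

Each scenario is a decision tree whose branches carry probabilities and
unit costs. With hospitalization rate `h` (standard care: `h₀ = 26/180 ≈
14.4%`; test scenario: the stratum mixture
`h₁ = s₌≤38 · p(hosp | ≤38) + s₌>38 · p(hosp | >38) = 0.794·0.0056 +
0.206·0.40 ≈ 8.7%`), the expected cohort cost is

```
C(h) = N·c_out + N·c_test·𝟙[test] + N·h·(d_pre·c_hosp + c_steroid)
       + N·E[birth stay]·c_hosp + NICU(h₀)·d_nicu·c_nicu
```

where the NICU term counts RDS admissions `N·h₀·12%`, thinned by a relative
20% in the test scenario (targeted admission plus corticosteroids reduce
neonatal respiratory distress syndrome). Outpatient and birth-period terms
are identical across scenarios and cancel in the saving. The one unit not
published, the NICU length of stay `d_nicu`, is calibrated in closed form —
the saving is affine in it — against the published base-case saving.
One-way sensitivity scenarios re-run the model with single-parameter
overrides; the microsimulation draws per-woman trajectories (ratio stratum,
hospitalization, preeclampsia outcome via NPV/PPV, stays, RDS/NICU) and
checks that empirical mean costs converge to the analytic expectations.

## Worked example

```python
from pecost import (calibrated_parameters, default_parameters,
                    per_patient_saving, round_jpy)

params = calibrated_parameters(default_parameters())
print(f"NICU stay: {params.stays.nicu_days:.2f} days")
result = per_patient_saving(params)
print(f"saving per patient: {round_jpy(result.per_patient_saving):,} JPY")
print(f"budget impact: {round_jpy(result.budget_impact):,} JPY")
```

prints

```
NICU stay: 14.51 days
saving per patient: 16,373 JPY
budget impact: 507,560,536 JPY
```

i.e. calibration resolves the NICU stay at about 14.5 days, introducing the
test saves 16,373 JPY per woman, and rolling that saving over the 31,000
women with suspected preeclampsia in Japan at any given time yields roughly
508 million JPY. The same numbers are available from the command line
(`pecost base-case`), alongside `pecost sensitivity --builtin`,
`pecost simulate` and `pecost calibrate`.

The narrative analyses live under `analysis/` as numbered drivers —
`01_base_case.py` (rates, admissions, calibration, saving, budget),
`02_sensitivity.py` (the eight one-way scenarios and tornado ordering),
`03_monte_carlo_validation.py` (microsimulation vs analytic expectations at
n = 200,000) and `04_parameter_recovery.py` (estimation at the observed
cohort size n = 180) — each writing its tables to `results/`.

## Limits

The model reports cost savings only — no QALYs, discounting or
probabilistic sensitivity analysis — and consumes the test's NPV/PPV and
cutoff as published constants rather than estimating them. See
`docs/methods.md` for assumptions, parameter defaults, calibration details
and known reproduction limits.
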