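# Methods

## Model structure

`pecost` evaluates a two-scenario decision tree over a model cohort of
`n_model` women with suspected preeclampsia. In the **no-test** scenario a
fraction `p_hosp_no_test` is admitted precautionarily before preeclampsia
onset; the rest are managed as outpatients. In the **test** scenario women
are first split at the sFlt-1/PlGF cutoff of 38 into a low-risk stratum
(share `share_low`, admission probability `p_hosp_given_low`) and a
high-risk stratum (`share_high`, `p_hosp_given_high`); the overall
admission rate is the mixture of the two. Expected cohort costs accumulate
over six components:

| component | no-test | test |
|---|---|---|
| outpatient | `n·c_out` | same (every woman, including admitted ones) |
| testing | 0 | `n·c_test` (doubled with the retest option) |
| pre-onset hospitalization | `n·h₀·d_pre·c_hosp` | `n·h₁·d_pre·c_hosp` |
| corticosteroid | `n·h₀·c_ster` | `n·h₁·c_ster` |
| birth hospitalization | `n·E[birth stay]·c_hosp` | identical by construction |
| NICU (neonatal RDS) | `n·h₀·r_RDS·d_NICU·c_NICU` | no-test value × `(1 − ρ)` |

with `h₀/h₁` the scenario admission rates, `d_pre = 4` days, `r_RDS = 12%`
and the relative RDS reduction `ρ = 20%`. Everything is an expectation;
the analytic module contains no randomness. Currency is carried as floats
in JPY and rounded half-up only at presentation.

Two accounting conventions deserve emphasis:

* **Corticosteroids ride with pre-onset admissions in both scenarios.**
  Every admitted woman receives high-intensity management including
  corticosteroids, so each avoided admission saves
  `4 × 87,300 + 1,752 = 350,952` JPY. The published scenario deltas are
  consistent with exactly this per-admission bundle.
* **Test-scenario NICU admissions are the no-test count thinned by the RDS
  reduction**, not test-scenario admissions times the RDS rate. The RDS
  risk attaches to the population that would be hospitalized under standard
  care; the test's neonatal effect is the 20% relative risk reduction from
  better-targeted admission and steroid timing. (The alternative reading —
  test admissions × 12% — is numerically incompatible with the published
  admission counts, which scale exactly by 0.8.)

The birth-period component is sized by `pe_incidence` (below) but
constrained to be identical across scenarios, since the test does not
change preeclampsia incidence; together with the outpatient component it
cancels in every saving.

## Parameter defaults

Branch probabilities default to the exact cohort fractions of the 180-woman
Japanese analysis set — 26/180 admitted under standard care, 143/180 at or
below the cutoff (0.56% of whom are admitted), 37/180 above (40% admitted;
the observed stratum rate of 27% is retained as an annotation, the model
deliberately uses the conservative 40%). Unit costs (JPY): outpatient care
57,053 per woman; inpatient day 87,300; ratio test 9,000; corticosteroid
course 1,752; NICU day 101,302. Stays: 4 pre-onset days; birth-period stay
13.6 days with preeclampsia, 9.3 without. The model cohort is 31,000 women.

`pe_incidence` — the fraction of women whose birth episode involves
preeclampsia — is not separately published. Its default is the four-week
incidence implied by the cutoff split and the test's predictive values,
`share_low·(1 − NPV₄wk) + share_high·PPV₄wk ≈ 0.1012`, which makes the
analytic birth component equal the synthetic cohort's expectation by
construction. If `performance` is overridden, `pe_incidence` should be
moved with it; nothing downstream of the saving depends on it.

## Calibration of the NICU stay

The NICU length of stay per RDS admission is not published. The per-patient
saving is affine in it,

```
saving(d) = saving(0) + ρ · p_hosp_no_test · r_RDS · c_NICU · d ,
```

so `calibrate_nicu_days` inverts this in closed form. The packaged default
target is the published whole-cohort saving divided by the model cohort
size (507,560,536 / 31,000 ≈ 16,372.92 JPY — the highest-precision
published statement of the base-case saving; it rounds to the headline
16,373). The solve yields ≈14.51 days, a plausible NICU stay for RDS. A
negative solution raises an error (parameters inconsistent with the
target); an explicitly configured `nicu_days` suppresses calibration so the
free parameter is never silently overridden, while a missing value is
calibrated automatically and logged.

## Sensitivity scenarios

The built-in catalogue holds the base case plus seven one-way scenarios:
no-test admission rate raised to the overall PROGNOSIS Asia rate (26.9%);
test cost ±20%; a second test for every woman; the low-stratum admission
rate moved to 4% and to 0%; the high-stratum rate raised to 50%. Each
scenario applies its overrides to a fresh copy of the base parameters, so
rows are order-independent and never leak state; a row with an invalid
override records its error without stopping the rest. Six of the seven
published one-way savings are reproduced within a few JPY from the single
base-case calibration. The 26.9% scenario is the exception: its published
value (69,482 JPY) is not recoverable from main-text parameters under this
model structure — the reconstruction lands near 64,481 JPY — so the
scenario is flagged `approximate` in output metadata, excluded from
golden-number tests, and covered instead by the property that the saving is
strictly increasing in the no-test admission rate. `tornado_ranking` orders
non-base rows by absolute excursion from the base saving with stable ties.

## Synthetic cohorts

`simulate_cohort` draws, per woman: a risk stratum (Bernoulli at the
stratum shares) and a ratio value from an arbitrary two-component positive
mixture straddling the cutoff (Beta-scaled below, Gamma-shifted above) —
only the stratum carries information, and no cost depends on the ratio
beyond it; a latent standard-care admission flag (Bernoulli `p_hosp_no_test`);
the realized admission (the latent flag in the no-test scenario, the
stratum-specific Bernoulli in the test scenario); four-week preeclampsia at
the stratum risks `1 − NPV₄wk` and `PPV₄wk`, with the one-week outcome
nested inside; stays from Gamma distributions matched to the published
means (shapes 4, 8 and 6 for pre-onset, birth and NICU stays — documented
dispersion conventions, since only means enter the analytic model); and
neonatal RDS as a Bernoulli on the **latent** flag, thinned by the RDS
reduction in the test scenario, realizing the analytic NICU convention at
patient level. All random vectors are drawn in a fixed order from one
seeded `numpy` Generator, so a seed fixes the cohort byte-for-byte and the
two scenarios simulated from the same seed share their latent randomness.

What the generator does *not* emulate: gestational-age dynamics, repeat
testing, enrollment, any real ratio distribution, and the joint dependence
between hospitalization and preeclampsia onset (the stratum-conditional
risks are illustrative; in-hospital preeclampsia fractions are not claimed
to match observation). Passing Monte Carlo checks therefore validate the
cost arithmetic and the estimators against the model's own assumptions,
not against real patient data.

`estimate_parameters` returns plug-in proportions and conditional stay
means and fails explicitly on an empty stratum. `monte_carlo_cost` averages
realized per-woman costs; its standard error is undefined (returned as
`None`) for a single woman.

## Numerical choices and validation sizes

* Probability blocks validate strictly (shares sum to one within 1e-9, all
  probabilities in [0,1]); degenerate cohorts (`n_model = 0`) produce zero
  costs rather than errors.
* Calibration round-trips to the target within 0.5 JPY over randomized
  parameter sets (tested over 100 draws).
* Oracle equivalence is checked at n = 200,000 simulated women per
  scenario (each mean within 3 standard errors of the analytic value, and
  the between-scenario difference within 3 pooled standard errors of the
  analytic saving); parameter recovery uses 100 cohorts at the observed
  n = 180 against exact 99% Clopper–Pearson intervals. These sizes give
  sub-percent Monte Carlo error while keeping the full validation suite in
  the seconds range.
* The length-of-stay diagnostic weights each admission episode by its
  length (one birth episode per woman plus a pre-onset episode per admitted
  woman). The reported scenario averages (10.4/10.2 days) are stored as
  inputs and compared, never enforced: the denominator convention behind
  them is not fully determined, and the diagnostic reports deviations
  (about −1.4/−0.9 days under the defaults) without failing the model.

## Known limitations

* No discounting, currency conversion, QALYs, or probabilistic sensitivity
  analysis — one-way scenarios only, matching the scope of the analysis the
  model implements.
* NPV/PPV and the cutoff of 38 are consumed as constants, never estimated.
* The published 69,482 JPY scenario and the in-hospital preeclampsia
  fractions (41.4%/24.1%) are not reproducible from main-text parameters;
  both are documented above rather than forced.
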