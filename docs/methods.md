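# Methods

`fraxpath` implements a FRAX-style opportunistic case-finding pipeline for
osteoporosis in postmenopausal women: a 10-year fracture-probability engine
with death as a competing risk, risk-equivalence intervention and
assessment thresholds, stochastic single imputation of unmeasured risk
factors, a BMD-triage management algorithm, and calibration reporting.
This note documents the models, the defaults and why, the numerical
choices, and what the synthetic cohorts do and do not demonstrate.

## The probability engine

The engine is an explicit, configurable surrogate for closed fracture-risk
calculators. It makes no claim of reproducing the proprietary FRAX
coefficients for any country; its purpose is to preserve the *method* that
sits on top of any such engine — risk-equivalence thresholds and triage are
invariant to the specific calibration.

For a woman with risk profile x, the cause-specific annual hazard of a
first major osteoporotic fracture (MOF: clinical spine, hip, humerus,
distal forearm) at attained age a is

    h_f(a | x) = h0(a) · exp( Σ_j x_j β_j + β_BMI (BMI − 25) + β_BMD · d(a) )

where the x_j are the seven dichotomous clinical risk factors, β_j are log
relative risks, and d(a) = (population mean T-score at age a) − (her
T-score) is the BMD deficit in SD units. When no T-score is supplied, the
BMD term is omitted, so "without BMD" coincides with the risk of a woman at
the age-specific population-mean T-score. Hip fracture has its own
baseline hazard with the same multipliers. The 10-year probability with
death as a competing risk is

    P(10) = ∫₀¹⁰ h_f(t) · exp( −∫₀ᵗ [h_f(u) + h_d(u)] du ) dt

Death hazard h_d is shared across profiles: risk factors confer no excess
mortality here. This is a simplification relative to full FRAX behaviour
(where e.g. smoking raises mortality) and slightly overstates fracture
probability for profiles whose factors also predict death.

### Numerical evaluation

The integral is evaluated on a fixed 0.05-year grid. Within each step the
hazards are frozen at their midpoint values and the step's contribution is
computed in closed form,

    ΔP_k = S_k · h_f/(h_f+h_d) · (1 − e^{−(h_f+h_d)Δ}),

with survival S_k updated multiplicatively. This actuarial update is exact
for constant hazards (machine-precision agreement with the closed
competing-risk formula, regardless of step size) and second-order accurate
for smooth hazards; halving the step changes default-model probabilities
by well under 1e-6. Evaluation is fully deterministic: identical inputs
give bit-identical probabilities.

Baseline hazards default to Gompertz curves h(a) = α e^{βa}, tabulated on
an integer-age grid with linear interpolation (so tabulated non-parametric
hazards are a drop-in alternative in the YAML configuration). Default
parameters put the cohort-mean 10-year MOF probability near 7.7% and hip
near 4.8% for the default synthetic cohort — the few-percent range typical
of published East-Asian estimates. Default relative risks are
literature-magnitude placeholders (prior fracture 1.8, parental hip
fracture and glucocorticoids 1.6, rheumatoid arthritis and high alcohol
1.4, type-2-diabetes secondary osteoporosis 1.3, smoking 1.2, BMD gradient
1.5 per SD, BMI −5% per kg/m² above 25). All are configuration inputs.

Ages are clamped to the operational range 40–90 (with a logged warning);
hazard tables extend to 105 so that follow-up windows beyond age 90 remain
integrable.

## Thresholds

Following the UK NOGG risk-equivalence approach: the intervention
threshold IT(age) is the MOF probability (without BMD) of a woman of
population-average BMI whose only risk factor is a prior fragility
fracture — the rationale being that if a prior fracture alone justifies
treatment, an equal probability from other sources should too. The lower
assessment threshold LAT(age) is the no-risk-factor probability: below it
neither treatment nor BMD testing is indicated. The upper assessment
threshold is UAT = 1.2 × IT (capped at 100%), limiting BMD testing among
women so far above the intervention threshold that BMD information could
not plausibly reclassify them.

Per-ethnicity probabilities are combined with age-specific population
weights on a 5-year grid from 40 to 90. The shipped weights (three groups,
Chinese-majority, mild ageing gradient) and the ethnicity- and
age-dependent mean BMI table are documented placeholders, not census data;
both are ordinary configuration inputs. Off-grid ages are linearly
interpolated; out-of-range lookups clamp to the end node with a warning.
UAT is derived from the unrounded IT; 2-decimal rounding is display-only,
and all triage comparisons use unrounded values. A published threshold
table can be loaded verbatim (`ThresholdCurve.from_csv`) and used as the
operating curve without any engine; a Singapore table is shipped.

## Imputation of unmeasured variables

Registry cohorts often lack some FRAX inputs. The pipeline fits
factor-specific regressions on a fully observed reference cohort and
stochastically assigns values in the target cohort:

* logistic models with protocol-fixed covariate sets — parental hip
  fracture ~ age + prior fracture; glucocorticoid use ~ age + sex + BMI;
  rheumatoid arthritis ~ sex + BMI + prior fracture;
* a linear model for the femoral-neck T-score ~ age + BMI + prior
  fracture + smoking, with residual SD taken as the RMS residual.

Assignment follows the uniform-draw rule: woman i is positive iff
u_i ≤ p̂_i with u_i drawn in record order from a seeded stream. Each factor
uses its own stream (base seed + a stable hash of the factor name), so
adding a factor never perturbs the other factors' draws. T-scores are
imputed as the conditional mean plus Gaussian residual noise by default;
without the noise the imputed T-score variance collapses to the explained
variance only, far below any realistic population SD, which would distort
both OSTA screening performance and with-BMD probabilities. A flag
disables the noise for diagnostic use.

Factors that are all-0 or all-1 in the reference (realistic for very rare
exposures such as heavy alcohol use) fall back to an intercept-only
prevalence model with a continuity correction and a logged warning.

Validation helpers: `prevalence_report` compares imputed prevalences with
reference prevalences age-standardised to the target cohort's 5-year age
distribution (bins absent from the reference are dropped with a warning —
with a 65+ reference the comparison is driven by the overlapping ages);
`osta_validate` computes the sensitivity and specificity of the OSTA index
0.2·(weight − age) against femoral-neck T ≤ −2.5, reconstructing weight
from BMI through a Normal(1.56 m, 0.06 m) height model when the cohort
carries BMI only. The screen-positive cutoff defaults to an index below
−1, the canonical OSTA low-risk boundary, and is configurable.

## Triage and reporting

The management algorithm: (1) prior fragility fracture → treat, no
probability computed; (2) otherwise MOF probability without BMD — strictly
below LAT → discharge, strictly above UAT → treat; (3) inside the band
(both boundary values included) a T-score is obtained — imputed and
flagged when unmeasured, or an error under `require_bmd` — the probability
is recomputed with BMD and treatment is recommended at or above IT. The
inclusive ≥ at IT is deliberate; the other boundaries route conservatively
into the BMD band. The five categories partition the cohort exactly.

The disposition summary mirrors guidance-audit tables whose rows overlap:
"otherwise eligible" = treat-above-UAT ∪ treat-after-BMD; "BMD tests" =
both band outcomes; "no treatment" = discharge ∪ no-treat-after-BMD.

Calibration bins women by baseline 10-year hip probability in left-closed
intervals [k·w, (k+1)·w) — a value exactly on an edge belongs to the
higher bin — and compares per-bin expected counts (each woman's
probability truncated to her own follow-up, death competing) with observed
events; the grand total equals `expected_fracture_count` by construction.

## Synthetic cohorts

The generator emulates a Singapore-like registry: women 50+, age
61.7 ± 7.8 years, BMI 23.2 ± 3.6, prior fracture 6.6% (mildly
age-dependent), smoking 5.4%, type-2-diabetes secondary osteoporosis
14.4%, heavy alcohol 0.06%, parental hip fracture 6.6%, glucocorticoid use
0.4%, rheumatoid arthritis 1.9%, femoral-neck T-score −1.89 ± 0.87 with an
age slope. Parental hip fracture, glucocorticoids, rheumatoid arthritis
and the T-score are generated and then blanked, with the truth kept in a
sidecar table, emulating variables the registry never measured. A fully
observed reference cohort (both sexes, age strata 65–69 / 70–74 / 75+ at
one third each) is generated from the *same* structural equations, so
imputation-model recovery is well-posed by construction.

Design choices worth flagging:

* Age is drawn from a normal truncated to [50, 90] whose pre-truncation
  parameters are solved so the *post*-truncation mean and SD hit their
  targets. A one-sided truncation at 50 with the same moment targets
  requires σ ≈ 10.9 and emits ages beyond 105 — outside any fracture
  calculator's range and impossible for a registry recruited in midlife —
  so the upper bound is set at the engine's operational maximum.
* Logistic intercepts are solved by deterministic quadrature (stratified
  quantile design points with an internal fixed seed, independent of the
  user's seeds) so the target cohort's marginals equal the configured
  prevalences by construction. The T-score noise SD is solved from the
  variance budget the same way; infeasible budgets (systematic variance
  exceeding the target SD) are rejected.
* Risk factors are conditionally independent given age, BMI, sex, prior
  fracture and smoking. Real cohorts have richer covariance (e.g.
  glucocorticoids co-occurring with rheumatoid arthritis); passing tests
  on these cohorts therefore demonstrates correctness of the *procedure*,
  not the adequacy of any particular imputation model for real data.
* The default T-score equation carries age and BMI slopes only; the
  imputation model's prior-fracture and smoking covariates then have true
  coefficient zero, exercised as null-effect recovery checks.

Follow-up is simulated per woman: an administrative censoring time drawn
uniformly on [6.7, 11.5] years (mean 9.1, the configured study profile),
and first-fracture and death times drawn from her cause-specific hazards
by inverse-transform sampling on a 0.01-year grid. An event is recorded
iff fracture precedes both death and censoring. `followup_years` records
the censoring time, not the death-truncated time: the engine's
competing-risk integral over that window is then exactly the expected
event count, making expected-vs-observed comparisons internally coherent,
and total person-years ≈ n × mean follow-up. Outcome simulation and
calibration scoring both use with-BMD (truth T-score) hazards by default,
so self-calibration holds by construction; scoring without BMD against
with-BMD outcomes carries a small Jensen-type upward bias in expected
counts (~e^{(β_BMD σ_resid)²/2}).

## Reproducibility and problem sizes

Every stochastic stage draws from a per-stage seed derived from one base
seed and recorded in the run manifest together with a configuration hash
and package version; CSVs are written with a fixed float format, so
re-running a configuration reproduces the bundle byte-for-byte (threshold
curves reload bit-identically via round-trip float parsing).

Default analysis sizes: target cohort 29,323 women, reference 4,000 in the
pipeline (50,000 in the parameter-recovery harness, where 3-SE coefficient
checks need the precision). The full pipeline at the default size runs in
seconds on one core; the test suite uses smaller cohorts (300–29,323)
chosen per check so that binomial/Poisson 3-SD bands are meaningful.

## Known limitations

* The engine's coefficients are placeholders; no output should be read as
  a FRAX value, and country calibration against fracture registries is out
  of scope.
* No interaction terms or age-dependent relative risks; no excess
  mortality from risk factors; single imputation only (no
  between-imputation variance pooling), matching the emulated procedure.
* The triage stage scores all women with one ethnicity's engine; ethnic
  mixing enters through the threshold weighting only.
* Weight for OSTA is reconstructed from BMI via a height model when
  absent, so OSTA results on BMI-only cohorts inherit that model's
  assumptions.
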