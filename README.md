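# fraxpath

FRAX-style case finding for osteoporosis: who should be treated, who
should get a bone-density (BMD) test, and who can safely be discharged,
when treatment decisions are driven by 10-year fracture probability rather
than BMD alone.

The package is aimed at biostatisticians and guideline developers who want
to prototype or audit probability-based assessment pathways on cohort
data. It provides:

* **A competing-risk probability engine** — a transparent, configurable
  surrogate for closed calculators of the FRAX family. The 10-year
  probability of a first major osteoporotic fracture (MOF) or hip fracture
  is P = ∫₀¹⁰ h_f(t)·exp(−∫₀ᵗ[h_f+h_d]) dt with multiplicative clinical
  risk factors, a BMI term, and an optional femoral-neck T-score gradient
  on Gompertz (or tabulated) baseline hazards. It is *not* FRAX and ships
  clearly-labelled placeholder coefficients.
* **Risk-equivalence thresholds** (NOGG methodology): the intervention
  threshold IT(age) is the MOF probability of a woman of average BMI whose
  only risk factor is a prior fragility fracture; the lower assessment
  threshold LAT(age) is the no-risk-factor probability; the upper
  assessment threshold is 1.2 × IT. Per-ethnicity probabilities are
  combined with age-specific population weights. A published Singapore
  threshold table is shipped and can be used as the operating curve
  directly.
* **Stochastic imputation** of unmeasured FRAX variables from a fully
  observed reference cohort (logistic/linear regressions with
  protocol-fixed covariates, uniform-draw assignment, seeded per-factor
  streams), with prevalence and OSTA-screening validation.
* **The triage algorithm**: prior fracture → treat; below LAT → discharge;
  above UAT → treat without BMD; in between → BMD test and treat at ≥ IT.
  Plus disposition audits and expected-vs-observed calibration tables.
* **Synthetic cohort generators** that reproduce configured marginals
  (ages, BMI, risk-factor prevalences, T-score distribution) and simulate
  follow-up outcomes from any hazard model — the pipeline is fully
  exercisable without access to any real cohort.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import fraxpath as fp
from fraxpath.pipeline import load_full_config, published_curve_path

models, weights, bmi_ref, uat_factor = load_full_config()
engine = models["chinese"]

# one woman: age 65, BMI 23, smoker, no BMD measurement
profile = fp.RiskProfile(age=65, bmi=23, current_smoking=1)
pair = fp.ten_year_probability(profile, engine)
print(f"MOF {pair.mof_pct:.1f}%  hip {pair.hip_pct:.1f}%")

# where does she fall on the published Singapore threshold curve?
curve = fp.ThresholdCurve.from_csv(published_curve_path())
print(f"LAT {curve.lat(65):.2f}  IT {curve.it(65):.2f}  UAT {curve.uat(65):.2f}")
```

prints

```
MOF 8.4%  hip 4.7%
LAT 6.51  IT 13.07  UAT 15.68
```

Her 8.4% probability lies between the age-65 lower (6.51%) and upper
(15.68%) assessment thresholds, so she would be referred for a BMD test;
after the test, treatment is recommended if her probability recomputed
with BMD reaches the 13.07% intervention threshold.

An end-to-end synthetic study (generate cohort → simulate follow-up → fit
and apply imputation → thresholds → triage → calibration, with a manifest
and byte-reproducible CSVs):

```sh
fraxpath run --outdir out/demo --n 29323 --seed 1
```

or stage by stage via `fraxpath simulate / fit-impute / impute /
thresholds / triage`. Re-running with the same seed reproduces every CSV
byte-identically.

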