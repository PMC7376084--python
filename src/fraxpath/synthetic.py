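"""Synthetic cohorts with the marginal structure of a Singapore-like study.

Two generators share one set of structural equations:

* a target cohort of women age 50+ (age ~ 61.7 +/- 7.8, BMI 23.2 +/- 3.6)
  in which femoral-neck T-score, parental hip fracture, glucocorticoid use
  and rheumatoid arthritis are generated but then blanked, emulating a
  registry that never measured them (the blanked truth is kept separately);
* a fully observed age-stratified reference cohort (both sexes, strata
  65-69 / 70-74 / 75+ at one third each) on which imputation models can be
  fitted, mirroring an elderly-volunteer BMD cohort.

Risk factors are conditionally independent given age, BMI, sex, prior
fracture and smoking; prior fracture itself is mildly age-dependent.
Intercepts are solved numerically so that the target cohort reproduces the
configured marginal prevalences, and the T-score noise SD is solved so the
marginal T-score SD matches its target.  Follow-up is simulated from a
hazard model by inverse-transform sampling of fracture and death times
against an administrative censoring time.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .risk_engine import CLINICAL_RISK_FACTORS, HazardModel

logger = logging.getLogger(__name__)

AGE_CENTER = 61.7
BMI_CENTER = 23.2

#: columns blanked in the target cohort (never recorded by the registry)
BLANKED_COLUMNS = ("parental_hip_fracture", "glucocorticoids",
                   "rheumatoid_arthritis", "fn_tscore")

COHORT_COLUMNS = ["id", "age", "sex", "bmi", *CLINICAL_RISK_FACTORS,
                  "fn_tscore", "followup_years", "hip_fracture_observed"]

_INTERNAL_SEED = 20101201  # fixed: used only for deterministic quadrature points
_N_DESIGN = 8192


@dataclass(frozen=True)
class CohortSpec:
    """Marginal targets and structural coefficients for the target cohort.

    Prevalences are cohort-level marginals; ``*_coef`` are log-odds slopes on
    centred covariates (age - 61.7 years, BMI - 23.2 kg/m2, female indicator
    - 1), with intercepts solved at generation time so the marginals hold.
    """

    n: int = 29323
    age_mean: float = 61.7
    age_sd: float = 7.8
    age_min: float = 50.0
    age_max: float = 90.0
    bmi_mean: float = 23.2
    bmi_sd: float = 3.6
    bmi_min: float = 14.0
    prev_prior_fracture: float = 0.066
    prev_current_smoking: float = 0.054
    prev_secondary_osteoporosis: float = 0.144
    prev_alcohol_3plus: float = 0.0006
    prev_parental_hip_fracture: float = 0.066
    prev_glucocorticoids: float = 0.004
    prev_rheumatoid_arthritis: float = 0.019
    prior_fracture_age_slope: float = 0.05
    parental_coef: tuple = (("age", 0.02), ("prior_fracture", 0.3))
    gluco_coef: tuple = (("age", 0.03), ("sex_female", 0.3), ("bmi", -0.05))
    ra_coef: tuple = (("sex_female", 0.6), ("bmi", -0.04), ("prior_fracture", 0.4))
    tscore_mean: float = -1.89
    tscore_sd: float = 0.87
    tscore_coef: tuple = (("age", -0.045), ("bmi", 0.03))
    blank_columns: tuple = BLANKED_COLUMNS

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        for name in ("age_sd", "bmi_sd", "tscore_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name, v in self.__dict__.items():
            if name.startswith("prev_") and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class FollowupSpec:
    """Administrative follow-up: Uniform(2*mean - max, max) gives the stated
    mean and maximum."""

    mean_years: float = 9.1
    max_years: float = 11.5

    def __post_init__(self):
        if not (0 < self.mean_years <= self.max_years):
            raise ValueError("need 0 < mean <= max follow-up")
        if 2 * self.mean_years - self.max_years < 0:
            raise ValueError("mean/max incompatible with a uniform window")

    @property
    def min_years(self) -> float:
        return 2 * self.mean_years - self.max_years


# ---------------------------------------------------------------------------
# distribution helpers
# ---------------------------------------------------------------------------

def _truncnorm_params(target_mean: float, target_sd: float, lower: float,
                      upper: float = np.inf):
    """(mu, sigma) of a normal whose truncation to [lower, upper] has the
    target mean and SD."""

    def moments(x):
        mu, log_sigma = x
        sigma = np.exp(log_sigma)
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - target_mean, np.sqrt(v) - target_sd]

    sol = optimize.fsolve(moments, [target_mean, np.log(target_sd)],
                          full_output=False)
    mu, sigma = float(sol[0]), float(np.exp(sol[1]))
    return mu, sigma


def _draw_truncnorm(rng, n, target_mean, target_sd, lower, upper=np.inf):
    mu, sigma = _truncnorm_params(target_mean, target_sd, lower, upper)
    a, b = (lower - mu) / sigma, (upper - mu) / sigma
    return truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def _sub_rng(seed: int, label: str) -> np.random.Generator:
    """Independent per-column stream: adding a column never perturbs others."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(label.encode())])


# ---------------------------------------------------------------------------
# structural equations (shared between target and reference generators)
# ---------------------------------------------------------------------------

def _centred(name, age, bmi, sex_female, prior_fracture, current_smoking):
    if name == "age":
        return age - AGE_CENTER
    if name == "bmi":
        return bmi - BMI_CENTER
    if name == "sex_female":
        return sex_female - 1.0
    if name == "prior_fracture":
        return prior_fracture
    if name == "current_smoking":
        return current_smoking
    raise KeyError(f"unknown structural covariate {name!r}")


def _linpred(coef, intercept, **cov):
    lp = intercept
    for name, c in coef:
        lp = lp + c * _centred(name, **cov)
    return lp


def _design_points(spec: CohortSpec):
    """Deterministic stratified (age, BMI) quadrature points for the target
    covariate distribution, with Latin-hypercube pairing."""
    q = (np.arange(_N_DESIGN) + 0.5) / _N_DESIGN
    mu, sigma = _truncnorm_params(spec.age_mean, spec.age_sd, spec.age_min,
                                  spec.age_max)
    a, b = (spec.age_min - mu) / sigma, (spec.age_max - mu) / sigma
    age = truncnorm.ppf(q, a, b, loc=mu, scale=sigma)
    mu_b, sigma_b = _truncnorm_params(spec.bmi_mean, spec.bmi_sd, spec.bmi_min)
    bmi = truncnorm.ppf(q, (spec.bmi_min - mu_b) / sigma_b, np.inf,
                        loc=mu_b, scale=sigma_b)
    np.random.default_rng(_INTERNAL_SEED).shuffle(bmi)
    return age, bmi


def _expected_prevalence(intercept, coef, age, bmi, p_pf_given_age, p_smoke):
    """E[expit(lp)] over the design points, enumerating the binary covariates."""
    total = 0.0
    for pf in (0.0, 1.0):
        w_pf = p_pf_given_age if pf else 1.0 - p_pf_given_age
        for sm in (0.0, 1.0):
            w = w_pf * (p_smoke if sm else 1.0 - p_smoke)
            lp = _linpred(coef, intercept, age=age, bmi=bmi, sex_female=1.0,
                          prior_fracture=pf, current_smoking=sm)
            total += float(np.mean(w * expit(lp)))
    return total


@dataclass(frozen=True)
class StructuralModel:
    """Solved structural equations: coefficient sets plus intercepts such
    that the *target* covariate distribution reproduces the spec marginals."""

    spec: CohortSpec
    pf_intercept: float
    parental_intercept: float
    gluco_intercept: float
    ra_intercept: float
    tscore_intercept: float
    tscore_noise_sd: float

    def prob_prior_fracture(self, age):
        return expit(self.pf_intercept
                     + self.spec.prior_fracture_age_slope * (age - AGE_CENTER))

    def prob_factor(self, factor, **cov):
        coef, b0 = {
            "parental_hip_fracture": (self.spec.parental_coef, self.parental_intercept),
            "glucocorticoids": (self.spec.gluco_coef, self.gluco_intercept),
            "rheumatoid_arthritis": (self.spec.ra_coef, self.ra_intercept),
        }[factor]
        return expit(_linpred(coef, b0, **cov))

    def tscore_mean_value(self, **cov):
        return _linpred(self.spec.tscore_coef, self.tscore_intercept, **cov)


def solve_structural_model(spec: CohortSpec) -> StructuralModel:
    """Solve intercepts (and the T-score noise SD) against the target
    covariate distribution by deterministic quadrature."""
    age, bmi = _design_points(spec)

    if spec.prev_prior_fracture in (0.0, 1.0):
        pf_b0 = -np.inf if spec.prev_prior_fracture == 0.0 else np.inf
    else:
        pf_b0 = optimize.brentq(
            lambda b0: float(np.mean(expit(
                b0 + spec.prior_fracture_age_slope * (age - AGE_CENTER)
            ))) - spec.prev_prior_fracture, -30, 30, xtol=1e-12)
    p_pf = expit(pf_b0 + spec.prior_fracture_age_slope * (age - AGE_CENTER)) \
        if np.isfinite(pf_b0) else np.full_like(age, spec.prev_prior_fracture)

    def solve(coef, target):
        if target in (0.0, 1.0):
            return -np.inf if target == 0.0 else np.inf
        return optimize.brentq(
            lambda b0: _expected_prevalence(b0, coef, age, bmi, p_pf,
                                            spec.prev_current_smoking) - target,
            -30, 30, xtol=1e-12)

    # T-score: intercept from the mean, noise SD from the variance budget
    means, sqs, w_tot = 0.0, 0.0, 0.0
    for pf in (0.0, 1.0):
        w_pf = p_pf if pf else 1.0 - p_pf
        for sm in (0.0, 1.0):
            w = w_pf * (spec.prev_current_smoking if sm else 1.0 - spec.prev_current_smoking)
            lp = _linpred(spec.tscore_coef, 0.0, age=age, bmi=bmi, sex_female=1.0,
                          prior_fracture=pf, current_smoking=sm)
            means += float(np.mean(w * lp))
            sqs += float(np.mean(w * lp ** 2))
    var_lp = sqs - means ** 2
    if var_lp > spec.tscore_sd ** 2:
        raise ValueError("systematic T-score variance exceeds the target SD; "
                         "reduce the structural slopes or raise tscore_sd")
    return StructuralModel(
        spec=spec,
        pf_intercept=float(pf_b0),
        parental_intercept=float(solve(spec.parental_coef, spec.prev_parental_hip_fracture)),
        gluco_intercept=float(solve(spec.gluco_coef, spec.prev_glucocorticoids)),
        ra_intercept=float(solve(spec.ra_coef, spec.prev_rheumatoid_arthritis)),
        tscore_intercept=float(spec.tscore_mean - means),
        tscore_noise_sd=float(np.sqrt(spec.tscore_sd ** 2 - var_lp)),
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _generate_from_structure(spec: CohortSpec, structural: StructuralModel,
                             seed: int, age, sex_female, id_offset=0) -> pd.DataFrame:
    """Draw all columns given ages and sexes, using per-column RNG streams."""
    n = len(age)
    bmi = _draw_truncnorm(_sub_rng(seed, "bmi"), n, spec.bmi_mean, spec.bmi_sd,
                          spec.bmi_min)
    pf = (_sub_rng(seed, "prior_fracture").random(n)
          <= structural.prob_prior_fracture(age)).astype(int)
    smoke = (_sub_rng(seed, "current_smoking").random(n)
             <= spec.prev_current_smoking).astype(int)
    sec = (_sub_rng(seed, "secondary_osteoporosis").random(n)
           <= spec.prev_secondary_osteoporosis).astype(int)
    alc = (_sub_rng(seed, "alcohol_3plus").random(n)
           <= spec.prev_alcohol_3plus).astype(int)
    cov = dict(age=age, bmi=bmi, sex_female=sex_female,
               prior_fracture=pf.astype(float), current_smoking=smoke.astype(float))
    out = {"id": np.arange(id_offset, id_offset + n),
           "age": age,
           "sex": np.where(sex_female > 0.5, "female", "male"),
           "bmi": bmi, "prior_fracture": pf, "current_smoking": smoke,
           "secondary_osteoporosis": sec, "alcohol_3plus": alc}
    for factor in ("parental_hip_fracture", "glucocorticoids",
                   "rheumatoid_arthritis"):
        p = structural.prob_factor(factor, **cov)
        out[factor] = (_sub_rng(seed, factor).random(n) <= p).astype(int)
    ts = structural.tscore_mean_value(**cov) \
        + structural.tscore_noise_sd * _sub_rng(seed, "fn_tscore").standard_normal(n)
    out["fn_tscore"] = np.clip(ts, -6.0, 4.0)
    out["followup_years"] = np.nan
    out["hip_fracture_observed"] = np.nan
    return pd.DataFrame(out)[COHORT_COLUMNS]


def generate_target_cohort(spec: CohortSpec, seed: int):
    """Target cohort with unmeasured columns blanked.

    Returns ``(cohort, truth)``: ``cohort`` has the spec's blanked columns set
    to missing; ``truth`` keeps every generated value so that imputations and
    follow-up simulation can be validated against it.
    """
    structural = solve_structural_model(spec)
    age = _draw_truncnorm(_sub_rng(seed, "age"), spec.n, spec.age_mean,
                          spec.age_sd, spec.age_min, spec.age_max)
    truth = _generate_from_structure(spec, structural, seed, age,
                                     sex_female=np.ones(spec.n))
    cohort = truth.copy()
    for col in spec.blank_columns:
        cohort[col] = np.nan
    return cohort, truth


def generate_reference_cohort(n: int, seed: int, spec: CohortSpec | None = None,
                              female_fraction: float = 0.5,
                              age_max: float = 85.0) -> pd.DataFrame:
    """Fully observed reference cohort, ages 65+, strata at one third each.

    Strata are 65-69, 70-74 and 75+ (uniform ages within each), both sexes;
    every risk factor and the T-score are observed.  Uses the same structural
    equations as :func:`generate_target_cohort`, so fitting imputation models
    on this cohort recovers the generating coefficients.
    """
    if n < 30:
        raise ValueError("reference cohort below 30 records: fits unstable")
    spec = spec or CohortSpec()
    structural = solve_structural_model(spec)
    rng_age = _sub_rng(seed, "ref_age")
    sizes = [n // 3, n // 3, n - 2 * (n // 3)]
    bounds = [(65.0, 70.0), (70.0, 75.0), (75.0, age_max)]
    age = np.concatenate([rng_age.uniform(lo, hi, size=k)
                          for (lo, hi), k in zip(bounds, sizes)])
    sex_female = (_sub_rng(seed, "ref_sex").random(n) < female_fraction).astype(float)
    df = _generate_from_structure(spec, structural, seed + 1, age, sex_female)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# follow-up simulation
# ---------------------------------------------------------------------------

def simulate_followup(truth: pd.DataFrame, model: HazardModel,
                      spec: FollowupSpec, seed: int,
                      use_tscore: bool = True, outcome: str = "hip",
                      time_step: float = 0.01, chunk: int = 2000) -> pd.DataFrame:
    """Simulate first-fracture outcomes against death and censoring.

    Per woman an administrative censoring time is drawn uniformly on
    [2*mean - max, max]; first-fracture and death times come from her
    individual cause-specific hazards by inverse-transform sampling on a
    fine time grid.  ``hip_fracture_observed`` is 1 iff the fracture precedes
    both death and censoring; ``followup_years`` records the censoring time,
    so summed probabilities over these windows (death competing) equal the
    expected event count.

    Requires a fully observed table (use the generator's truth output, not
    the blanked cohort).
    """
    from .risk_engine import _batch_multiplier  # shared hazard conventions

    n = len(truth)
    rng = np.random.default_rng(int(seed) % (2**31))
    censor = rng.uniform(spec.min_years, spec.max_years, size=n)
    e_frac = rng.exponential(size=n)
    e_death = rng.exponential(size=n)

    from .risk_engine import AGE_MAX, AGE_MIN
    # clamp to the engine's operational range so simulated outcomes use the
    # same hazards the scoring side would assign
    ages0 = np.clip(truth["age"].to_numpy(dtype=float), AGE_MIN, AGE_MAX)
    lp0 = _batch_multiplier(truth, model, use_tscore)
    ts = truth["fn_tscore"].to_numpy(dtype=float) if use_tscore else None
    if use_tscore and np.any(~np.isfinite(ts)):
        raise ValueError("use_tscore=True requires fn_tscore for every record")

    n_steps = int(np.ceil(spec.max_years / time_step))
    mids = (np.arange(n_steps) + 0.5) * time_step
    edges = np.arange(n_steps + 1) * time_step
    base = model.baseline(outcome)

    t_frac = np.full(n, np.inf)
    t_death = np.full(n, np.inf)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        a = ages0[lo:hi, None] + mids[None, :]
        lp = lp0[lo:hi, None]
        if use_tscore:
            lp = lp + model.bmd_log_rr_per_sd * (
                model.tscore_mean_by_age(a) - ts[lo:hi, None])
        hf = base(a) * np.exp(lp)
        hd = model.death_hazard(a) + np.zeros_like(hf)
        cum_f = np.concatenate([np.zeros((hi - lo, 1)),
                                np.cumsum(hf * time_step, axis=1)], axis=1)
        cum_d = np.concatenate([np.zeros((hi - lo, 1)),
                                np.cumsum(hd * time_step, axis=1)], axis=1)
        for rows, cum, e, tgt in ((slice(lo, hi), cum_f, e_frac, t_frac),
                                  (slice(lo, hi), cum_d, e_death, t_death)):
            ee = e[rows]
            idx = np.array([np.searchsorted(c, x) for c, x in zip(cum, ee)])
            hit = idx <= n_steps
            ii = np.where(hit, idx, 1)
            c_lo = np.take_along_axis(cum, (ii - 1)[:, None], axis=1)[:, 0]
            c_hi = np.take_along_axis(cum, ii[:, None], axis=1)[:, 0]
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(c_hi > c_lo, (ee - c_lo) / (c_hi - c_lo), 1.0)
            t = edges[ii - 1] + frac * time_step
            tgt[rows] = np.where(hit, t, np.inf)

    observed = (t_frac < np.minimum(t_death, censor)).astype(int)
    out = truth.copy()
    out["followup_years"] = censor
    out["hip_fracture_observed"] = observed
    return out
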