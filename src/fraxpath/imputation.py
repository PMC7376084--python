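"""Stochastic single imputation of unmeasured FRAX risk factors.

A fully observed reference cohort provides factor-specific regressions:
logistic for the dichotomous factors, ordinary least squares (with a
residual SD) for the femoral-neck T-score.  The covariate set of each model
is fixed by the case-finding protocol:

* parental hip fracture  ~ age + prior fracture
* glucocorticoid use     ~ age + sex + BMI
* rheumatoid arthritis   ~ sex + BMI + prior fracture
* femoral-neck T-score   ~ age + BMI + prior fracture + smoking

Imputation assigns each woman a positive value when a uniform draw from a
seeded stream is at or below her predicted probability, and draws T-scores
as the predicted mean plus (optionally) Gaussian residual noise.  Each
factor gets its own RNG stream derived from the base seed and a stable hash
of the factor name, so adding a factor never perturbs the others' draws.
Validation helpers report age-standardised prevalence differences against
the reference and the sensitivity/specificity of the OSTA screening index.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

#: protocol-fixed covariate sets (enforced at fit time)
COVARIATE_SETS = {
    "parental_hip_fracture": ("age", "prior_fracture"),
    "glucocorticoids": ("age", "sex_female", "bmi"),
    "rheumatoid_arthritis": ("sex_female", "bmi", "prior_fracture"),
    "fn_tscore": ("age", "bmi", "prior_fracture", "current_smoking"),
}

DICHOTOMOUS_FACTORS = ("parental_hip_fracture", "glucocorticoids",
                       "rheumatoid_arthritis")
MIN_REFERENCE_SIZE = 200


class MissingCovariateError(KeyError):
    """A covariate required by an imputation model is absent or missing."""


def factor_seed(base_seed: int, factor: str) -> int:
    """Stable per-factor stream seed (kept below 2**31)."""
    return (int(base_seed) + zlib.crc32(factor.encode())) % (2**31)


def _design_matrix(df: pd.DataFrame, covariates, factor: str) -> np.ndarray:
    cols = [np.ones(len(df))]
    for cov in covariates:
        if cov == "sex_female":
            if "sex" not in df.columns:
                raise MissingCovariateError(f"{factor}: cohort lacks 'sex'")
            x = (df["sex"].astype(str) == "female").to_numpy(dtype=float)
        else:
            if cov not in df.columns:
                raise MissingCovariateError(f"{factor}: cohort lacks {cov!r}")
            x = df[cov].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(x))
        if bad.size:
            raise MissingCovariateError(
                f"{factor}: covariate {cov!r} missing at row(s) {bad[:5].tolist()}")
        cols.append(x)
    return np.column_stack(cols)


@dataclass
class FactorModel:
    """One factor's fitted regression: intercept-first coefficient vector."""

    factor: str
    covariates: tuple
    coef: np.ndarray              # [intercept, *covariates]
    residual_sd: float | None = None   # T-score model only
    intercept_only: bool = False

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        if self.intercept_only:
            return np.full(len(df), self.coef[0])
        return _design_matrix(df, self.covariates, self.factor) @ self.coef


@dataclass
class ImputationModel:
    """Per-factor fitted models, serialisable to/from YAML."""

    factors: dict

    def __getitem__(self, factor: str) -> FactorModel:
        return self.factors[factor]

    def to_yaml(self, path) -> None:
        payload = {}
        for name, fm in self.factors.items():
            entry = {"covariates": list(fm.covariates),
                     "coef": {"intercept": float(fm.coef[0]),
                              **{c: float(v) for c, v in
                                 zip(fm.covariates, fm.coef[1:])}},
                     "intercept_only": bool(fm.intercept_only)}
            if fm.residual_sd is not None:
                entry["residual_sd"] = float(fm.residual_sd)
            payload[name] = entry
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ImputationModel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        factors = {}
        for name, entry in payload.items():
            covs = tuple(entry["covariates"])
            intercept_only = bool(entry.get("intercept_only", False))
            if intercept_only:
                coef = np.array([entry["coef"]["intercept"]], dtype=float)
            else:
                coef = np.array([entry["coef"]["intercept"],
                                 *[entry["coef"][c] for c in covs]],
                                dtype=float)
            factors[name] = FactorModel(
                factor=name, covariates=covs, coef=coef,
                residual_sd=entry.get("residual_sd"),
                intercept_only=intercept_only)
        return cls(factors)


def _fit_logistic(df: pd.DataFrame, factor: str) -> FactorModel:
    covs = COVARIATE_SETS[factor]
    y = df[factor].to_numpy(dtype=float)
    k = float(np.sum(y))
    n = float(len(y))
    if k == 0 or k == n:
        p = (k + 0.5) / (n + 1.0)
        logger.warning("%s: all-%d outcome; intercept-only prevalence model",
                       factor, int(k > 0))
        return FactorModel(factor, covs, np.array([logit(p)]),
                           intercept_only=True)
    X = _design_matrix(df, covs, factor)
    try:
        res = sm.Logit(y, X).fit(disp=False, maxiter=200)
        if not res.mle_retvals.get("converged", True) or not np.all(
                np.isfinite(res.params)):
            raise RuntimeError("logistic fit did not converge")
    except Exception as exc:  # quasi-separation and friends
        logger.warning("%s: %s; falling back to intercept-only model", factor, exc)
        return FactorModel(factor, covs, np.array([logit(k / n)]),
                           intercept_only=True)
    return FactorModel(factor, covs, np.asarray(res.params, dtype=float))


def _fit_linear(df: pd.DataFrame, factor: str = "fn_tscore") -> FactorModel:
    covs = COVARIATE_SETS[factor]
    y = df[factor].to_numpy(dtype=float)
    X = _design_matrix(df, covs, factor)
    res = sm.OLS(y, X).fit()
    rmse = float(np.sqrt(np.mean(res.resid ** 2)))
    return FactorModel(factor, covs, np.asarray(res.params, dtype=float),
                       residual_sd=rmse)


def fit_imputation_model(reference: pd.DataFrame) -> ImputationModel:
    """Fit all factor models on a fully observed reference cohort."""
    needed = set(c for covs in COVARIATE_SETS.values() for c in covs
                 if c != "sex_female") | set(COVARIATE_SETS) | {"sex"}
    missing = needed - set(reference.columns)
    if missing:
        raise MissingCovariateError(f"reference lacks columns {sorted(missing)}")
    if len(reference) < MIN_REFERENCE_SIZE:
        raise ValueError(f"reference cohort too small "
                         f"({len(reference)} < {MIN_REFERENCE_SIZE})")
    if reference[list(needed - {"sex"})].isna().any().any():
        raise ValueError("reference cohort must be fully observed")
    factors = {f: _fit_logistic(reference, f) for f in DICHOTOMOUS_FACTORS}
    factors["fn_tscore"] = _fit_linear(reference)
    return ImputationModel(factors)


def impute_dichotomous(cohort: pd.DataFrame, model: ImputationModel,
                       factor: str, rng_seed: int) -> pd.DataFrame:
    """Fill one dichotomous factor by the uniform-draw assignment rule.

    Each woman's predicted probability p is compared with u ~ Uniform(0,1)
    drawn in record order from the factor's seeded stream; she is positive
    iff u <= p.  Deterministic given the seed.
    """
    fm = model[factor]
    p = expit(fm.linear_predictor(cohort))
    u = np.random.default_rng(factor_seed(rng_seed, factor)).random(len(cohort))
    out = cohort.copy()
    out[factor] = (u <= p).astype(int)
    return out


def impute_tscore(cohort: pd.DataFrame, model: ImputationModel, rng_seed: int,
                  noise: bool = True) -> pd.DataFrame:
    """Fill the femoral-neck T-score from the linear model.

    With ``noise`` (default) a Gaussian residual with the fitted residual SD
    is added from the T-score stream; without it the conditional mean is
    used, which shrinks the imputed T-score variance below any realistic
    population SD.
    """
    fm = model["fn_tscore"]
    mean = fm.linear_predictor(cohort)
    out = cohort.copy()
    if noise:
        eps = np.random.default_rng(
            factor_seed(rng_seed, "fn_tscore")).standard_normal(len(cohort))
        out["fn_tscore"] = mean + fm.residual_sd * eps
    else:
        out["fn_tscore"] = mean
    return out


def impute_all(cohort: pd.DataFrame, model: ImputationModel, rng_seed: int,
               noise: bool = True) -> pd.DataFrame:
    """Impute every blanked factor the cohort is missing."""
    out = cohort
    for factor in DICHOTOMOUS_FACTORS:
        if factor in out.columns and out[factor].isna().all():
            out = impute_dichotomous(out, model, factor, rng_seed)
    if "fn_tscore" in out.columns and out["fn_tscore"].isna().all():
        out = impute_tscore(out, model, rng_seed, noise=noise)
    return out


def prevalence_report(imputed: pd.DataFrame, reference: pd.DataFrame,
                      factors=DICHOTOMOUS_FACTORS,
                      bin_width: float = 5.0) -> pd.DataFrame:
    """Imputed vs age-standardised reference prevalence per factor.

    The target (imputed) cohort's 5-year age distribution is the standard:
    reference bin prevalences are weighted by the target's bin shares.  Bins
    with no reference records are dropped with a warning.
    """
    t_bins = np.floor(imputed["age"] / bin_width) * bin_width
    r_bins = np.floor(reference["age"] / bin_width) * bin_width
    rows = []
    for factor in factors:
        shares = t_bins.value_counts(normalize=True)
        ref_prev = reference.groupby(r_bins)[factor].mean()
        kept = shares.index.intersection(ref_prev.index)
        dropped = shares.index.difference(ref_prev.index)
        if len(dropped):
            logger.warning("%s: no reference records in age bin(s) %s; dropped",
                           factor, sorted(dropped.tolist()))
        w = shares.loc[kept] / shares.loc[kept].sum()
        adj = float((w * ref_prev.loc[kept]).sum())
        obs = float(imputed[factor].mean())
        rows.append({"factor": factor, "imputed_prev": obs,
                     "reference_adjusted_prev": adj,
                     "abs_difference": abs(obs - adj)})
    return pd.DataFrame(rows)


def osta_index(weight_kg, age_years):
    """OSTA screening index: 0.2 * (weight in kg - age in years)."""
    return 0.2 * (np.asarray(weight_kg, dtype=float)
                  - np.asarray(age_years, dtype=float))


def osta_validate(cohort: pd.DataFrame, cutoff: float = -1.0,
                  tscore_threshold: float = -2.5,
                  height_mean_m: float = 1.56, height_sd_m: float = 0.06,
                  seed: int = 0) -> dict:
    """Sensitivity/specificity (%) of OSTA against femoral-neck osteoporosis.

    Screen-positive means index < ``cutoff``; condition-positive means
    T-score <= ``tscore_threshold``.  When the cohort carries no ``weight``
    column, weight is reconstructed from BMI with a Gaussian height model
    (logged).  Returns NaN sensitivity (with a flag) when there are no
    condition-positives.
    """
    if "weight" in cohort.columns and cohort["weight"].notna().all():
        weight = cohort["weight"].to_numpy(dtype=float)
    else:
        logger.info("osta_validate: reconstructing weight from BMI and a "
                    "Normal(%.2f, %.2f) height model", height_mean_m, height_sd_m)
        h = np.random.default_rng(factor_seed(seed, "osta_height")).normal(
            height_mean_m, height_sd_m, size=len(cohort))
        weight = cohort["bmi"].to_numpy(dtype=float) * h ** 2
    ts = cohort["fn_tscore"].to_numpy(dtype=float)
    if np.any(~np.isfinite(ts)):
        raise ValueError("osta_validate requires fn_tscore for every record")
    screen_pos = osta_index(weight, cohort["age"].to_numpy(dtype=float)) < cutoff
    cond_pos = ts <= tscore_threshold
    tp = int(np.sum(screen_pos & cond_pos))
    fn = int(np.sum(~screen_pos & cond_pos))
    tn = int(np.sum(~screen_pos & ~cond_pos))
    fp = int(np.sum(screen_pos & ~cond_pos))
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    if not (tp + fn):
        logger.warning("osta_validate: no condition-positives; "
                       "sensitivity undefined")
    return {"sensitivity_pct": sens, "specificity_pct": spec,
            "tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "sensitivity_defined": bool(tp + fn)}
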