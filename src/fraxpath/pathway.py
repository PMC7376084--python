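"""Case-finding management algorithm and disposition/calibration reports.

Triage of one woman proceeds in the NOGG style:

1. a prior fragility fracture alone makes her eligible for treatment
   (no probability is computed for the decision);
2. otherwise her 10-year MOF probability without BMD is compared with the
   age-specific assessment band: strictly below the lower assessment
   threshold she is discharged; strictly above the upper assessment
   threshold she is treated without a BMD test;
3. inside the band (boundary values included) a femoral-neck BMD T-score is
   obtained — imputed when unmeasured, unless that is disabled — the
   probability is recomputed with BMD and treatment is recommended when it
   is at or above the intervention threshold.

The disposition summary mirrors guidance-audit tables whose rows overlap:
"otherwise eligible" unites treat-above-UAT with treat-after-BMD, "BMD
tests" unites both band outcomes, and "no treatment" unites discharge with
no-treat-after-BMD.  The calibration table bins hip-fracture probability in
left-closed intervals and compares expected with observed event counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imputation import ImputationModel, impute_tscore
from .risk_engine import (HazardModel, expected_fracture_count,
                          ten_year_probability_batch)
from .thresholds import ThresholdCurve

logger = logging.getLogger(__name__)

CATEGORIES = ("treat_prior_fracture", "treat_above_uat", "bmd_then_treat",
              "bmd_then_no_treat", "no_treat_below_lat")


def triage(cohort: pd.DataFrame, curve: ThresholdCurve, model: HazardModel,
           imputation_model: ImputationModel | None = None,
           seed: int = 0, require_bmd: bool = False,
           noise: bool = True) -> pd.DataFrame:
    """Assign each woman exactly one disposition category.

    Returns one record per woman: her category, MOF probabilities without
    BMD (and with BMD where a test was indicated), hip probabilities, the
    thresholds at her age, and whether her T-score had to be imputed.
    Comparisons use unrounded probabilities and thresholds.
    """
    if cohort["id"].duplicated().any():
        raise ValueError("duplicate ids in cohort")
    n = len(cohort)
    ages = cohort["age"].to_numpy(dtype=float)
    lat = curve.lat(ages)
    it = curve.it(ages)
    uat = curve.uat(ages)

    mof_no = ten_year_probability_batch(cohort, model, "mof", use_tscore=False)
    hip_no = ten_year_probability_batch(cohort, model, "hip", use_tscore=False)

    prior = cohort["prior_fracture"].to_numpy(dtype=float) > 0
    below = ~prior & (mof_no < lat)
    above = ~prior & (mof_no > uat)
    band = ~prior & ~below & ~above

    category = np.empty(n, dtype=object)
    category[prior] = "treat_prior_fracture"
    category[below] = "no_treat_below_lat"
    category[above] = "treat_above_uat"

    mof_with = np.full(n, np.nan)
    hip_with = np.full(n, np.nan)
    tscore_used = cohort["fn_tscore"].to_numpy(dtype=float).copy()
    tscore_imputed = np.zeros(n, dtype=bool)
    if band.any():
        need = band & ~np.isfinite(tscore_used)
        if need.any():
            if require_bmd or imputation_model is None:
                rows = cohort.loc[need, "id"].tolist()[:5]
                raise ValueError(
                    f"{int(need.sum())} women in the BMD band lack a T-score "
                    f"and imputation is unavailable (e.g. ids {rows})")
            filled = impute_tscore(cohort.loc[need], imputation_model,
                                   rng_seed=seed, noise=noise)
            tscore_used[need] = filled["fn_tscore"].to_numpy(dtype=float)
            tscore_imputed[need] = True
        sub = cohort.loc[band].copy()
        sub["fn_tscore"] = tscore_used[band]
        mof_with[band] = ten_year_probability_batch(sub, model, "mof",
                                                    use_tscore=True)
        hip_with[band] = ten_year_probability_batch(sub, model, "hip",
                                                    use_tscore=True)
        treat = band & (mof_with >= it)
        category[treat] = "bmd_then_treat"
        category[band & ~treat] = "bmd_then_no_treat"

    return pd.DataFrame({
        "id": cohort["id"].to_numpy(),
        "age": ages,
        "category": category,
        "mof_pct_no_bmd": mof_no,
        "hip_pct_no_bmd": hip_no,
        "mof_pct_with_bmd": mof_with,
        "hip_pct_with_bmd": hip_with,
        "fn_tscore_used": tscore_used,
        "tscore_imputed": tscore_imputed,
        "lat_pct": lat, "it_pct": it, "uat_pct": uat,
    })


_SUMMARY_ROWS = {
    "entire_cohort": CATEGORIES,
    "treated_prior_fracture": ("treat_prior_fracture",),
    "otherwise_eligible": ("treat_above_uat", "bmd_then_treat"),
    "bmd_tests": ("bmd_then_treat", "bmd_then_no_treat"),
    "no_treatment": ("no_treat_below_lat", "bmd_then_no_treat"),
}


def disposition_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Audit table with overlapping guidance-style rows.

    Per row: count, % of cohort, mean T-score where known, and mean MOF/hip
    probabilities without BMD (and with BMD where computed).  Base-category
    counts partition the cohort exactly; the derived rows overlap by design.
    """
    if records["id"].duplicated().any():
        raise ValueError("duplicate ids in disposition records")
    n = len(records)
    rows = []
    all_rows = dict(_SUMMARY_ROWS)
    all_rows.update({c: (c,) for c in CATEGORIES})
    for name, cats in all_rows.items():
        sub = records[records["category"].isin(cats)]
        rows.append({
            "row": name,
            "count": len(sub),
            "pct": 100.0 * len(sub) / n if n else np.nan,
            "mean_fn_tscore": float(np.nanmean(sub["fn_tscore_used"]))
            if sub["fn_tscore_used"].notna().any() else np.nan,
            "mean_mof_pct_no_bmd": float(sub["mof_pct_no_bmd"].mean()),
            "mean_hip_pct_no_bmd": float(sub["hip_pct_no_bmd"].mean()),
            "mean_mof_pct_with_bmd": float(np.nanmean(sub["mof_pct_with_bmd"]))
            if sub["mof_pct_with_bmd"].notna().any() else np.nan,
            "mean_hip_pct_with_bmd": float(np.nanmean(sub["hip_pct_with_bmd"]))
            if sub["hip_pct_with_bmd"].notna().any() else np.nan,
        })
    out = pd.DataFrame(rows)
    base = out[out["row"].isin(CATEGORIES)]
    if int(base["count"].sum()) != n:
        raise AssertionError("disposition categories failed to partition cohort")
    return out


def left_closed_bins(values_pct, bin_width: float) -> np.ndarray:
    """Bin index under the left-closed convention [k*w, (k+1)*w).

    A value exactly on an edge belongs to the higher bin (e.g. 1.0 with
    width 1 falls in [1, 2)).
    """
    return np.floor(np.asarray(values_pct, dtype=float) / bin_width).astype(int)


def calibration_table(cohort: pd.DataFrame, model: HazardModel,
                      bin_width: float = 1.0, use_tscore: bool = False,
                      outcome: str = "hip") -> pd.DataFrame:
    """Expected vs observed fracture counts by baseline probability bin.

    Women are binned on their 10-year probability (%) in left-closed
    intervals [k*w, (k+1)*w): a value exactly on an edge falls in the higher
    bin.  Expected counts sum each woman's probability truncated to her own
    follow-up (death competing); observed counts are the recorded events.
    Cumulative columns accumulate from the lowest bin.
    """
    fu = cohort["followup_years"].to_numpy(dtype=float)
    if np.any(~np.isfinite(fu)) or np.any(fu < 0):
        raise ValueError("calibration requires non-negative follow-up for all")
    obs = cohort["hip_fracture_observed"].to_numpy(dtype=float)
    if np.any(~np.isfinite(obs)):
        raise ValueError("calibration requires observed outcomes for all")
    p10 = ten_year_probability_batch(cohort, model, outcome, use_tscore=use_tscore)
    p_fu = ten_year_probability_batch(cohort, model, outcome,
                                      use_tscore=use_tscore, horizons=fu) / 100.0
    idx = left_closed_bins(p10, bin_width)
    rows = []
    for k in range(int(idx.max()) + 1):
        m = idx == k
        rows.append({"bin_lo_pct": k * bin_width,
                     "bin_hi_pct": (k + 1) * bin_width,
                     "n": int(m.sum()),
                     "expected": float(p_fu[m].sum()),
                     "observed": int(obs[m].sum())})
    out = pd.DataFrame(rows)
    out["cum_expected"] = out["expected"].cumsum()
    out["cum_observed"] = out["observed"].cumsum()
    return out


def calibration_totals(cohort: pd.DataFrame, model: HazardModel,
                       use_tscore: bool = False,
                       outcome: str = "hip") -> dict:
    """Total observed events, total expected, and person-years."""
    expected = expected_fracture_count(cohort, model, outcome=outcome,
                                       use_tscore=use_tscore)
    return {"observed": int(cohort["hip_fracture_observed"].sum()),
            "expected": expected,
            "person_years": float(cohort["followup_years"].sum())}
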