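"""Age-dependent intervention and assessment thresholds.

Following the risk-equivalence approach used by UK (NOGG-style) FRAX
guidance, the intervention threshold (IT) at each age is the 10-year major
osteoporotic fracture probability, computed without BMD, of a woman of
population-average BMI whose only clinical risk factor is a prior fragility
fracture.  The lower assessment threshold (LAT) is the same probability with
no risk factors at all, and the upper assessment threshold (UAT) is a fixed
multiple of the IT (default 1.2).  Per-ethnicity probabilities are combined
with age-specific population weights.  Thresholds are evaluated on a 5-year
age grid from 40 to 90 with linear interpolation in between; all pathway
comparisons use unrounded values, with 2-decimal rounding applied only for
display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .risk_engine import (AGE_MAX, AGE_MIN, ConfigurationError, HazardModel,
                          RiskProfile, ten_year_probability)

logger = logging.getLogger(__name__)

GRID_AGES = tuple(float(a) for a in range(40, 95, 5))
DEFAULT_UAT_FACTOR = 1.2


def _bin_lo(age: float) -> int:
    """Lower edge of the 5-year age bin holding ``age`` (bins 40..85 tile 40-90)."""
    return int(min(max(5 * (int(age) // 5), 40), 85))


@dataclass
class PopulationWeights:
    """Ethnic population proportions per 5-year age bin (lower edges 40..85)."""

    entries: pd.DataFrame  # columns: ethnicity, age_lo, proportion

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.entries)
        required = {"ethnicity", "age_lo", "proportion"}
        if not required.issubset(df.columns):
            raise ConfigurationError(f"weights need columns {sorted(required)}")
        bins = sorted(df["age_lo"].unique())
        if bins != list(range(40, 90, 5)):
            raise ConfigurationError(
                f"age bins must be the 5-year bins 40..85, got {bins}")
        sums = df.groupby("age_lo")["proportion"].sum()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ConfigurationError(f"bin proportions must sum to 1: {sums.to_dict()}")
        self.entries = df

    def at_age(self, age: float) -> dict[str, float]:
        lo = _bin_lo(age)
        sub = self.entries[self.entries["age_lo"] == lo]
        return dict(zip(sub["ethnicity"], sub["proportion"]))

    def ethnicities(self) -> list[str]:
        return sorted(self.entries["ethnicity"].unique())


@dataclass
class BmiReference:
    """Mean BMI (kg/m2) by ethnicity and 5-year age bin."""

    table: Mapping[tuple[str, int], float]

    def __post_init__(self) -> None:
        for (eth, lo), v in self.table.items():
            if not (14.0 < v < 45.0):
                raise ConfigurationError(f"implausible BMI {v} for ({eth}, {lo})")

    def lookup(self, ethnicity: str, age: float) -> float:
        key = (ethnicity, _bin_lo(age))
        try:
            return float(self.table[key])
        except KeyError:
            raise ConfigurationError(f"no BMI reference for {key}") from None


def _weighted_probability(age: float, models: Mapping[str, HazardModel],
                          weights: PopulationWeights, bmi_ref: BmiReference,
                          prior_fracture: int) -> float:
    w = weights.at_age(age)
    total = 0.0
    for eth, weight in w.items():
        if eth not in models:
            raise ConfigurationError(f"weights include ethnicity {eth!r} "
                                     f"with no hazard model")
        profile = RiskProfile(age=age, bmi=bmi_ref.lookup(eth, age),
                              sex="female", prior_fracture=prior_fracture)
        total += weight * ten_year_probability(profile, models[eth]).mof_pct
    return total


def intervention_threshold(age: float, models: Mapping[str, HazardModel],
                           weights: PopulationWeights,
                           bmi_ref: BmiReference) -> float:
    """IT (%): population-weighted MOF probability of the prior-fracture profile."""
    return _weighted_probability(age, models, weights, bmi_ref, prior_fracture=1)


def lower_assessment_threshold(age: float, models: Mapping[str, HazardModel],
                               weights: PopulationWeights,
                               bmi_ref: BmiReference) -> float:
    """LAT (%): population-weighted MOF probability with no clinical risk factors."""
    return _weighted_probability(age, models, weights, bmi_ref, prior_fracture=0)


def upper_assessment_threshold(it_pct: float,
                               uat_factor: float = DEFAULT_UAT_FACTOR) -> float:
    """UAT (%) = uat_factor x IT, capped at 100."""
    if it_pct < 0:
        raise ValueError(f"intervention threshold must be non-negative, got {it_pct}")
    return min(uat_factor * it_pct, 100.0)


@dataclass
class ThresholdCurve:
    """IT/LAT/UAT on the 5-year age grid with linear off-grid interpolation."""

    ages: np.ndarray
    it_pct: np.ndarray
    lat_pct: np.ndarray
    uat_pct: np.ndarray
    uat_factor: float = DEFAULT_UAT_FACTOR

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.it_pct = np.asarray(self.it_pct, dtype=float)
        self.lat_pct = np.asarray(self.lat_pct, dtype=float)
        self.uat_pct = np.asarray(self.uat_pct, dtype=float)
        if not np.all(np.diff(self.ages) > 0):
            raise ConfigurationError("threshold curve age grid must be increasing")
        if not (np.all(self.lat_pct < self.it_pct)
                and np.all(self.it_pct < self.uat_pct)):
            raise ConfigurationError("need LAT < IT < UAT at every grid age")

    def _interp(self, values: np.ndarray, age) -> np.ndarray:
        a = np.asarray(age, dtype=float)
        if np.any(a < self.ages[0]) or np.any(a > self.ages[-1]):
            logger.warning("threshold lookup outside [%g, %g]; clamped",
                           self.ages[0], self.ages[-1])
            a = np.clip(a, self.ages[0], self.ages[-1])
        return np.interp(a, self.ages, values)

    def it(self, age):
        return self._interp(self.it_pct, age)

    def lat(self, age):
        return self._interp(self.lat_pct, age)

    def uat(self, age):
        return self._interp(self.uat_pct, age)

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"age": self.ages, "it_pct": self.it_pct,
                           "lat_pct": self.lat_pct, "uat_pct": self.uat_pct})
        return df.round(decimals) if decimals is not None else df

    def to_csv(self, path, decimals: int | None = None) -> None:
        self.to_frame(decimals).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, uat_factor: float = DEFAULT_UAT_FACTOR) -> "ThresholdCurve":
        """Load a curve verbatim, e.g. a published threshold table."""
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(ages=df["age"], it_pct=df["it_pct"], lat_pct=df["lat_pct"],
                   uat_pct=df["uat_pct"], uat_factor=uat_factor)


def build_threshold_curve(models: Mapping[str, HazardModel],
                          weights: PopulationWeights, bmi_ref: BmiReference,
                          uat_factor: float = DEFAULT_UAT_FACTOR) -> ThresholdCurve:
    """Evaluate IT/LAT on the 5-year grid 40-90 and derive UAT before rounding."""
    it = np.array([intervention_threshold(a, models, weights, bmi_ref)
                   for a in GRID_AGES])
    lat = np.array([lower_assessment_threshold(a, models, weights, bmi_ref)
                    for a in GRID_AGES])
    uat = np.array([upper_assessment_threshold(x, uat_factor) for x in it])
    return ThresholdCurve(ages=np.array(GRID_AGES), it_pct=it, lat_pct=lat,
                          uat_pct=uat, uat_factor=uat_factor)


def population_weights_from_dict(cfg: Sequence[Mapping]) -> PopulationWeights:
    return PopulationWeights(pd.DataFrame(cfg))


def bmi_reference_from_dict(cfg: Mapping[str, Mapping]) -> BmiReference:
    """``{ethnicity: {age_lo: bmi, ...}, ...}`` from YAML."""
    table = {(eth, int(lo)): float(v)
             for eth, by_age in cfg.items() for lo, v in by_age.items()}
    return BmiReference(table)
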