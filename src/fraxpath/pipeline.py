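"""End-to-end case-finding run: simulate, impute, derive thresholds, triage,
calibrate, and write a reproducible report bundle.

Every stochastic stage draws from a seed recorded in the run manifest, and
every output CSV is written with a fixed float format, so re-running with
the same configuration reproduces the bundle byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imputation import (fit_imputation_model, impute_all, osta_validate,
                         prevalence_report)
from .io import FLOAT_FORMAT, read_cohort, write_cohort
from .pathway import (calibration_table, calibration_totals,
                      disposition_summary, triage)
from .risk_engine import HazardModel, load_hazard_models
from .synthetic import (CohortSpec, FollowupSpec, generate_reference_cohort,
                        generate_target_cohort, simulate_followup)
from .thresholds import (ThresholdCurve, bmi_reference_from_dict,
                         build_threshold_curve, population_weights_from_dict)

logger = logging.getLogger(__name__)


def default_model_path() -> Path:
    return Path(resources.files("fraxpath") / "data" / "default_model.yaml")


def published_curve_path() -> Path:
    return Path(resources.files("fraxpath") / "data"
                / "singapore_thresholds_published.csv")


def load_full_config(path=None):
    """Hazard models + population weights + BMI reference from one YAML."""
    path = path or default_model_path()
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    models = load_hazard_models(path)
    weights = population_weights_from_dict(cfg["population_weights"])
    bmi_ref = bmi_reference_from_dict(cfg["bmi_reference_by_age"])
    return models, weights, bmi_ref, float(cfg.get("uat_factor", 1.2))


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str
    n: int = 29323
    n_reference: int = 4000
    seed: int = 1
    model_config: str | None = None     # default surrogate config when None
    curve_csv: str | None = None        # engine-derived curve when None
    cohort_csv: str | None = None       # generated when None
    triage_ethnicity: str = "chinese"
    uat_factor: float | None = None     # model-config value when None
    osta_cutoff: float = -1.0
    bin_width: float = 1.0
    tscore_noise: bool = True
    make_plots: bool = True

    # derived per-stage seeds (recorded in the manifest)
    def stage_seeds(self) -> dict:
        base = int(self.seed) % (2**20)
        return {"cohort": base * 1000 + 1, "reference": base * 1000 + 2,
                "impute": base * 1000 + 3, "followup": base * 1000 + 4,
                "triage": base * 1000 + 5, "osta": base * 1000 + 6}

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**cfg)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    stage = "configuration"
    try:
        models, weights, bmi_ref, cfg_uat = load_full_config(config.model_config)
        uat_factor = config.uat_factor if config.uat_factor is not None else cfg_uat
        engine = models[config.triage_ethnicity]

        stage = "simulate"
        spec = CohortSpec(n=config.n)
        if config.cohort_csv:
            cohort = read_cohort(config.cohort_csv)
            truth = cohort
        else:
            cohort, truth = generate_target_cohort(spec, seed=seeds["cohort"])
            truth = simulate_followup(truth, engine, FollowupSpec(),
                                      seed=seeds["followup"])
            cohort[["followup_years", "hip_fracture_observed"]] = \
                truth[["followup_years", "hip_fracture_observed"]]
            write_cohort(cohort, out / "cohort.csv")
            write_cohort(truth, out / "cohort_truth.csv")
        logger.info("stage simulate: %d target rows", len(cohort))

        stage = "fit-impute"
        reference = generate_reference_cohort(config.n_reference,
                                              seed=seeds["reference"], spec=spec)
        imodel = fit_imputation_model(reference)
        imodel.to_yaml(out / "imputation_model.yaml")
        logger.info("stage fit-impute: %d reference rows", len(reference))

        stage = "impute"
        imputed = impute_all(cohort, imodel, rng_seed=seeds["impute"],
                             noise=config.tscore_noise)
        write_cohort(imputed, out / "cohort_imputed.csv")
        prev = prevalence_report(imputed, reference)
        _write_csv(prev, out / "prevalence_check.csv")
        osta = osta_validate(imputed, cutoff=config.osta_cutoff,
                             seed=seeds["osta"])

        stage = "thresholds"
        if config.curve_csv:
            curve = ThresholdCurve.from_csv(config.curve_csv,
                                            uat_factor=uat_factor)
        else:
            curve = build_threshold_curve(models, weights, bmi_ref,
                                          uat_factor=uat_factor)
        curve.to_csv(out / "threshold_curve.csv")
        curve.to_csv(out / "threshold_curve_display.csv", decimals=2)

        stage = "triage"
        records = triage(imputed, curve, engine, imputation_model=imodel,
                         seed=seeds["triage"], noise=config.tscore_noise)
        _write_csv(records, out / "dispositions.csv")
        summary = disposition_summary(records)
        _write_csv(summary, out / "disposition_summary.csv")
        (out / "disposition_summary.txt").write_text(
            summary.to_string(index=False, float_format=lambda v: f"{v:.2f}")
            + "\n")

        stage = "calibration"
        calib = calibration_table(imputed, engine, bin_width=config.bin_width,
                                  use_tscore=True)
        _write_csv(calib, out / "calibration.csv")
        totals = calibration_totals(imputed, engine, use_tscore=True)

        if config.make_plots:
            stage = "plots"
            _plot_calibration(calib, out / "calibration.svg")
            _plot_threshold_zones(curve, out / "threshold_zones.svg")

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "seeds": seeds,
            "n_cohort": int(len(cohort)),
            "n_reference": int(len(reference)),
            "uat_factor": uat_factor,
            "osta": {k: osta[k] for k in
                     ("sensitivity_pct", "specificity_pct")},
            "calibration_totals": totals,
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True) + "\n")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _plot_calibration(calib: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    x = calib["bin_lo_pct"]
    w = calib["bin_hi_pct"] - calib["bin_lo_pct"]
    ax.bar(x, calib["expected"], width=0.4 * w, align="edge",
           label="expected", color="tab:blue")
    ax.bar(x + 0.4 * w, calib["observed"], width=0.4 * w, align="edge",
           label="observed", color="tab:orange")
    ax.set_xlabel("10-year hip fracture probability at baseline (%)")
    ax.set_ylabel("first hip fractures during follow-up")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _plot_threshold_zones(curve: ThresholdCurve, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ages = curve.ages
    top = float(np.max(curve.uat_pct)) * 1.15
    ax.fill_between(ages, curve.uat_pct, top, color="#d62728", alpha=0.5,
                    label="treat")
    ax.fill_between(ages, curve.lat_pct, curve.uat_pct, color="#ff7f0e",
                    alpha=0.5, label="measure BMD")
    ax.fill_between(ages, 0, curve.lat_pct, color="#2ca02c", alpha=0.5,
                    label="no treatment")
    ax.plot(ages, curve.it_pct, "k--", label="intervention threshold")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("10-year MOF probability (%)")
    ax.legend(loc="upper left")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
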