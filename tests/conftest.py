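import numpy as np
import pytest

from fraxpath.pipeline import load_full_config, published_curve_path
from fraxpath.risk_engine import CLINICAL_RISK_FACTORS, AgeCurve, HazardModel
from fraxpath.thresholds import ThresholdCurve


def make_constant_model(h_mof, h_death, h_hip=None, log_rr=None,
                        bmd_log_rr=0.4055, bmi_log_rr=0.0,
                        tscore_mean=-1.89, ethnicity="test"):
    """Constant-hazard model: every closed-form check builds on this."""
    if h_hip is None:
        h_hip = h_mof
    ages = [40.0, 105.0]
    rr = {k: 0.0 for k in CLINICAL_RISK_FACTORS}
    rr["prior_fracture"] = np.log(1.8)
    rr["bmi_per_unit"] = bmi_log_rr
    if log_rr:
        rr.update(log_rr)
    return HazardModel(
        ethnicity=ethnicity,
        mof_hazard=AgeCurve(ages, [h_mof, h_mof], "mof"),
        hip_hazard=AgeCurve(ages, [h_hip, h_hip], "hip"),
        death_hazard=AgeCurve(ages, [h_death, h_death], "death"),
        log_rr=rr,
        bmd_log_rr_per_sd=bmd_log_rr,
        tscore_mean_by_age=AgeCurve(ages, [tscore_mean, tscore_mean], "tmean"),
    )


def closed_form_competing(lf, ld, horizon=10.0):
    """P(first f-event by `horizon`) under constant cause-specific hazards."""
    tot = lf + ld
    if tot == 0:
        return 0.0
    return lf / tot * (1.0 - np.exp(-horizon * tot))


@pytest.fixture(scope="session")
def default_config():
    return load_full_config()


@pytest.fixture(scope="session")
def default_models(default_config):
    return default_config[0]


@pytest.fixture(scope="session")
def engine(default_models):
    return default_models["chinese"]


@pytest.fixture(scope="session")
def published_curve():
    return ThresholdCurve.from_csv(published_curve_path())
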