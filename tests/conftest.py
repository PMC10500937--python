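import numpy as np
import pandas as pd
import pytest

from iculos import (ModelSpec, Registry, default_sim_config, fit_glmm_log_gaussian,
                    fit_lmm, generate_registry, predict_los, simple_sim_config)

SMALL_TERMS = ["apache3", "log_anzrod", "vent_d1", "died_icu"]
SMALL_BETA = {"intercept": 0.6, "apache3": 0.008, "log_anzrod": 0.08,
              "vent_d1": 0.4, "died_icu": -0.4}


@pytest.fixture(scope="session")
def small_spec():
    return ModelSpec(fixed_terms=SMALL_TERMS, interactions=[])


@pytest.fixture(scope="session")
def registry20():
    """20 ICUs x 150 patients, lognormal noise, known ground truth."""
    cfg = simple_sim_config(20, 150, beta=SMALL_BETA, gen_terms=SMALL_TERMS,
                            tau2=0.05, sigma2=0.8, seed=5)
    return generate_registry(cfg)


@pytest.fixture(scope="session")
def lmm20(registry20, small_spec):
    return fit_lmm(registry20, small_spec)


@pytest.fixture(scope="session")
def glmm20(registry20, small_spec, lmm20):
    return fit_glmm_log_gaussian(registry20, small_spec, start_from=lmm20)


@pytest.fixture(scope="session")
def fe_days20(glmm20, registry20):
    return predict_los(glmm20, registry20, mode="FE", scale="days").values


@pytest.fixture(scope="session")
def fe_log20(lmm20, registry20):
    return predict_los(lmm20, registry20, mode="FE", scale="log_days").values


@pytest.fixture(scope="session")
def default_registry():
    """The full calibrated cohort emulation (125 ICUs, ~94k admissions)."""
    return generate_registry(default_sim_config(seed=1))


def registry_from_los(los_by_icu: dict, male=None) -> Registry:
    """Tiny hand-built registry with valid covariates and prescribed LOS."""
    rows = []
    for icu, los_list in los_by_icu.items():
        for k, los in enumerate(los_list):
            rows.append({
                "icu_id": icu, "age": 60.0 + k, "apache3": 50 + k,
                "anzrod": 0.02, "preicu_days": 0.5, "died_icu": 0, "arf": 0,
                "limitation": 0, "arrest": 0, "vent_d1": k % 2,
                "dx_group": 1 + (k % 3), "los_days": float(los),
                "male": (male if male is not None else k % 2),
            })
    patients = pd.DataFrame(rows)
    sites = pd.DataFrame({
        "icu_id": list(los_by_icu),
        "hosp_class": ["MET"] * len(los_by_icu),
        "annual_volume": [len(v) for v in los_by_icu.values()],
    })
    return Registry(patients=patients, sites=sites)
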