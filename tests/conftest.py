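"""Shared fixtures: published odds ratios, a tiny hand-built event fixture,
and session-scoped synthetic cohorts reused across tests."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from drainsurv.model import PredictionRule, build_prediction_rule
from drainsurv.synth_cohort import (
    GeneratorConfig,
    RawEventTables,
    generate_cohort,
    generate_model_cohort,
)

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*convergence.*")

# published multivariable odds ratios of the final model
PUBLISHED_ORS = {
    "drain_type_evd": 5.26,
    "n_drains": 2.04,
    "crp": 1.02,
    "crp_sq": 0.99,
    "crp_cu": 1.26,
    "blood_leukocytes": 1.08,
    "csf_leukocytes_log": 1.42,
    "culture_positive": 13.70,
    "empiric_abx": 1.32,
    "n_abx_started": 4.33,
}


@pytest.fixture(scope="session")
def published_ors():
    return dict(PUBLISHED_ORS)


@pytest.fixture(scope="session")
def published_rule():
    """Published-OR rule with intercept calibrated to 15.3 % prevalence on a
    large reference draw."""
    betas = {k: float(np.log(v)) for k, v in PUBLISHED_ORS.items()}
    ref, _, _ = generate_model_cohort(PredictionRule(0.0, betas), 20_000, seed=991)
    return build_prediction_rule(PUBLISHED_ORS, reference_X=ref, prevalence=0.153)


@pytest.fixture(scope="session")
def big_cohort():
    """n = 20 000 complete cohort for distribution-calibration checks."""
    return generate_cohort(GeneratorConfig(n_patients=20_000, seed=20240101))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(GeneratorConfig(n_patients=537, seed=11))


def _tiny_tables() -> RawEventTables:
    """Five-event hand-computable fixture: one adult patient, one EVD,
    two CRP values, one CSF leukocyte value, one positive culture (S. aureus),
    vancomycin + ceftazidime started day 6."""
    patients = pd.DataFrame(
        {
            "patient_id": [1],
            "age": [60.0],
            "sex_female": [1],
            "admission_day": [0],
            "discharge_day": [30],
            "icu_days": [5],
            "death_day": [-1],
            "preexisting_cns_infection": [0],
            "placed_other_centre": [0],
            "external_site": [0],
            "year": [2006],
        }
    )
    drains = pd.DataFrame(
        {
            "patient_id": [1],
            "drain_type": ["EVD"],
            "insertion_day": [3],
            "removal_day": [10],
            "indication": ["sah_ivh"],
        }
    )
    labs = pd.DataFrame(
        {
            "patient_id": [1, 1, 1],
            "day": [4, 8, 9],
            "analyte": ["crp", "crp", "csf_leukocytes"],
            "value": [50.0, 200.0, 12.0],
            "unit": ["mg/L", "mg/L", "1e2/uL"],
        }
    )
    cultures = pd.DataFrame(
        {
            "patient_id": [1],
            "day": [7],
            "site": ["csf"],
            "organism": ["Staphylococcus aureus"],
            "cons_flag": [0],
            "positive_flag": [1],
        }
    )
    antibiotics = pd.DataFrame(
        {
            "patient_id": [1, 1],
            "agent": ["vancomycin", "ceftazidime"],
            "start_day": [6, 6],
            "systemic_flag": [1, 1],
        }
    )
    outcomes = pd.DataFrame(
        {"patient_id": [1], "drm_flag": [1], "infection_day": [7]}
    )
    return RawEventTables(patients, drains, labs, cultures, antibiotics, outcomes)


@pytest.fixture()
def tiny_tables():
    return _tiny_tables()
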