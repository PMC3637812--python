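import numpy as np
import pandas as pd
import pytest

import coloscreen as cs


@pytest.fixture(scope="session")
def default_dictionary():
    return cs.CodeDictionary.default()


@pytest.fixture(scope="session")
def study_cohort():
    """Default-sized synthetic cohort (n = 1,230) with a fixed seed."""
    cfg = cs.SyntheticConfig.default()
    return cs.generate_cohort(cfg)


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort (n = 100,000) for Monte-Carlo marginal checks."""
    cfg = cs.SyntheticConfig.default()
    cfg.n_patients = 100_000
    cfg.seed = 424242
    return cs.generate_cohort(cfg)


@pytest.fixture(scope="session")
def study_features(study_cohort, default_dictionary):
    truth, indicators, claims = study_cohort
    return cs.extract_features(claims, truth, default_dictionary)


def make_cohort_frame(patients):
    """cohort table from [(patient_id, index_date), ...] with dummy age/sex."""
    return pd.DataFrame(
        {
            "patient_id": [p for p, _ in patients],
            "age": 60,
            "sex": "F",
            "index_date": [d for _, d in patients],
        }
    )


def make_claims_frame(rows):
    """claims table from [(patient_id, date, code, system, record_type), ...]."""
    return pd.DataFrame(
        rows, columns=["patient_id", "date", "code", "code_system", "record_type"]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
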