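import numpy as np
import pandas as pd
import pytest

from statinadh.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-signal cohort shared by read-only tests."""
    cfg = SimConfig(
        n_patients=600, n_latent_factors=5, n_code_vars=60, n_drug_vars=30,
        n_lab_vars=8, seed=11,
        adherence_intercept=0.2,
        adherence_coefficients={"age_std": 0.8, "factor_0": 0.4},
        adherence_event_coefficient=-0.4,
        event_coefficients={1: 0.4},
        base_event_rate=4e-4,
    )
    return generate_cohort(cfg)


def toy_claims(rows):
    """Build a claims frame from (patient_id, month, kind, code, value,
    days_supply, new_refill_flag) tuples; missing tail entries default."""
    recs = []
    for r in rows:
        r = list(r) + [None] * (7 - len(r))
        recs.append({
            "patient_id": r[0], "month": r[1], "kind": r[2], "code": r[3],
            "value": r[4] if r[4] is not None else np.nan,
            "days_supply": r[5] if r[5] is not None else np.nan,
            "strength": 10.0 if r[2] == "drug" else np.nan,
            "new_refill_flag": r[6] if r[2] == "drug" else np.nan,
        })
    return pd.DataFrame(recs)


def toy_demo(pids, age=50):
    return pd.DataFrame({
        "patient_id": list(pids),
        "age": [age] * len(pids) if np.isscalar(age) else list(age),
        "sex": "M", "race": "white", "tobacco": False,
        "pharmacy_program": "retail",
    })
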