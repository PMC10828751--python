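import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from pewrisk import Cohort, SimulationConfig, generate, load_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def synthetic_cohort():
    """Default-config synthetic cohort at the published size."""
    return generate(SimulationConfig(n=868, seed=20240))


def make_patient_row(
    patient_id="P1",
    sex="M",
    marital="married",
    age=60.0,
    bmi=22.0,
    functional="normal",
    vintage_years=0.5,
    albumin_gL=40.0,
    ferritin_ugL=200.0,
    dm=0,
    htn=0,
    ihd=0,
    cvd=0,
    epo=0,
    hemoglobin_gL=110.0,
    ktv=1.5,
    adm_vascular=0,
    adm_nonvascular=0,
    died=0,
    quarter=0,
):
    return dict(locals())


@pytest.fixture
def toy_cohort():
    """Ten hand-constructed patients: five scoring 0 (low), five scoring >=6 (high)."""
    rows = []
    for i in range(5):
        rows.append(make_patient_row(patient_id=f"L{i}", sex="M" if i < 3 else "F"))
    for i in range(5):
        rows.append(
            make_patient_row(
                patient_id=f"H{i}",
                sex="F" if i < 3 else "M",
                bmi=15.0,
                functional="bed_chair_bound",
                vintage_years=6.0,
                albumin_gL=25.0,
                ferritin_ugL=1200.0,
                dm=1, htn=1, ihd=1, cvd=1,
                died=1 if i < 2 else 0,
            )
        )
    return Cohort(data=pd.DataFrame(rows), provenance="synthetic")


def brute_force_chi2(counts: np.ndarray) -> float:
    """Independent oracle: direct cell-by-cell sum of (O-E)^2 / E."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            expected = counts[i].sum() * counts[:, j].sum() / total
            stat += (counts[i, j] - expected) ** 2 / expected
    return stat
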