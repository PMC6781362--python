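import numpy as np
import pytest

from pembropred.cohort import CohortConfig, generate_cohort
from pembropred.dynamics import ModelParameters
from pembropred.records import PatientRecord, ScanPoint


@pytest.fixture(scope="session")
def base_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Small noise-free cohort: fits and intervals are exact round trips."""
    return generate_cohort(CohortConfig(n_patients=14, seed=3, noise_sigma=0.0))


@pytest.fixture(scope="session")
def noisy_cohort():
    """Small cohort under the default observation noise."""
    return generate_cohort(CohortConfig(n_patients=12, seed=7))


def make_record(patient_id: str, days, sods, followup_end: float,
                covariates: dict | None = None, center: str = "") -> PatientRecord:
    cov = {"baseline_sod": float(sods[0])}
    cov.update(covariates or {})
    return PatientRecord(patient_id=patient_id, covariates=cov,
                         scans=[ScanPoint(float(d), float(s))
                                for d, s in zip(days, sods)],
                         followup_end=followup_end, center=center)


@pytest.fixture(scope="session")
def synthetic_record(base_params):
    """Noise-free single patient generated at (a_pem=500, gamma=0.005)."""
    from pembropred.calibration import predict_sod

    days = [0.0, 90.0, 180.0, 270.0, 365.0]
    stub = make_record("X", [0.0], [79.0], 365.0)
    truth = base_params.personalized(a_pem=500.0, gamma_mel=0.005)
    sod = predict_sod(truth, stub, days=days)
    return make_record("X", days, sod, 365.0), truth
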