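import numpy as np
import pytest

from tacmipd import (CovariateState, DoseEvent, EtaPair, Observation,
                     PatientRecord, concentration_profile, demo_model)


@pytest.fixture(scope="session")
def model():
    return demo_model()


@pytest.fixture()
def reference_cov(model):
    """Covariates at the model's reference values (no fluconazole)."""
    return CovariateState(age=model.age_ref, crcl=model.crcl_ref, fluconazole=False)


@pytest.fixture()
def simple_patient(model):
    """Four 2 mg doses q12h, constant covariates, three noise-free troughs."""
    doses = [DoseEvent(time=12.0 * j, amount=2.0) for j in range(4)]
    cov = [CovariateState(age=6.0, crcl=110.0, fluconazole=False)]
    proto = PatientRecord(doses=doses, covariates=cov, id="simple")
    times = [12.0, 24.0, 36.0]
    conc = concentration_profile(proto, model, EtaPair(0.1, -0.1), times)
    obs = [Observation(time=t, concentration=float(c)) for t, c in zip(times, conc)]
    return PatientRecord(doses=doses, observations=obs, covariates=cov, id="simple")


def random_patient(rng: np.random.Generator, model, n_doses=None, n_obs=None,
                   with_cov_change=False):
    """Small random patient for property tests (kept light on purpose)."""
    n_doses = n_doses or int(rng.integers(2, 9))
    tau = 12.0
    amount = float(rng.uniform(0.5, 4.0))
    doses = [DoseEvent(time=j * tau, amount=amount) for j in range(n_doses)]
    age = float(rng.uniform(0.5, 17.0))
    crcl = float(rng.uniform(30.0, 300.0))
    flu = bool(rng.random() < 0.5)
    covs = [CovariateState(age=age, crcl=crcl, fluconazole=flu)]
    if with_cov_change and n_doses > 2:
        covs.append(CovariateState(age=age, crcl=crcl * float(rng.uniform(0.6, 1.5)),
                                   fluconazole=not flu,
                                   effective_from=tau * int(rng.integers(1, n_doses))))
    proto = PatientRecord(doses=doses, covariates=covs, id="rand")
    n_obs = n_obs or int(rng.integers(1, min(6, n_doses) + 1))
    times = sorted(rng.choice([tau * j for j in range(1, n_doses + 1)],
                              size=n_obs, replace=False).tolist())
    eta = EtaPair(float(rng.normal(0, model.omega_ke)),
                  float(rng.normal(0, model.omega_V)))
    clean = concentration_profile(proto, model, eta, times)
    noisy = np.maximum(clean + rng.normal(0, model.sigma_add, n_obs), 0.0)
    obs = [Observation(time=t, concentration=float(c)) for t, c in zip(times, noisy)]
    return PatientRecord(doses=doses, observations=obs, covariates=covs, id="rand"), eta
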