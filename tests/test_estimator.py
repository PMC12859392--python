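import math

import numpy as np
import pytest

from tacmipd import (CovariateState, DoseEvent, EtaPair, Observation,
                     PatientRecord, concentration_profile, fit_map,
                     map_objective)
from tacmipd.estimator import MapIndividualization, SolverSettings
from tacmipd import oracle

from conftest import random_patient


def patient_at_eta(model, eta, times=(12.0, 24.0, 36.0), n_doses=4, amount=2.0,
                   noise=None, rng=None):
    """Patient whose troughs are exact engine predictions at a known eta."""
    doses = [DoseEvent(time=12.0 * j, amount=amount) for j in range(n_doses)]
    cov = [CovariateState(age=6.0, crcl=110.0, fluconazole=False)]
    proto = PatientRecord(doses=doses, covariates=cov, id="sim")
    conc = concentration_profile(proto, model, eta, list(times))
    if noise is not None:
        conc = np.maximum(conc + rng.normal(0.0, noise, len(conc)), 0.0)
    obs = [Observation(time=t, concentration=float(c)) for t, c in zip(times, conc)]
    return PatientRecord(doses=doses, observations=obs, covariates=cov, id="sim")


class TestObjective:
    def test_pure_prior_at_mode_is_zero(self, model):
        p = PatientRecord(doses=[DoseEvent(time=0.0, amount=1.0)],
                          covariates=[CovariateState(age=5.0, crcl=100.0,
                                                     fluconazole=False)], id="p")
        assert map_objective(p, model, EtaPair(0.0, 0.0)) == 0.0

    def test_noise_free_observations_leave_only_prior_term(self, model):
        eta = EtaPair(0.25, -0.15)
        p = patient_at_eta(model, eta)
        expected = eta.eta_ke ** 2 / model.omega_ke ** 2 + eta.eta_V ** 2 / model.omega_V ** 2
        assert map_objective(p, model, eta) == pytest.approx(expected, rel=1e-9)

    def test_objective_grid_matches_independent_surface(self, model):
        """81x81 eta-grid evaluation agrees point-by-point with the oracle's coding."""
        rng = np.random.default_rng(5)
        patient, _ = random_patient(rng, model, n_doses=6, n_obs=4)
        gke = np.linspace(-5 * model.omega_ke, 5 * model.omega_ke, 81)
        gV = np.linspace(-5 * model.omega_V, 5 * model.omega_V, 81)
        surface = oracle._grid_surface(patient, model, gke, gV)
        for i in range(0, 81, 16):
            for j in range(0, 81, 16):
                mine = map_objective(patient, model, EtaPair(float(gke[i]), float(gV[j])))
                assert mine == pytest.approx(float(surface[i, j]), rel=1e-9)

    def test_below_assay_floor_observations_excluded_with_warning(self, model):
        p = patient_at_eta(model, EtaPair(0.0, 0.0))
        low = Observation(time=40.0, concentration=0.5)
        p2 = PatientRecord(doses=p.doses, observations=p.observations + [low],
                           covariates=p.covariates, id="p")
        with pytest.warns(UserWarning, match="assay"):
            v = map_objective(p2, model, EtaPair(0.0, 0.0))
        assert v == pytest.approx(map_objective(p, model, EtaPair(0.0, 0.0)), abs=1e-12)


class TestFit:
    def test_truth_at_prior_mode_recovered(self, model):
        p = patient_at_eta(model, EtaPair(0.0, 0.0))
        fit = fit_map(p, model)
        assert fit.converged
        assert abs(fit.eta.eta_ke) < 1e-6 and abs(fit.eta.eta_V) < 1e-6

    def test_monotone_descent(self, model):
        rng = np.random.default_rng(9)
        for _ in range(5):
            patient, _ = random_patient(rng, model, n_doses=8, n_obs=5)
            fit = fit_map(patient, model)
            h = fit.objective_history
            assert all(b <= a + 1e-12 for a, b in zip(h, h[1:]))
            assert fit.objective_value <= h[0]

    def test_separable_quadratic_minimum_recovered_exactly(self, model, simple_patient):
        m = MapIndividualization(simple_patient, model)
        a, b = 0.313, -0.741
        m.objective = lambda eta: (eta.eta_ke - a) ** 2 + 2.0 * (eta.eta_V - b) ** 2
        fit = m.fit()
        assert fit.converged
        assert fit.eta.eta_ke == pytest.approx(a, abs=1e-6)
        assert fit.eta.eta_V == pytest.approx(b, abs=1e-6)

    def test_shrinkage_with_single_observation(self, model):
        rng = np.random.default_rng(21)
        p = patient_at_eta(model, EtaPair(0.5, 0.4), times=(24.0,), noise=1.0, rng=rng)
        # omegas large enough that the prior penalty is negligible, i.e. a
        # residual-only fit, while keeping exp(eta) finite over the bracket
        loose = model.model_copy(update={"omega_ke": 30.0, "omega_V": 30.0})
        fit_prior = fit_map(p, model)
        fit_residual_only = fit_map(p, loose)
        assert abs(fit_prior.eta.eta_ke) <= abs(fit_residual_only.eta.eta_ke) + 1e-9
        assert abs(fit_prior.eta.eta_V) <= abs(fit_residual_only.eta.eta_V) + 1e-9

    def test_objective_value_matches_grid_oracle(self, model):
        rng = np.random.default_rng(13)
        for _ in range(15):
            patient, _ = random_patient(rng, model, n_doses=6)
            fit = fit_map(patient, model)
            ref = oracle.grid_objective(patient, model)
            if ref.objective_value > 1e-12:
                rel = abs(fit.objective_value - ref.objective_value) / ref.objective_value
                assert rel < 1e-6

    def test_parameter_recovery_improves_with_observations(self, model):
        """Bias of the fitted etas shrinks from 3 to 15 troughs per patient."""
        truth = EtaPair(0.30, -0.25)
        rng = np.random.default_rng(42)
        errs = {}
        for n_obs in (3, 15):
            fitted = []
            for _ in range(25):
                times = tuple(12.0 * j for j in range(1, n_obs + 1))
                p = patient_at_eta(model, truth, times=times, n_doses=n_obs + 1,
                                   noise=model.sigma_add, rng=rng)
                f = fit_map(p, model)
                fitted.append((f.eta.eta_ke, f.eta.eta_V))
            mean = np.mean(fitted, axis=0)
            errs[n_obs] = np.hypot(mean[0] - truth.eta_ke, mean[1] - truth.eta_V)
        assert errs[15] < errs[3]

    def test_prior_only_fit_is_flagged_not_silent(self, model):
        p = PatientRecord(doses=[DoseEvent(time=0.0, amount=1.0)],
                          covariates=[CovariateState(age=5.0, crcl=100.0,
                                                     fluconazole=False)], id="p")
        fit = fit_map(p, model)
        assert fit.prior_only
        assert fit.eta == EtaPair(0.0, 0.0)
        with pytest.raises(ValueError, match="prior-only"):
            fit_map(p, model, allow_prior_only=False)

    def test_deterministic_for_fixed_inputs(self, model, simple_patient):
        f1 = fit_map(simple_patient, model)
        f2 = fit_map(simple_patient, model)
        assert f1.eta == f2.eta and f1.objective_value == f2.objective_value

    def test_summary_mentions_convergence_and_etas(self, model, simple_patient):
        s = fit_map(simple_patient, model).summary()
        assert "eta_ke" in s and "converged" in s
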