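import math

import numpy as np
import pytest

from tacmipd import (CovariateState, DoseEvent, EtaPair, IndividualParameters,
                     PatientRecord, PKState, concentration_profile, propagate,
                     steady_state_trough, steady_state_trough_exact)
from tacmipd import oracle
from tacmipd.model import FlipFlopError

from conftest import random_patient

PARAMS = IndividualParameters(ke=0.08, V=75.0, ka=3.43)


def one_dose_patient(amount=2.0, age=6.0, crcl=110.0, flu=False):
    return PatientRecord(
        doses=[DoseEvent(time=0.0, amount=amount)],
        covariates=[CovariateState(age=age, crcl=crcl, fluconazole=flu)],
        id="p")


class TestPropagate:
    def test_zero_dt_is_identity(self):
        s = PKState(gut_amount=3.0, central_amount=1.0, at_time=5.0)
        assert propagate(s, PARAMS, 0.0) == s

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            propagate(PKState(), PARAMS, -1.0)

    def test_pure_elimination_is_mono_exponential(self):
        s = PKState(gut_amount=0.0, central_amount=4.0)
        out = propagate(s, PARAMS, 7.0)
        assert out.central_amount == pytest.approx(4.0 * math.exp(-0.08 * 7.0), rel=1e-14)
        assert out.gut_amount == 0.0

    def test_absorption_matches_numeric_ode(self, model):
        # 5 mg in the depot, advanced 12 h; compare against the ODE oracle
        patient = one_dose_patient(amount=5.0, age=model.age_ref, crcl=model.crcl_ref)
        out = propagate(PKState(gut_amount=5.0), IndividualParameters(ke=0.05, V=1.0, ka=3.43),
                        12.0)
        m = model.model_copy(update={"theta_ke": 0.05, "theta_V": 1.0})
        ref = oracle.integrate_numeric(patient, m, EtaPair(0.0, 0.0), [12.0])
        assert out.central_amount * 1000.0 == pytest.approx(float(ref[0]), rel=1e-8)

    def test_flip_flop_guarded(self):
        with pytest.raises(FlipFlopError):
            propagate(PKState(gut_amount=1.0), IndividualParameters(ke=3.43, V=10.0, ka=3.43),
                      1.0)


class TestConcentrationProfile:
    def test_zero_at_time_of_first_dose(self, model):
        conc = concentration_profile(one_dose_patient(), model, EtaPair(0, 0), [0.0])
        assert conc[0] == 0.0

    def test_query_before_time_zero_rejected(self, model):
        with pytest.raises(ValueError):
            concentration_profile(one_dose_patient(), model, EtaPair(0, 0), [-1.0])

    def test_linearity_in_dose(self, model):
        doses = [DoseEvent(time=12.0 * j, amount=1.5) for j in range(3)]
        doubled = [DoseEvent(time=d.time, amount=2.0 * d.amount) for d in doses]
        cov = [CovariateState(age=4.0, crcl=90.0, fluconazole=True)]
        times = [6.0, 12.0, 20.0, 36.0]
        c1 = concentration_profile(PatientRecord(doses=doses, covariates=cov, id="a"),
                                   model, EtaPair(0.2, 0.1), times)
        c2 = concentration_profile(PatientRecord(doses=doubled, covariates=cov, id="b"),
                                   model, EtaPair(0.2, 0.1), times)
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-14)

    def test_superposition_of_single_doses(self, model):
        # constant covariates: the response to each dose depends only on the lag
        rng = np.random.default_rng(7)
        dose_times = [0.0, 12.0, 26.0, 40.0]
        amounts = rng.uniform(0.5, 3.0, len(dose_times))
        cov = [CovariateState(age=8.0, crcl=150.0, fluconazole=False)]
        eta = EtaPair(-0.3, 0.2)
        patient = PatientRecord(
            doses=[DoseEvent(time=t, amount=float(a)) for t, a in zip(dose_times, amounts)],
            covariates=cov, id="multi")
        times = np.linspace(1.0, 72.0, 40)
        total = concentration_profile(patient, model, eta, times)
        summed = np.zeros_like(total)
        for t0, a in zip(dose_times, amounts):
            single = PatientRecord(doses=[DoseEvent(time=0.0, amount=float(a))],
                                   covariates=cov, id="single")
            lags = np.clip(times - t0, 0.0, None)
            summed += concentration_profile(single, model, eta, lags) * (times > t0)
        np.testing.assert_allclose(total, summed, rtol=1e-11, atol=1e-14)

    def test_mass_balance_never_exceeds_administered_dose(self, model):
        rng = np.random.default_rng(3)
        for _ in range(20):
            patient, eta = random_patient(rng, model)
            times = np.linspace(0.0, patient.doses[-1].time + 24.0, 30)
            conc = concentration_profile(patient, model, eta, times)
            total_mg = sum(d.amount for d in patient.doses)
            params_V = []  # central amount alone is bounded by the total dose
            cov = patient.covariates_at(0.0)
            assert np.all(conc >= 0.0)
            # conc (ng/mL) * V (L) / 1000 = central mg <= cumulative dose
            from tacmipd.model import individual_params
            for t, c in zip(times, conc):
                V = individual_params(model, patient.covariates_at(t), eta).V
                assert c * V / 1000.0 <= total_mg + 1e-9

    def test_segment_split_with_identical_covariates_is_noop(self, model):
        doses = [DoseEvent(time=12.0 * j, amount=2.0) for j in range(4)]
        cov = CovariateState(age=6.0, crcl=110.0, fluconazole=True)
        split = CovariateState(age=6.0, crcl=110.0, fluconazole=True, effective_from=18.0)
        times = np.linspace(0.0, 60.0, 61)
        eta = EtaPair(0.15, -0.2)
        base = concentration_profile(PatientRecord(doses=doses, covariates=[cov], id="a"),
                                     model, eta, times)
        forked = concentration_profile(
            PatientRecord(doses=doses, covariates=[cov, split], id="b"), model, eta, times)
        np.testing.assert_allclose(forked, base, rtol=1e-12, atol=1e-15)

    def test_trough_convention_pre_dose_at_dose_time(self, model):
        doses = [DoseEvent(time=0.0, amount=2.0), DoseEvent(time=12.0, amount=2.0)]
        patient = PatientRecord(doses=doses,
                                covariates=[CovariateState(age=6.0, crcl=110.0,
                                                           fluconazole=False)], id="p")
        eta = EtaPair(0.0, 0.0)
        at_dose, just_before, just_after = concentration_profile(
            patient, model, eta, [12.0, 12.0 - 1e-7, 12.0 + 1e-4])
        assert at_dose == pytest.approx(just_before, rel=1e-5)
        assert just_after > at_dose  # absorption from the new dose has begun

    def test_fluconazole_stop_matches_numeric_ode(self, model):
        doses = [DoseEvent(time=12.0 * j, amount=2.0) for j in range(12)]
        covs = [CovariateState(age=6.0, crcl=110.0, fluconazole=True),
                CovariateState(age=6.0, crcl=110.0, fluconazole=False,
                               effective_from=120.0)]
        patient = PatientRecord(doses=doses, covariates=covs, id="p")
        eta = EtaPair(0.1, -0.1)
        times = [12.0, 60.0, 119.0, 121.0, 144.0, 160.0]
        pred = concentration_profile(patient, model, eta, times)
        ref = oracle.integrate_numeric(patient, model, eta, times)
        np.testing.assert_allclose(pred, ref, rtol=1e-6)

    def test_random_patients_match_numeric_ode(self, model):
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(100):
            patient, eta = random_patient(rng, model, with_cov_change=True)
            times = sorted(rng.uniform(0.5, patient.doses[-1].time + 12.0, 5).tolist())
            pred = concentration_profile(patient, model, eta, times)
            ref = oracle.integrate_numeric(patient, model, eta, times)
            keep = ref > 1e-9
            worst = max(worst, float(np.max(np.abs(pred[keep] - ref[keep]) / ref[keep])))
        assert worst < 1e-6


class TestSteadyStateTrough:
    def test_linear_in_dose(self):
        assert steady_state_trough(4.0, 12.0, PARAMS) == pytest.approx(
            2.0 * steady_state_trough(2.0, 12.0, PARAMS), rel=1e-13)

    def test_long_interval_approaches_single_dose_trough(self):
        # ke*tau = 20: accumulation ratio ~ 1
        params = IndividualParameters(ke=0.5, V=50.0, ka=3.43)
        tau = 40.0
        multi = steady_state_trough(3.0, tau, params)
        # single-dose trough at tau
        single = (3.0 * params.ka / (params.V * (params.ka - params.ke))
                  * (math.exp(-params.ke * tau) - math.exp(-params.ka * tau))) * 1000.0
        assert multi == pytest.approx(single, rel=1e-6)

    def test_200_dose_superposition_matches_closed_form(self):
        params = IndividualParameters(ke=0.06, V=80.0, ka=3.43)
        sim = steady_state_trough(4.0, 12.0, params, n_doses=200)
        exact = steady_state_trough_exact(4.0, 12.0, params)
        assert abs(sim - exact) / exact < 1e-6

    @pytest.mark.parametrize("ke,V,tau", [(0.02, 30.0, 12.0), (0.1, 120.0, 12.0),
                                          (0.3, 60.0, 8.0), (0.05, 200.0, 24.0)])
    def test_closed_form_agreement_across_parameters(self, ke, V, tau):
        params = IndividualParameters(ke=ke, V=V, ka=3.43)
        sim = steady_state_trough(2.5, tau, params, n_doses=200)
        exact = steady_state_trough_exact(2.5, tau, params)
        assert abs(sim - exact) / exact < 1e-6

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            steady_state_trough(0.0, 12.0, PARAMS)
        with pytest.raises(ValueError):
            steady_state_trough(1.0, 0.0, PARAMS)
        with pytest.raises(ValueError):
            steady_state_trough_exact(-1.0, 12.0, PARAMS)
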