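"""Steady-state trough-targeted dose suggestion and display curves.

Because the PK is linear in dose, the dose attaining a target steady-state
trough is found exactly by scaling: predict the 200-dose trough of a 1 mg
probe regimen at the patient's last-observed covariates and MAP parameters,
then scale.  The scaled dose is cross-checked internally by re-simulating
200 doses; the relative error must be below 1e-6 before any rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np

from .data import DoseEvent, PatientRecord
from .engine import concentration_profile, steady_state_trough
from .model import EtaPair, PopPKModel, individual_params

__all__ = ["DoseRecommendation", "suggest_dose", "predicted_curve"]

DEFAULT_TARGET_NGML = 12.0
DEFAULT_INTERVAL_H = 12.0
DEFAULT_THERAPEUTIC_RANGE = (10.0, 14.0)
N_DOSES_STEADY_STATE = 200


@dataclass(frozen=True)
class DoseRecommendation:
    """Suggested per-administration dose for a stated interval and target trough.

    ``dose`` is the exact (unrounded) amount; ``rounded_dose`` is populated
    only when a rounding increment was requested and is reported separately
    so the exact solution is never silently discarded.
    """

    dose: float                 # mg per administration (exact)
    interval: float             # h
    target_trough: float        # ng/mL
    predicted_trough: float     # ng/mL, from the 200-dose cross-check
    within_range: bool
    therapeutic_range: Tuple[float, float]
    curve: List[Tuple[float, float]]
    rounded_dose: Optional[float] = None

    def summary(self) -> str:
        lo, hi = self.therapeutic_range
        lines = [
            "Dose recommendation",
            "=" * 46,
            f"{'dose (mg)':<26}{self.dose:.4f}",
        ]
        if self.rounded_dose is not None:
            lines.append(f"{'rounded dose (mg)':<26}{self.rounded_dose:.2f}")
        lines += [
            f"{'interval (h)':<26}{self.interval:g}",
            f"{'target trough (ng/mL)':<26}{self.target_trough:g}",
            f"{'predicted trough (ng/mL)':<26}{self.predicted_trough:.4f}",
            f"{'therapeutic range':<26}{lo:g}-{hi:g} ng/mL",
            f"{'within range':<26}{self.within_range}",
        ]
        return "\n".join(lines)


def _resolve_eta(fit_or_eta) -> EtaPair:
    if isinstance(fit_or_eta, EtaPair):
        return fit_or_eta
    if not fit_or_eta.converged:
        warnings.warn("MAP fit did not converge; dose suggestion may be unreliable",
                      stacklevel=3)
    return fit_or_eta.eta


def suggest_dose(patient: PatientRecord, model: PopPKModel, fit,
                 target: float = DEFAULT_TARGET_NGML,
                 interval: float = DEFAULT_INTERVAL_H,
                 therapeutic_range: Tuple[float, float] = DEFAULT_THERAPEUTIC_RANGE,
                 rounding_increment: Optional[float] = None,
                 with_curve: bool = True,
                 curve_horizon: float = 72.0,
                 curve_step: float = 0.25,
                 n_doses: int = N_DOSES_STEADY_STATE,
                 probe_dose: float = 1.0) -> DoseRecommendation:
    """Dose per ``interval`` attaining ``target`` ng/mL trough at steady state.

    Covariates are frozen at the patient's last-observed state.  ``fit`` may
    be a :class:`~tacmipd.estimator.MapResults` or a raw :class:`EtaPair`.
    """
    if target <= 0:
        raise ValueError("target trough must be positive")
    if interval <= 0:
        raise ValueError("interval must be positive")
    eta = _resolve_eta(fit)
    params = individual_params(model, patient.last_covariates, eta)

    if probe_dose <= 0:
        raise ValueError("probe_dose must be positive")
    probe_trough = steady_state_trough(probe_dose, interval, params, n_doses)
    if probe_trough <= 0:
        raise ValueError("non-positive steady-state trough for the probe dose")
    dose = probe_dose * target / probe_trough

    predicted = steady_state_trough(dose, interval, params, n_doses)
    if abs(predicted - target) / target >= 1e-6:
        raise RuntimeError(
            f"dose cross-check failed: simulated trough {predicted:.6f} vs "
            f"target {target:.6f}")

    rounded = None
    if rounding_increment is not None:
        if rounding_increment <= 0:
            raise ValueError("rounding increment must be positive")
        rounded = round(dose / rounding_increment) * rounding_increment

    curve: List[Tuple[float, float]] = []
    if with_curve:
        curve = predicted_curve(patient, model, eta, dose, curve_horizon,
                                interval=interval, step=curve_step)

    lo, hi = therapeutic_range
    return DoseRecommendation(
        dose=dose, interval=interval, target_trough=target,
        predicted_trough=predicted, within_range=lo <= predicted <= hi,
        therapeutic_range=therapeutic_range, curve=curve, rounded_dose=rounded)


def predicted_curve(patient: PatientRecord, model: PopPKModel, fit,
                    future_dose: float, horizon: float,
                    interval: float = DEFAULT_INTERVAL_H,
                    step: float = 0.25) -> List[Tuple[float, float]]:
    """Fitted-history profile concatenated with the projected future regimen.

    The future regimen starts one interval after the last historical dose and
    repeats every ``interval`` hours at ``future_dose`` mg (``0`` shows pure
    washout).  The grid runs from 0 to ``last dose + horizon`` at ``step``
    hours and always includes the observation times, so curve values there
    coincide with the predictions used in the MAP objective.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if future_dose < 0:
        raise ValueError("future_dose must be non-negative")
    eta = _resolve_eta(fit)
    t_last = patient.doses[-1].time if patient.doses else 0.0
    end = t_last + horizon

    doses = list(patient.doses)
    if future_dose > 0:
        t = t_last + interval
        while t <= end + 1e-9:
            doses.append(DoseEvent(time=t, amount=future_dose))
            t += interval
    future_patient = PatientRecord(doses=doses, observations=[],
                                   covariates=list(patient.covariates),
                                   id=patient.id)

    grid = np.arange(0.0, end + step / 2, step)
    times = np.unique(np.concatenate(
        [grid, [o.time for o in patient.observations], [end]]))
    times = times[times <= end + 1e-9]
    conc = concentration_profile(future_patient, model, eta, times)
    return list(zip(times.tolist(), conc.tolist()))
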