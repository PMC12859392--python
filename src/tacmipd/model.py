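"""Population-PK model specification for tacrolimus dose individualization.

The model is a one-compartment disposition with first-order absorption,
parameterized on the elimination rate constant ``ke`` (1/h), apparent volume
of distribution ``V`` (L, absorbing oral bioavailability), and a fixed
absorption rate constant ``ka`` (1/h).  Between-subject variability enters as
log-normal random effects (ETAs) on ``ke`` and ``V``; residual error on
observed trough concentrations is additive.  Covariates:

* creatinine clearance (power law) and fluconazole co-therapy
  (multiplicative fraction) act on ``ke``;
* age (power law) acts on ``V``.

The individual parameters are

.. math::

    k_e = \\theta_{ke} \\cdot (CrCl/CrCl_{ref})^{\\beta_{crcl}}
          \\cdot \\beta_{flu}^{[flu]} \\cdot e^{\\eta_{ke}},
    \\qquad
    V = \\theta_V \\cdot (age/age_{ref})^{\\beta_{age}} \\cdot e^{\\eta_V}.

This module only *consumes* a fitted population model (loaded from a flat
key-value config file); it does not estimate population parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = [
    "PopPKModel",
    "CovariateState",
    "EtaPair",
    "IndividualParameters",
    "FlipFlopError",
    "ModelConfigError",
    "load_model",
    "save_model",
    "individual_params",
    "demo_model",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

#: relative distance between individual ke and ka below which the closed-form
#: solution (which divides by ka - ke) is rejected as numerically degenerate.
FLIP_FLOP_REL_TOL = 1e-6


class ModelConfigError(ValueError):
    """Raised when a model config is missing or violates an invariant."""


class FlipFlopError(ValueError):
    """Individual ke is numerically indistinguishable from ka.

    In that regime absorption and elimination rates swap roles and the
    closed-form concentration expression is singular.
    """


class PopPKModel(BaseModel):
    """Population pharmacokinetic model parameters and covariate references.

    All rates are 1/h, volumes L, concentrations ng/mL, times h.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    theta_ke: float = Field(gt=0, description="typical elimination rate constant, 1/h")
    theta_V: float = Field(gt=0, description="typical apparent volume of distribution, L")
    ka: float = Field(default=3.43, gt=0, description="fixed first-order absorption rate, 1/h")
    beta_crcl: float = Field(description="power exponent of CrCl on ke")
    beta_flu: float = Field(gt=0, description="multiplicative fluconazole fraction on ke")
    beta_age: float = Field(description="power exponent of age on V")
    crcl_ref: float = Field(gt=0, description="reference CrCl, mL/min/1.73 m^2")
    age_ref: float = Field(gt=0, description="reference age, years")
    omega_ke: float = Field(gt=0, description="SD of eta_ke (log scale)")
    omega_V: float = Field(gt=0, description="SD of eta_V (log scale)")
    sigma_add: float = Field(gt=0, description="additive residual SD, ng/mL")


@dataclass(frozen=True)
class CovariateState:
    """Covariate values in force from ``effective_from`` (h since first dose)."""

    age: float
    crcl: float
    fluconazole: bool
    effective_from: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.age <= 25.0:
            raise ValueError(f"age {self.age} outside plausible pediatric range [0, 25] y")
        if self.crcl <= 0:
            raise ValueError(f"crcl must be positive, got {self.crcl}")
        if self.effective_from < 0:
            raise ValueError("effective_from must be non-negative")


@dataclass(frozen=True)
class EtaPair:
    """Log-scale random effects on ke and V; (0, 0) is the population-typical subject."""

    eta_ke: float = 0.0
    eta_V: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.eta_ke) and math.isfinite(self.eta_V)):
            raise ValueError("eta values must be finite")


@dataclass(frozen=True)
class IndividualParameters:
    """Individual PK parameters after covariate and ETA adjustment."""

    ke: float
    V: float
    ka: float

    def __post_init__(self) -> None:
        if min(self.ke, self.V, self.ka) <= 0:
            raise ValueError("individual parameters must be strictly positive")


def baseline_ke(model: PopPKModel, cov: CovariateState) -> float:
    """Covariate-adjusted typical ke (before the ETA multiplier)."""
    f_crcl = (cov.crcl / model.crcl_ref) ** model.beta_crcl
    f_flu = model.beta_flu if cov.fluconazole else 1.0
    return model.theta_ke * f_crcl * f_flu


def baseline_V(model: PopPKModel, cov: CovariateState) -> float:
    """Covariate-adjusted typical V (before the ETA multiplier)."""
    return model.theta_V * (cov.age / model.age_ref) ** model.beta_age


def individual_params(model: PopPKModel, cov: CovariateState, eta: EtaPair) -> IndividualParameters:
    """Map population parameters + covariates + ETAs to individual (ke, V, ka).

    ETAs are log-scale: they are exponentiated and multiplied onto the
    covariate-adjusted typical values.  Raises :class:`FlipFlopError` when the
    individual ke lands within ``FLIP_FLOP_REL_TOL`` (relative) of ka.
    """
    ke = baseline_ke(model, cov) * math.exp(eta.eta_ke)
    V = baseline_V(model, cov) * math.exp(eta.eta_V)
    if not (math.isfinite(ke) and math.isfinite(V)):
        raise ValueError("non-finite individual parameters (check covariates and etas)")
    if abs(ke - model.ka) / model.ka < FLIP_FLOP_REL_TOL:
        raise FlipFlopError(
            f"individual ke={ke:.6g} within {FLIP_FLOP_REL_TOL:g} relative of ka={model.ka:g}"
        )
    return IndividualParameters(ke=ke, V=V, ka=model.ka)


def load_model(config_source: Union[str, Path, Mapping[str, Any]]) -> PopPKModel:
    """Load and validate a model from a flat key-value config (YAML file or mapping).

    The config may omit ``ka`` (defaults to the fixed 3.43/h) and carries a
    ``schema_version`` key.  Any missing or non-positive required parameter
    raises :class:`ModelConfigError` naming the offending field.
    """
    if isinstance(config_source, (str, Path)):
        with open(config_source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ModelConfigError(f"model config {config_source} is not a key-value mapping")
    else:
        raw = dict(config_source)
    version = raw.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ModelConfigError(f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})")
    try:
        return PopPKModel(**raw)
    except ValidationError as exc:
        fields = ", ".join(str(err["loc"][0]) if err["loc"] else "?" for err in exc.errors())
        raise ModelConfigError(f"invalid model config (fields: {fields}): {exc}") from exc


def save_model(model: PopPKModel, path: Union[str, Path]) -> None:
    """Serialize a model to the flat YAML config format (round-trips with load_model)."""
    payload = {"schema_version": SCHEMA_VERSION, **model.model_dump()}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def demo_model() -> PopPKModel:
    """Illustrative model used by the self-validation protocol and examples.

    The values are pharmacologically plausible for pediatric oral tacrolimus
    (typical trough near 10 ng/mL at ~0.05 mg/kg every 12 h) but are NOT a
    published clinical model; clinical use requires an explicit model file.
    """
    return PopPKModel(
        theta_ke=0.08,
        theta_V=75.0,
        ka=3.43,
        beta_crcl=0.35,
        beta_flu=0.7,
        beta_age=0.8,
        crcl_ref=120.0,
        age_ref=5.7,
        omega_ke=0.40,
        omega_V=0.35,
        sigma_add=1.5,
    )
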