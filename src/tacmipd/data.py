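"""Patient-level data containers: dose events, trough observations, records.

Times are decimal hours since the first tacrolimus dose; amounts mg;
concentrations ng/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

from .model import CovariateState

__all__ = ["DoseEvent", "Observation", "PKState", "PatientRecord",
           "ASSAY_LOWER_NGML", "ASSAY_UPPER_NGML"]

# Linear range of the whole-blood LC-MS/MS assay, ng/mL.
ASSAY_LOWER_NGML = 1.0
ASSAY_UPPER_NGML = 40.0


@dataclass(frozen=True)
class DoseEvent:
    """A single oral/enteral dose."""

    time: float          # h since first dose
    amount: float        # mg
    interval_id: int = 0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be non-negative")
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")


@dataclass(frozen=True)
class Observation:
    """A measured trough concentration."""

    time: float           # h since first dose
    concentration: float  # ng/mL

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("observation time must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")

    @property
    def below_assay_range(self) -> bool:
        return self.concentration < ASSAY_LOWER_NGML

    @property
    def above_assay_range(self) -> bool:
        return self.concentration > ASSAY_UPPER_NGML

    @property
    def in_assay_range(self) -> bool:
        return not (self.below_assay_range or self.above_assay_range)


@dataclass(frozen=True)
class PKState:
    """Drug amounts in the depot (gut) and central compartments, mg."""

    gut_amount: float = 0.0
    central_amount: float = 0.0
    at_time: float = 0.0

    def __post_init__(self) -> None:
        if self.gut_amount < -1e-12 or self.central_amount < -1e-12:
            raise ValueError("compartment amounts must be non-negative")


@dataclass
class PatientRecord:
    """One individual's dosing history, trough observations, and covariates.

    Covariates are piecewise constant: each :class:`CovariateState` is in
    force from its ``effective_from`` time until the next one.  The first
    covariate state must start at time 0.
    """

    doses: List[DoseEvent]
    observations: List[Observation] = field(default_factory=list)
    covariates: List[CovariateState] = field(default_factory=list)
    id: str = ""

    def __post_init__(self) -> None:
        if not self.covariates:
            raise ValueError(f"patient {self.id!r}: a covariate state at time 0 is required")
        if self.covariates[0].effective_from != 0.0:
            raise ValueError(f"patient {self.id!r}: first covariate state must start at time 0")
        for name, times in (
            ("doses", [d.time for d in self.doses]),
            ("observations", [o.time for o in self.observations]),
        ):
            if any(b < a for a, b in zip(times, times[1:])):
                raise ValueError(f"patient {self.id!r}: {name} not time-sorted")
        cov_times = [c.effective_from for c in self.covariates]
        if any(b <= a for a, b in zip(cov_times, cov_times[1:])):
            raise ValueError(f"patient {self.id!r}: covariate times must be strictly increasing")
        if self.doses and self.doses[0].time != 0.0:
            raise ValueError(f"patient {self.id!r}: first dose must be at time 0")

    def covariates_at(self, time: float) -> CovariateState:
        """Covariate state in force at ``time`` (right-continuous step function)."""
        current = self.covariates[0]
        for cov in self.covariates[1:]:
            if cov.effective_from <= time:
                current = cov
            else:
                break
        return current

    @property
    def last_covariates(self) -> CovariateState:
        return self.covariates[-1]

    def usable_observations(self) -> List[Observation]:
        """Observations at/above the assay floor (below-range troughs are excluded
        from fitting, matching the assay's stated linear range)."""
        return [o for o in self.observations if not o.below_assay_range]


def validate_sorted(times: Sequence[float], label: str) -> None:
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError(f"{label} must be time-sorted")
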