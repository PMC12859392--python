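"""Dataset reader/writer for the NONMEM-flavored CSV dialect.

Columns: ``ID, TIME, AMT, DV, AGE, CRCL, FLUC`` — one row per event.  A row
with a non-empty ``AMT`` is a dose; a non-empty ``DV`` is a trough
observation; a row may not be both.  ``TIME`` is decimal hours since the
individual's first dose and must be non-decreasing within an ID.  Covariate
columns are carried forward when blank; the first row of each individual
must provide all three.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import IO, List, Sequence, Union

import pandas as pd

from .data import ASSAY_LOWER_NGML, DoseEvent, Observation, PatientRecord
from .model import CovariateState

__all__ = ["read_dataset", "write_dataset", "read_trough_series",
           "datetimes_to_hours", "COLUMNS"]

COLUMNS = ["ID", "TIME", "AMT", "DV", "AGE", "CRCL", "FLUC"]


class DatasetError(ValueError):
    """Malformed dataset row or structure."""


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or value == ""


def read_dataset(source: Union[str, Path, IO]) -> List[PatientRecord]:
    """Parse a dataset CSV into validated patient records.

    Warns on observations below the assay's linear range (1 ng/mL); raises
    :class:`DatasetError` (with the row number) on rows that are both dose
    and observation, or on non-monotone TIME within an ID.
    """
    df = pd.read_csv(source, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"dataset missing columns: {', '.join(missing)}")

    patients: List[PatientRecord] = []
    for pid, group in df.groupby("ID", sort=False):
        doses: List[DoseEvent] = []
        observations: List[Observation] = []
        covariates: List[CovariateState] = []
        current = None  # (age, crcl, flu)
        prev_time = -math.inf
        for row_idx, row in group.iterrows():
            line = row_idx + 2  # header + 1-based
            t = float(row["TIME"])
            if t < prev_time:
                raise DatasetError(f"row {line}: TIME decreases within ID {pid!r}")
            prev_time = t
            amt, dv = row["AMT"], row["DV"]
            if not _is_blank(amt) and not _is_blank(dv):
                raise DatasetError(f"row {line}: row is both a dose (AMT) and an "
                                   f"observation (DV)")
            if _is_blank(amt) and _is_blank(dv):
                raise DatasetError(f"row {line}: row is neither a dose nor an observation")

            cov_vals = []
            for col, cast in (("AGE", float), ("CRCL", float), ("FLUC", lambda v: bool(int(v)))):
                v = row[col]
                if _is_blank(v):
                    if current is None:
                        raise DatasetError(f"row {line}: first row of ID {pid!r} must "
                                           f"provide {col}")
                    cov_vals.append(None)
                else:
                    cov_vals.append(cast(v))
            if current is None:
                new = tuple(cov_vals)
            else:
                new = tuple(c if c is not None else old
                            for c, old in zip(cov_vals, current))
            if new != current:
                if covariates and covariates[-1].effective_from == t:
                    covariates[-1] = CovariateState(age=new[0], crcl=new[1],
                                                    fluconazole=new[2], effective_from=t)
                else:
                    covariates.append(CovariateState(age=new[0], crcl=new[1],
                                                     fluconazole=new[2], effective_from=t))
                current = new

            if not _is_blank(amt):
                doses.append(DoseEvent(time=t, amount=float(amt)))
            else:
                conc = float(dv)
                if conc < ASSAY_LOWER_NGML:
                    warnings.warn(f"row {line}: concentration {conc} ng/mL below the "
                                  "assay's linear range (1-40 ng/mL)", stacklevel=2)
                observations.append(Observation(time=t, concentration=conc))
        patients.append(PatientRecord(doses=doses, observations=observations,
                                      covariates=covariates, id=str(pid)))
    return patients


def write_dataset(patients: Sequence[PatientRecord], target: Union[str, Path, IO]) -> None:
    """Write patient records in the dataset dialect (round-trips with read_dataset).

    Covariates are written in full on each individual's first row and
    repeated only when they change.
    """
    rows = []
    for p in patients:
        events = ([("dose", d.time, d) for d in p.doses]
                  + [("obs", o.time, o) for o in p.observations])
        events.sort(key=lambda e: (e[1], 0 if e[0] == "obs" else 1))  # trough pre-dose
        last_cov = None
        for kind, t, ev in events:
            cov = p.covariates_at(t)
            if cov != last_cov:
                age, crcl, flu = cov.age, cov.crcl, int(cov.fluconazole)
                last_cov = cov
            else:
                age = crcl = flu = None
            rows.append({
                "ID": p.id, "TIME": t,
                "AMT": ev.amount if kind == "dose" else None,
                "DV": ev.concentration if kind == "obs" else None,
                "AGE": age, "CRCL": crcl, "FLUC": flu,
            })
    pd.DataFrame(rows, columns=COLUMNS).to_csv(target, index=False)


def read_trough_series(source: Union[str, Path, IO]) -> List[tuple]:
    """Read a (day, concentration) CSV used by the endpoint calculator."""
    df = pd.read_csv(source)
    cols = {c.lower(): c for c in df.columns}
    if "day" not in cols or "concentration" not in cols:
        raise DatasetError("trough series needs columns: day, concentration")
    return list(zip(df[cols["day"]].astype(float), df[cols["concentration"]].astype(float)))


def datetimes_to_hours(datetimes: Sequence) -> List[float]:
    """Convert datetimes to decimal hours since the first entry (the first dose)."""
    ts = pd.to_datetime(list(datetimes))
    if len(ts) == 0:
        return []
    return [(t - ts[0]).total_seconds() / 3600.0 for t in ts]
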