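"""Core participant-level data containers shared across the pipeline.

A cohort is a list of :class:`ParticipantRecord`; creatinine is carried in
mg/dL throughout (the point-of-care reporting unit), with conversion to
µmol/L confined to the I/O boundary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

FEMALE = "female"
MALE = "male"

#: unit conversion applied only at the I/O boundary
UMOL_PER_MGDL = 88.42

#: plausible serum-creatinine range in mg/dL; values above flag a unit mix-up
CREATININE_RANGE_MGDL = (0.0, 25.0)


class DomainError(ValueError):
    """An input lies outside the physical/clinical domain of an operation."""


def mgdl_to_umol(value: float) -> float:
    return value * UMOL_PER_MGDL


def umol_to_mgdl(value: float) -> float:
    return value / UMOL_PER_MGDL


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


@dataclass(frozen=True)
class PersonParams:
    """Demographic/anthropometric covariates of the kidney-function equations."""

    age: float
    sex: str
    weight: Optional[float] = None  # kg
    height: Optional[float] = None  # cm

    def __post_init__(self):
        if self.sex not in (FEMALE, MALE):
            raise DomainError(f"sex must be {FEMALE!r} or {MALE!r}, got {self.sex!r}")
        if _is_missing(self.age) or self.age <= 0:
            raise DomainError(f"age must be strictly positive, got {self.age}")
        for name in ("weight", "height"):
            v = getattr(self, name)
            if v is not None and not _is_missing(v) and v <= 0:
                raise DomainError(f"{name} must be strictly positive when present, got {v}")


@dataclass(frozen=True)
class CreatinineSeries:
    """Serum creatinine (mg/dL) at admission, 48 h and 3 months."""

    cr0: float
    cr48: Optional[float] = None
    cr3m: Optional[float] = None

    def __post_init__(self):
        lo, hi = CREATININE_RANGE_MGDL
        for name in ("cr0", "cr48", "cr3m"):
            v = getattr(self, name)
            if v is None or _is_missing(v):
                continue
            if not (lo < v <= hi):
                raise DomainError(
                    f"{name}={v} mg/dL outside ({lo}, {hi}]; values above {hi} "
                    "suggest µmol/L was supplied where mg/dL is expected"
                )

    def present(self, name: str) -> bool:
        return not _is_missing(getattr(self, name))


@dataclass(frozen=True)
class UrineFindings:
    """Dipstick findings at admission."""

    haematuria: bool = False
    proteinuria: bool = False


@dataclass
class ParticipantRecord:
    """One cohort row: demographics, vitals, HIV, creatinine series, urine,
    ultrasound index and vital status.

    Optional fields are ``None`` when the measurement is missing; analyses are
    complete-case per endpoint.
    """

    pid: str
    age: float
    sex: str
    hiv: Optional[bool] = None            # None: status unknown
    art: Optional[bool] = None            # antiretroviral therapy, among HIV+
    sbp: Optional[float] = None           # mm Hg
    dbp: Optional[float] = None           # mm Hg
    rr: Optional[float] = None            # breaths/min
    gcs: Optional[int] = None             # Glasgow Coma Scale 3-15
    cr0: Optional[float] = None           # mg/dL at admission
    cr48: Optional[float] = None          # mg/dL at 48 h
    cr3m: Optional[float] = None          # mg/dL at 3 months
    haematuria: Optional[bool] = None
    proteinuria: Optional[bool] = None
    ri: Optional[float] = None            # renal resistive index
    weight: Optional[float] = None        # kg
    height: Optional[float] = None        # cm
    died: Optional[bool] = None           # None: lost to follow-up
    followup_days: Optional[float] = None

    def person(self) -> PersonParams:
        return PersonParams(age=self.age, sex=self.sex, weight=self.weight, height=self.height)

    def series(self) -> CreatinineSeries:
        if _is_missing(self.cr0):
            raise DomainError(f"participant {self.pid}: admission creatinine (cr0) required")
        return CreatinineSeries(cr0=self.cr0, cr48=self.cr48, cr3m=self.cr3m)

    def urine(self) -> UrineFindings:
        return UrineFindings(haematuria=bool(self.haematuria), proteinuria=bool(self.proteinuria))


#: canonical cohort CSV column order (the interchange dictionary)
COHORT_COLUMNS = [f.name for f in fields(ParticipantRecord)]
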